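"""Synthetic-data generator: planted truth, determinism, calibrations."""

import numpy as np
import pytest

from paranome.motifs import vntr_dna
from paranome.simulate import (
    plant_events,
    revcomp,
    simulate_family,
    simulate_reads,
    simulate_sweep,
    simulate_transcripts,
)


def _div(a: str, b: str) -> float:
    x = np.frombuffer(a.encode(), dtype=np.uint8)
    y = np.frombuffer(b.encode(), dtype=np.uint8)
    return float((x != y).mean())


class TestFamily:
    def test_same_seed_identical(self):
        f1 = simulate_family(ancestor_len=2000, n_paralogs=3, seed=5, flank=500, spacer=500)
        f2 = simulate_family(ancestor_len=2000, n_paralogs=3, seed=5, flank=500, spacer=500)
        assert f1.assemblies() == f2.assemblies()

    def test_different_seed_differs(self):
        f1 = simulate_family(ancestor_len=2000, n_paralogs=3, seed=5, flank=500, spacer=500)
        f2 = simulate_family(ancestor_len=2000, n_paralogs=3, seed=6, flank=500, spacer=500)
        assert f1.ancestor_seq != f2.ancestor_seq

    def test_pairwise_divergence_matches_request(self):
        # binomial CI: 20 kbp at 3% -> +-20% comfortably covers sampling noise
        fam = simulate_family(ancestor_len=20_000, n_paralogs=8, inter_div=0.03, seed=1, flank=100, spacer=100)
        names = sorted(fam.paralog_seqs)
        divs = [
            _div(fam.paralog_seqs[a], fam.paralog_seqs[b])
            for i, a in enumerate(names)
            for b in names[i + 1 :]
        ]
        assert all(0.8 * 0.03 <= d <= 1.2 * 0.03 for d in divs)

    def test_zero_inter_div_rejected_but_tiny_allowed(self):
        with pytest.raises(ValueError):
            simulate_family(inter_div=0.0, intra_div=0.0, n_paralogs=2)
        with pytest.raises(ValueError):
            simulate_family(n_paralogs=0)

    def test_truth_conservation_copies(self, small_family):
        cn = small_family.planted_cn()
        for hap in small_family.haplotype_ids:
            total = cn[cn.haplotype == hap].cn.sum()
            assert total == len(small_family.copies(hap))
            # placements tile the assembly without overlap
            placements = small_family.placements(hap)
            for (_, s1, e1, _), (_, s2, _, _) in zip(placements, placements[1:]):
                assert s2 >= e1


class TestPlantEvents:
    def test_no_events_is_identity(self, small_family):
        fam2 = plant_events(small_family)
        assert fam2.assemblies() == small_family.assemblies()

    def test_inversion_flips_strands_and_order(self, small_family):
        fam2 = plant_events(small_family, inversions=[("s1_h1", 1, 2)])
        before = small_family.configuration("s1_h1")
        after = fam2.configuration("s1_h1")
        assert after[1] == (before[2][0], "-")
        assert after[2] == (before[1][0], "-")
        assert fam2.planted_inversions[0][2] == [before[1][0], before[2][0]]

    def test_igc_makes_acceptor_match_donor(self, small_family):
        fam2 = plant_events(small_family, igc_tracts=[("s1_h1", 0, "P3", 500, 1500)])
        copy = fam2.copies("s1_h1")[0]
        donor = fam2.paralog_seqs["P3"]
        assert copy.allele_seq[500:2000] == donor[500:2000]
        own = fam2.paralog_seqs[copy.paralog]
        assert _div(copy.allele_seq[500:2000], own[500:2000]) > 0.01

    def test_overlapping_igc_rejected(self, small_family):
        with pytest.raises(ValueError, match="overlap"):
            plant_events(
                small_family,
                igc_tracts=[("s1_h1", 0, "P3", 500, 1000), ("s1_h1", 0, "P4", 1200, 1000)],
            )

    def test_cn_changes_update_truth(self, small_family):
        fam2 = plant_events(small_family, cn_changes=[("s1_h1", "P2", 2), ("s1_h2", "P3", -1)])
        cn = fam2.planted_cn().set_index(["haplotype", "paralog"]).cn
        assert cn[("s1_h1", "P2")] == 3
        assert cn[("s1_h2", "P3")] == 0

    def test_unknown_paralog_rejected(self, small_family):
        with pytest.raises(ValueError):
            plant_events(small_family, cn_changes=[("s1_h1", "P99", 1)])
        with pytest.raises(ValueError):
            plant_events(small_family, igc_tracts=[("s1_h1", 0, "P1", 0, 100)])  # donor == acceptor


class TestReads:
    def test_same_seed_identical_reads(self, small_family):
        r1, _ = simulate_reads(small_family, "dna_short", depth=2, read_len=100, seed=9)
        r2, _ = simulate_reads(small_family, "dna_short", depth=2, read_len=100, seed=9)
        assert r1 == r2

    def test_depth_poisson_bounds(self):
        # CN=2 region (one copy per haplotype): depth 30 -> per-base coverage
        # within the 99% Poisson interval around 30
        fam = simulate_family(ancestor_len=3000, n_paralogs=2, seed=11, flank=4000, spacer=2000)
        reads, truth = simulate_reads(fam, "dna_short", depth=30, read_len=100, err_rate=0.0, seed=2)
        hap = "s1_h1"
        # coverage of the first paralog copy region on h1 from truth starts
        t = truth[truth.haplotype == hap]
        region = fam.placements(hap)[0]
        mid = (region[1] + region[2]) // 2
        cov_h1 = ((t.start <= mid) & (t.start + 100 > mid)).sum()
        t2 = truth[truth.haplotype == "s1_h2"]
        cov = cov_h1 + ((t2.start <= mid) & (t2.start + 100 > mid)).sum()
        lo, hi = 30 - 3 * np.sqrt(30), 30 + 3 * np.sqrt(30)
        assert lo <= cov <= hi

    def test_isoseq_contains_planted_vntr_units(self, vntr_family, vntr_transcripts):
        reads, truth = simulate_reads(
            vntr_family, "isoseq", depth=20, err_rate=0.0,
            transcripts=vntr_transcripts, expression_profile={"P3": 1.0}, seed=3,
        )
        unit_dna = vntr_dna(7, 6, 5)
        for seq in reads.values():
            assert unit_dna in seq

    def test_unknown_profile_paralog_rejected(self, small_family):
        with pytest.raises(ValueError, match="unknown paralog"):
            simulate_reads(small_family, "isoseq", depth=5, expression_profile={"nope": 1.0}, seed=1)

    def test_truth_covers_every_read(self, small_family):
        reads, truth = simulate_reads(small_family, "dna_short", depth=1, read_len=100, seed=4)
        assert set(reads) == set(truth.read)
        assert truth.read.is_unique


class TestSweep:
    def test_no_mutation_no_sites(self):
        vm, _ = simulate_sweep(n_haplotypes=10, L=1000, mu=0.0, rho=0.0, s=0.0, N=20, seed=1)
        assert vm.n_sites == 0

    def test_neutral_diversity_matches_coalescent_expectation(self):
        # E[pi/bp] = 2*N*mu for a haploid Wright-Fisher population
        reps = 40
        pis = []
        for seed in range(reps):
            vm, _ = simulate_sweep(n_haplotypes=20, L=10_000, mu=1e-5, rho=0.0, s=0.0, N=100, seed=seed)
            h = vm.haplotypes
            n = h.shape[0]
            ac = h.sum(axis=0)
            pis.append(float((2.0 * ac * (n - ac)).sum() / (n * (n - 1))) / 10_000)
        pis = np.array(pis)
        se = pis.std(ddof=1) / np.sqrt(reps)
        assert abs(pis.mean() - 2 * 100 * 1e-5) < 3 * se

    def test_sweep_increases_local_haplotype_homozygosity(self):
        # at a sweep of appreciable strength (N*s = 20), haplotype
        # homozygosity around the sweep site exceeds the mean neutral level
        # in most replicates
        from collections import Counter

        def hom(vm):
            sub = vm.slice(20_000, 30_000)
            if sub.n_sites == 0:
                return 1.0
            c = Counter(tuple(r) for r in sub.haplotypes)
            n = sub.n_haplotypes
            return sum(k * (k - 1) for k in c.values()) / (n * (n - 1))

        reps = 10
        kw = dict(n_haplotypes=20, L=50_000, mu=2e-6, rho=2e-7, N=100)
        neut = [hom(simulate_sweep(s=0.0, seed=seed, **kw)[0]) for seed in range(reps)]
        sweep = [hom(simulate_sweep(s=0.2, seed=seed, **kw)[0]) for seed in range(reps)]
        neutral_mean = float(np.mean(neut))
        wins = sum(h > neutral_mean for h in sweep)
        assert wins >= 0.7 * reps

    def test_sweep_truth_recorded(self):
        vm, truth = simulate_sweep(n_haplotypes=10, L=20_000, mu=2e-6, rho=0, s=0.2, N=50, seed=3)
        assert truth["s"] == 0.2
        assert truth["attempts"] >= 1
        assert truth["final_freq"] >= 0.8

    def test_population_smaller_than_sample_rejected(self):
        with pytest.raises(ValueError):
            simulate_sweep(n_haplotypes=50, N=20)


def test_revcomp_involution():
    s = "ACGTTGCA"
    assert revcomp(revcomp(s)) == s
    assert revcomp("ACGT") == "ACGT"
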