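"""Unique k-mer catalogs, detectable groups, read classification, enrichment."""

import itertools

import numpy as np
import pandas as pd
import pytest

from paranome.kmers import (
    ParalogGroups,
    build_catalog,
    canonical,
    classify_reads,
    enrichment,
    expression_table,
    merge_groups,
)
from paranome.simulate import revcomp, simulate_family, simulate_reads, simulate_transcripts


@pytest.fixture(scope="module")
def family_catalog():
    fam = simulate_family(
        ancestor_len=6_000, n_paralogs=6, inter_div=0.03, intra_div=0.001,
        seed=41, flank=2_000, spacer=1_000,
    )
    ts = simulate_transcripts(fam)
    models = {}
    for t in ts:
        models.setdefault(t.paralog, []).append(t.cdna)
    cat = build_catalog(models, k=31)
    return fam, ts, models, cat


class TestCatalog:
    def test_canonical_strand_folding(self):
        km = "ACGTACGTACGTACGTACGTACGTACGTACG"
        assert canonical(km) == canonical(revcomp(km))

    def test_identical_models_share_every_kmer(self):
        m = {"P1": "ACGTAGGCTTACGATCGATCGGATTACCGGA" * 3}
        models = {"P1": m["P1"], "P2": m["P1"]}
        cat = build_catalog(models, k=31)
        assert all(owners == frozenset({"P1", "P2"}) for owners in cat.kmer_to_paralogs.values())
        assert cat.unique_position_count({"P1"}) == 0

    def test_background_occurrence_removes_kmer(self):
        model = "ATCGGATTACCGGATAGCATTGCAGGCTAAC" + "GGTTCAGGACCATTAGCTTGACCATTGGACA"
        genome = {"chr": "TTTT" + model[:31] + "AAAA"}  # first k-mer is background
        cat = build_catalog({"P1": model}, genome=genome, k=31)
        assert canonical(model[:31]) not in cat.kmer_to_paralogs
        assert canonical(model[5:36]) in cat.kmer_to_paralogs
        assert cat.n_background_excluded >= 1

    def test_model_loci_are_not_background(self):
        model = "ATCGGATTACCGGATAGCATTGCAGGCTAACGGTTCAGGACCATTAGCTTGACC"
        genome = {"chr": "TT" + model + "AA"}
        cat = build_catalog({"P1": model}, genome=genome, model_loci={"chr": [(2, 2 + len(model))]}, k=31)
        assert len(cat.kmer_to_paralogs) == len(model) - 30

    def test_unique_counts_match_bruteforce_enumeration(self, family_catalog):
        _, _, models, cat = family_catalog
        # independent set-algebra oracle over raw k-mer sets
        k = 31
        sets = {}
        for p, seqs in models.items():
            s = set()
            for seq in seqs:
                for i in range(len(seq) - k + 1):
                    s.add(canonical(seq[i : i + k]))
            sets[p] = s
        for p in models:
            others = set().union(*(sets[q] for q in sets if q != p))
            unique_kmers = sets[p] - others
            # position count: starts in p's models covered by p-unique k-mers
            n_pos = 0
            for seq in models[p]:
                for i in range(len(seq) - k + 1):
                    if canonical(seq[i : i + k]) in unique_kmers:
                        n_pos += 1
            assert cat.unique_position_count({p}) == n_pos

    def test_k_longer_than_model_rejected(self):
        with pytest.raises(ValueError, match="shortest"):
            build_catalog({"P1": "ACGT"}, k=31)


class TestMergeGroups:
    def test_divergent_paralogs_stay_singletons(self, family_catalog):
        _, _, _, cat = family_catalog
        groups = merge_groups(cat)
        assert all(len(g) == 1 for g in groups.groups)

    def test_identical_pair_merges(self, family_catalog):
        _, _, models, _ = family_catalog
        models2 = dict(models)
        models2["P1"] = models2["P2"]  # make P1 and P2 indistinguishable
        cat = build_catalog(models2, k=31)
        groups = merge_groups(cat)
        assert frozenset({"P1", "P2"}) in groups.groups
        assert all(v >= 5 for v in groups.unique_positions.values())

    def test_global_deficit_collapses_to_one_group(self):
        m = "ACGTAGGCTTACGATCGATCGGATTACCGGA" * 2
        cat = build_catalog({"P1": m, "P2": m, "P3": m}, k=31)
        groups = merge_groups(cat)
        assert groups.groups == [frozenset({"P1", "P2", "P3"})]

    def test_uniqueness_monotone_under_merging(self, family_catalog):
        _, _, _, cat = family_catalog
        paralogs = cat.paralogs
        for a, b in itertools.combinations(paralogs[:4], 2):
            merged = cat.unique_position_count({a, b})
            assert merged >= cat.unique_position_count({a}) + cat.unique_position_count({b})

    def test_merge_count_bounded(self, family_catalog):
        _, _, models, _ = family_catalog
        models2 = {p: models["P1"] for p in models}  # all identical
        cat = build_catalog(models2, k=31)
        groups = merge_groups(cat)
        assert len(groups.merges) <= len(models2) - 1

    def test_partition_invariant_to_input_order(self, family_catalog):
        _, _, models, _ = family_catalog
        models2 = dict(models)
        models2["P1"] = models2["P2"]
        g1 = merge_groups(build_catalog(models2, k=31))
        g2 = merge_groups(build_catalog(dict(reversed(list(models2.items()))), k=31))
        assert set(g1.groups) == set(g2.groups)


class TestClassifyReads:
    def test_error_free_reads_no_misassignment(self, family_catalog):
        fam, ts, _, cat = family_catalog
        groups = merge_groups(cat)
        profile = {"P1": 5, "P2": 1, "P3": 1, "P4": 0, "P5": 2, "P6": 1}
        reads, truth = simulate_reads(
            fam, "rna_short", depth=2, read_len=100,
            expression_profile=profile, transcripts=ts, seed=6,
        )
        rc = classify_reads(reads, groups, cat)
        t_by_read = dict(zip(truth.read, truth.paralog))
        assert all(t_by_read[r] in g.split("/") for r, g in rc.assignments.items())
        # count conservation at every stage
        t = rc.tallies
        assert sum(t.values()) == len(reads)

    def test_read_with_conflicting_unique_kmers_ambiguous(self, family_catalog):
        fam, ts, _, cat = family_catalog
        groups = merge_groups(cat)
        # chimera: half from P1 transcript, half from P3 transcript
        t1 = next(t for t in ts if t.paralog == "P1")
        t3 = next(t for t in ts if t.paralog == "P3")
        chimera = t1.cdna[:120] + t3.cdna[:120]
        rc = classify_reads({"chi": chimera}, groups, cat)
        assert rc.ambiguous == ["chi"]

    def test_non_family_read(self, family_catalog):
        _, _, _, cat = family_catalog
        groups = merge_groups(cat)
        rc = classify_reads({"r": "A" * 100}, groups, cat)
        assert rc.non_family == ["r"]

    def test_recovered_proportions_match_profile(self, family_catalog):
        fam, ts, _, cat = family_catalog
        groups = merge_groups(cat)
        profile = {"P1": 4.0, "P2": 1.0}
        reads, truth = simulate_reads(
            fam, "rna_short", depth=4, read_len=100,
            expression_profile=profile, transcripts=ts, seed=7,
        )
        rc = classify_reads(reads, groups, cat)
        counts = pd.Series(list(rc.assignments.values())).value_counts()
        # transcripts have equal length: expect reads 4:1 within binomial CI
        n = counts.get("P1", 0) + counts.get("P2", 0)
        phat = counts.get("P1", 0) / n
        se = np.sqrt(0.8 * 0.2 / n)
        assert abs(phat - 0.8) < 3 * se


class TestEnrichment:
    def _counts(self):
        return pd.DataFrame(
            {"sA1": [10, 10], "sA2": [12, 12], "sB1": [10, 10], "sB2": [8, 8]},
            index=["G1", "G2"],
        )

    def test_identical_proportions_zero_z(self):
        counts = self._counts()
        meta = {"sA1": "brain", "sA2": "brain", "sB1": "testis", "sB2": "testis"}
        enr = enrichment(counts, meta, n_perm=50, seed=1)
        assert (enr.z.abs() < 1e-12).all()

    def test_doubled_tissue_positive_z(self):
        counts = pd.DataFrame(
            {f"s{i}": [20 if i == 0 else 10, 10] for i in range(10)},
            index=["G1", "G2"],
        )
        meta = {f"s{i}": f"t{i}" for i in range(10)}
        enr = enrichment(counts, meta, n_perm=100, seed=2)
        g1 = enr[enr.group == "G1"].set_index("tissue")
        assert g1.loc["t0", "z"] > 0
        assert (g1.drop("t0").z < 0).all()

    def test_null_permutation_p_uniform(self, rng):
        # label shuffling of null data: p-values approximately uniform
        # (one independent draw per replicate: a fixed group/tissue cell)
        from scipy.stats import kstest

        pvals = []
        for rep in range(40):
            counts = pd.DataFrame(
                rng.poisson(50, size=(2, 12)), index=["G1", "G2"],
                columns=[f"s{i}" for i in range(12)],
            )
            meta = {f"s{i}": f"t{i % 4}" for i in range(12)}
            enr = enrichment(counts, meta, n_perm=400, seed=rep)
            cell = enr[(enr.group == "G1") & (enr.tissue == "t0")]
            pvals.append(float(cell.p_perm.iloc[0]))
        stat = kstest(pvals, "uniform")
        assert stat.pvalue > 0.01

    def test_single_tissue_rejected(self):
        counts = self._counts()
        with pytest.raises(ValueError):
            enrichment(counts, {c: "brain" for c in counts.columns})

    def test_single_sample_tissue_unreliable(self):
        counts = self._counts()
        meta = {"sA1": "brain", "sA2": "brain", "sB1": "testis", "sB2": "liver"}
        enr = enrichment(counts, meta, n_perm=20, seed=3)
        assert not enr[enr.tissue == "liver"].reliable.any()
        assert enr[enr.tissue == "brain"].reliable.all()


def test_expression_table_column_sums_match_assignments(family_catalog):
    fam, ts, _, cat = family_catalog
    groups = merge_groups(cat)
    reads, truth = simulate_reads(
        fam, "rna_short", depth=1, read_len=100, transcripts=ts, seed=9,
    )
    rc = classify_reads(reads, groups, cat)
    read_sample = {r: ("s1" if i % 2 else "s2") for i, r in enumerate(rc.assignments)}
    tab = expression_table(rc, read_sample, groups)
    assert int(tab.values.sum()) == len(rc.assignments)
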