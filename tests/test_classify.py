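"""Paralog assignment by supported clades; copy-number tables."""

import numpy as np
import pytest

from paranome.classify import assign_clades, copy_table, distance_nj, p_distance_matrix
from paranome.io import parse_newick
from paranome.simulate import _mutate, simulate_family


def _family_leaves(fam):
    seqs, truth, anchors = {}, {}, {}
    for hap in fam.haplotype_ids:
        for i, c in enumerate(fam.copies(hap)):
            cid = f"{hap}_c{i}"
            seqs[cid] = c.allele_seq
            truth[cid] = c.paralog
    for p, s in fam.paralog_seqs.items():
        seqs[f"anchor_{p}"] = s
        anchors[f"anchor_{p}"] = p
    rng = np.random.default_rng(9)
    seqs["OUT"] = _mutate(rng, fam.ancestor_seq, 0.15)
    return seqs, truth, anchors


class TestDistanceNJ:
    def test_recovers_additive_topology(self):
        # 4 taxa with additive distances: ((A,B),(C,D))
        base = "A" * 400
        rng = np.random.default_rng(2)
        root_ab = _mutate(rng, base, 0.10)
        root_cd = _mutate(rng, base, 0.10)
        seqs = {
            "A": _mutate(rng, root_ab, 0.01),
            "B": _mutate(rng, root_ab, 0.01),
            "C": _mutate(rng, root_cd, 0.01),
            "D": _mutate(rng, root_cd, 0.01),
        }
        tree = distance_nj(seqs)
        # unrooted 4-taxon tree: the AB|CD split must be present
        tipsets = {frozenset(t.name for t in n.tips()) for n in tree.non_tips()}
        assert frozenset({"A", "B"}) in tipsets or frozenset({"C", "D"}) in tipsets

    def test_identical_sequences_zero_distances(self):
        seqs = {"A": "ACGT" * 50, "B": "ACGT" * 50, "C": "ACGT" * 50}
        dm = p_distance_matrix(seqs)
        assert not dm.data.any()
        tree = distance_nj(seqs)
        assert {t.name for t in tree.tips()} == {"A", "B", "C"}

    def test_input_order_invariance(self):
        rng = np.random.default_rng(3)
        base = rng.choice(list("ACGT"), 300)
        seqs = {f"t{i}": _mutate(np.random.default_rng(i), "".join(base), 0.05) for i in range(6)}
        t1 = distance_nj(seqs)
        t2 = distance_nj(dict(reversed(list(seqs.items()))))
        assert t1.compare_rfd(t2) == 0

    def test_gappy_columns_dropped(self):
        seqs = {"A": "AC-T", "B": "AC-T", "C": "GC-A"}
        dm = p_distance_matrix(seqs)
        assert dm["A", "C"] == pytest.approx(2 / 3)

    def test_fewer_than_three_rejected(self):
        with pytest.raises(ValueError):
            distance_nj({"A": "ACGT", "B": "ACGT"})


class TestAssignClades:
    def test_all_copies_named_by_true_paralog(self, small_family):
        seqs, truth, anchors = _family_leaves(small_family)
        asn = assign_clades(distance_nj(seqs), anchors, outgroup="OUT")
        assert all(asn.names[c] == truth[c] for c in truth)

    def test_merged_name_for_unseparated_anchors(self):
        t = parse_newick(
            "(((B12A:0.001,(c1:0.001,B13A:0.001)60:0.0005)95:0.01,"
            "(c2:0.001,A5A:0.001)99:0.01)90:0.02,OUT:0.1);"
        )
        asn = assign_clades(t, {"B12A": "B12", "B13A": "B13", "A5A": "A5"}, outgroup="OUT")
        assert asn.names["c1"] == "B12/B13"
        assert asn.names["c2"] == "A5"
        assert "B12/B13" in asn.merged_names

    def test_novel_clade_named_after_nearest_anchor(self):
        t = parse_newick(
            "(((A1A:0.001,c1:0.001)99:0.02,(n1:0.001,n2:0.001)99:0.02)95:0.03,"
            "(B2A:0.001,c3:0.002)99:0.04,OUT:0.2);"
        )
        asn = assign_clades(t, {"A1A": "A1", "B2A": "B2"}, outgroup="OUT")
        assert asn.names["n1"] == asn.names["n2"] == "A1L1"
        assert asn.novel_clades["A1L1"] == ["n1", "n2"]
        assert asn.names["c1"] == "A1"

    def test_novel_paralog_in_simulated_family(self, small_family):
        seqs, truth, anchors = _family_leaves(small_family)
        # drop one anchor: its copies form a supported anchor-free clade
        del seqs["anchor_P6"]
        anchors = {k: v for k, v in anchors.items() if v != "P6"}
        asn = assign_clades(distance_nj(seqs), anchors, outgroup="OUT")
        p6_names = {asn.names[c] for c in truth if truth[c] == "P6"}
        assert len(p6_names) == 1
        assert next(iter(p6_names)).endswith("L1")
        others = [c for c in truth if truth[c] != "P6"]
        assert all(asn.names[c] == truth[c] for c in others)

    def test_low_support_coarsens_names(self):
        # the internal split separating the anchors is below threshold
        t = parse_newick("(((X1:0.01,c1:0.01)50:0.01,X2:0.02)95:0.05,OUT:0.3);")
        asn = assign_clades(t, {"X1": "A", "X2": "B"}, outgroup="OUT", support_min=75)
        assert asn.names["c1"] == "A/B"
        asn_low = assign_clades(t, {"X1": "A", "X2": "B"}, outgroup="OUT", support_min=40)
        assert asn_low.names["c1"] == "A"

    def test_raising_support_coarsens_each_copy(self, small_family):
        # each copy's anchor-name set only grows as the threshold rises,
        # and above every support value a single merged name remains
        seqs, truth, anchors = _family_leaves(small_family)
        tree = distance_nj(seqs)
        rng = np.random.default_rng(5)
        for node in tree.non_tips():
            node.support = float(rng.integers(40, 101))
        prev: dict[str, set] = {}
        for smin in (0, 50, 75, 90):
            asn = assign_clades(tree, anchors, outgroup="OUT", support_min=smin)
            cur = {c: set(n.split("/")) for c, n in asn.names.items() if "L" not in n and n != "unassigned"}
            for c, nameset in cur.items():
                if c in prev:
                    assert nameset >= prev[c]
            prev = cur
        top = assign_clades(tree, anchors, outgroup="OUT", support_min=101)
        assert len(set(top.names.values())) == 1

    def test_missing_anchor_leaf_rejected(self, small_family):
        seqs, _, anchors = _family_leaves(small_family)
        anchors["ghost"] = "PX"
        with pytest.raises(ValueError, match="anchor"):
            assign_clades(distance_nj(seqs), anchors, outgroup="OUT")


class TestCopyTable:
    def _build(self, cn_pairs, paralog="P1"):
        assignments, copy_hap, samples = {}, {}, {}
        k = 0
        for i, (a, b) in enumerate(cn_pairs):
            s = f"s{i}"
            samples[s] = (f"{s}_h1", f"{s}_h2")
            for j, n in enumerate((a, b)):
                for _ in range(n):
                    assignments[f"cp{k}"] = paralog
                    copy_hap[f"cp{k}"] = f"{s}_h{j + 1}"
                    k += 1
        return assignments, copy_hap, samples

    def test_heterozygosity_one_of_four_discordant(self):
        asn, ch, samples = self._build([(2, 2), (2, 3), (3, 3), (2, 2)])
        tab = copy_table(asn, ch, samples)
        assert tab.heterozygosity["P1"] == 0.25

    def test_all_concordant_zero(self):
        asn, ch, samples = self._build([(1, 1), (1, 1), (1, 1)])
        tab = copy_table(asn, ch, samples)
        assert tab.heterozygosity["P1"] == 0.0

    def test_heterozygosity_bounds(self):
        asn, ch, samples = self._build([(0, 3), (1, 2), (2, 1)])
        tab = copy_table(asn, ch, samples)
        assert 0.0 <= tab.heterozygosity["P1"] <= 1.0
        assert tab.heterozygosity["P1"] == 1.0

    def test_half_validated_sample_excluded_from_denominator(self):
        asn, ch, samples = self._build([(2, 2), (2, 3)])
        validated = {"s0_h1": True, "s0_h2": True, "s1_h1": True, "s1_h2": False}
        tab = copy_table(asn, ch, samples, validated=validated)
        assert tab.heterozygosity["P1"] == 0.0  # only s0 counted
        assert set(tab.cn.haplotype) == {"s0_h1", "s0_h2", "s1_h1"}

    def test_planted_truth_recovered(self, small_family):
        fam = small_family
        assignments, copy_hap = {}, {}
        for hap in fam.haplotype_ids:
            for i, c in enumerate(fam.copies(hap)):
                cid = f"{hap}_c{i}"
                assignments[cid] = c.paralog
                copy_hap[cid] = hap
        tab = copy_table(assignments, copy_hap, fam.samples)
        truth = fam.planted_cn()
        merged = tab.cn.merge(truth, on=["sample", "haplotype", "paralog"], suffixes=("", "_true"))
        assert (merged.cn == merged.cn_true).all()
        assert all(v == 0.0 for v in tab.heterozygosity.values())
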