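"""Phylogenetic paralog assignment and copy-number/heterozygosity tables.

Copies are named by membership in supported monophyletic clades anchored
by reference copies of known paralogs.  Where the reference anchors for
two paralogs cannot be separated by a supported split, copies get the
merged name ("B12/B13"-style); well-separated supported clades without
any anchor are treated as novel paralogs and named after their nearest
anchor with an "L" suffix and ordinal ("A1L1"-style).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

logger = logging.getLogger("paranome")

GAP_CHARS = set("-.")


# ---------------------------------------------------------------------------
# distance NJ fallback
# ---------------------------------------------------------------------------


def p_distance_matrix(seqs: Mapping[str, str], max_gap_frac: float = 0.5) -> DistanceMatrix:
    """Pairwise p-distances over columns with <= ``max_gap_frac`` gaps."""
    names = sorted(seqs)
    arrs = [np.frombuffer(seqs[n].upper().encode(), dtype=np.uint8) for n in names]
    lengths = {a.size for a in arrs}
    if len(lengths) != 1:
        raise ValueError("sequences must be aligned (equal length)")
    mat = np.vstack(arrs)
    gap = (mat == ord("-")) | (mat == ord("."))
    keep = gap.mean(axis=0) <= max_gap_frac
    mat = mat[:, keep]
    gap = gap[:, keep]
    n = len(names)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(gap[i] | gap[j])
            ncmp = int(ok.sum())
            d = float((mat[i, ok] != mat[j, ok]).sum() / ncmp) if ncmp else 0.0
            dm[i, j] = dm[j, i] = d
    return DistanceMatrix(dm, ids=names)


def distance_nj(seqs: Mapping[str, str]) -> TreeNode:
    """Neighbor-joining tree from p-distances of an aligned sequence set.

    Fallback when no externally inferred tree is supplied; the tree
    carries no support values (clade logic then trusts every split).
    Negative NJ branch lengths are clamped to 0.
    """
    if len(seqs) < 3:
        raise ValueError("need at least 3 sequences for NJ")
    tree = nj(p_distance_matrix(seqs))
    for node in tree.traverse(include_self=True):
        if node.length is not None and node.length < 0:
            node.length = 0.0
        if not node.is_tip():
            node.support = None
    return tree


# ---------------------------------------------------------------------------
# clade assignment
# ---------------------------------------------------------------------------


@dataclass
class ParalogAssignment:
    """copy -> clade-name mapping plus the clades that produced the names."""

    names: dict[str, str]
    supports: dict[str, float | None] = field(default_factory=dict)
    novel_clades: dict[str, list[str]] = field(default_factory=dict)
    merged_names: list[str] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "copy_id": list(self.names),
                "clade": [self.names[c] for c in self.names],
                "support": [self.supports.get(c) for c in self.names],
            }
        )


def _supported(node: TreeNode, support_min: float) -> bool:
    sup = getattr(node, "support", None)
    return sup is None or sup > support_min


def _natural_key(name: str):
    import re

    return [int(p) if p.isdigit() else p for p in re.split(r"(\d+)", name)]


def assign_clades(
    tree: TreeNode,
    anchors: Mapping[str, str],
    outgroup: str | None = None,
    support_min: float = 75.0,
    novel_min_dist: float | None = None,
) -> ParalogAssignment:
    """Assign every non-anchor leaf to a paralog name via supported clades.

    ``anchors`` maps anchor leaf labels to paralog names.  The tree is
    rooted at ``outgroup`` when given.  A copy is named by the smallest
    supported clade containing it that holds anchors: one anchor name
    gives that name; several give the merged "X/Y" name.  A supported
    anchor-free clade of two or more copies whose patristic distance to
    every anchor exceeds ``novel_min_dist`` (default: half the smallest
    inter-anchor distance, i.e. paralog-level divergence) becomes a novel
    paralog named after the nearest anchor with an "L" ordinal.  Missing
    support values are treated as supported.
    """
    work = tree.copy()
    if outgroup is not None:
        og = work.find(outgroup)
        # root above the outgroup but keep it: pruning would collapse the
        # ingroup's root clade and lose its support value
        work = work.root_at(og, above=True, branch_attrs=["support"])
    skip = {outgroup} if outgroup is not None else set()
    missing = [a for a in anchors if a not in {t.name for t in work.tips()}]
    if missing:
        raise ValueError(f"anchor leaves not in tree: {missing}")

    # patristic distances from each node's tips to anchors
    tipdist = work.tip_tip_distances()
    anchor_ids = [a for a in anchors]
    copy_ids = [t.name for t in work.tips() if t.name not in anchors and t.name not in skip]
    if novel_min_dist is None:
        # novel = paralog-level divergence from every anchor: well above the
        # allele-level copy-to-anchor distances, with an inter-anchor floor
        if len(anchor_ids) >= 2 and copy_ids:
            nearest = [
                min(tipdist[c, a] for a in anchor_ids) for c in copy_ids
            ]
            inter = min(
                tipdist[a, b] for a, b in itertools.combinations(anchor_ids, 2)
            )
            novel_min_dist = max(4.0 * float(np.percentile(nearest, 25)), 0.25 * inter)
        else:
            novel_min_dist = float("inf")

    def anchors_under(node) -> set[str]:
        return {anchors[t.name] for t in node.tips() if t.name in anchors}

    def min_anchor_dist(node) -> float:
        tips = [t.name for t in node.tips() if t.name not in anchors and t.name not in skip]
        if not tips or not anchor_ids:
            return float("inf")
        return min(tipdist[t, a] for t in tips for a in anchor_ids)

    def nearest_anchor_name(node) -> str:
        tips = [t.name for t in node.tips() if t.name not in anchors and t.name not in skip]
        best = min(
            ((tipdist[t, a], a) for t in tips for a in anchor_ids),
            key=lambda x: x[0],
        )
        return anchors[best[1]]

    names: dict[str, str] = {}
    supports: dict[str, float | None] = {}
    novel_clades: dict[str, list[str]] = {}
    merged_names: set[str] = set()
    novel_counter: dict[str, int] = {}

    def supported_subclades_and_leaves(node):
        """Maximal supported proper subclades, and leaves not inside any."""
        clades, leaves = [], []

        def descend(child):
            if child.is_tip():
                leaves.append(child)
            elif _supported(child, support_min):
                clades.append(child)
            else:
                for gc in child.children:
                    descend(gc)

        for child in node.children:
            descend(child)
        return clades, leaves

    def name_all(node, label, support):
        for t in node.tips():
            if t.name not in anchors and t.name not in skip:
                names[t.name] = label
                supports[t.name] = support

    def handle_anchor_free(node, context_label, support):
        """Novel clade if far from every anchor, else fall back to context."""
        copies = [t.name for t in node.tips() if t.name not in anchors and t.name not in skip]
        if len(copies) >= 2 and min_anchor_dist(node) > novel_min_dist:
            base = nearest_anchor_name(node)
            novel_counter[base] = novel_counter.get(base, 0) + 1
            label = f"{base}L{novel_counter[base]}"
            novel_clades[label] = copies
            name_all(node, label, getattr(node, "support", None))
        else:
            name_all(node, context_label, support)

    def assign(node, is_root: bool):
        A = sorted(anchors_under(node), key=_natural_key)
        support = getattr(node, "support", None)
        if len(A) == 1:
            clades, leaves = supported_subclades_and_leaves(node)
            for leaf in leaves:
                if leaf.name not in anchors and leaf.name not in skip:
                    names[leaf.name] = A[0]
                    supports[leaf.name] = support
            for sub in clades:
                if anchors_under(sub):
                    assign(sub, False)
                else:
                    handle_anchor_free(sub, A[0], support)
            return
        merged = "/".join(A)
        clades, leaves = supported_subclades_and_leaves(node)
        sub_with_anchor = [s for s in clades if anchors_under(s)]
        for leaf in leaves:
            if leaf.name not in anchors and leaf.name not in skip:
                if is_root:
                    names[leaf.name] = "unassigned"
                    supports[leaf.name] = None
                    logger.warning("copy %s outside all supported clades", leaf.name)
                else:
                    names[leaf.name] = merged
                    supports[leaf.name] = support
                    merged_names.add(merged)
        for sub in clades:
            if anchors_under(sub):
                assign(sub, False)
            else:
                handle_anchor_free(sub, "unassigned" if is_root else merged, support)
        if not is_root and not sub_with_anchor and len(A) > 1:
            merged_names.add(merged)

    assign(work, True)
    # ensure every copy got exactly one name
    for t in work.tips():
        if t.name not in anchors and t.name not in skip and t.name not in names:
            names[t.name] = "unassigned"
            supports[t.name] = None
    return ParalogAssignment(
        names=names,
        supports=supports,
        novel_clades=novel_clades,
        merged_names=sorted(merged_names),
    )


# ---------------------------------------------------------------------------
# copy-number table
# ---------------------------------------------------------------------------


@dataclass
class CopyNumberTable:
    cn: pd.DataFrame  # columns: sample, haplotype, paralog, cn
    heterozygosity: dict[str, float]

    def matrix(self) -> pd.DataFrame:
        return self.cn.pivot_table(
            index="paralog", columns="haplotype", values="cn", fill_value=0
        )


def copy_table(
    assignments: Mapping[str, str],
    copy_haplotype: Mapping[str, str],
    samples: Mapping[str, Sequence[str]],
    validated: Mapping[str, bool] | None = None,
) -> CopyNumberTable:
    """Integer copy number per (sample, haplotype, paralog) and heterozygosity.

    Copy-number heterozygosity of a paralog is the fraction of samples
    whose two haplotypes carry discordant integer copy numbers, over the
    samples with both haplotypes validated; samples with a single
    validated haplotype are excluded from the denominator (logged).
    """
    validated = validated or {}
    paralogs = sorted({v for v in assignments.values() if v != "unassigned"}, key=_natural_key)
    rows = []
    counts: dict[tuple[str, str], dict[str, int]] = {}
    for sample, haps in samples.items():
        for hap in haps:
            counts[(sample, hap)] = {p: 0 for p in paralogs}
    for copy_id, name in assignments.items():
        if name == "unassigned":
            continue
        hap = copy_haplotype[copy_id]
        for sample, haps in samples.items():
            if hap in haps:
                counts[(sample, hap)][name] += 1
    for (sample, hap), cn in counts.items():
        if not validated.get(hap, True):
            continue
        for p, n in cn.items():
            rows.append({"sample": sample, "haplotype": hap, "paralog": p, "cn": n})
    cn_df = pd.DataFrame(rows, columns=["sample", "haplotype", "paralog", "cn"])

    het: dict[str, float] = {}
    full_samples = []
    for sample, haps in samples.items():
        ok = [h for h in haps if validated.get(h, True)]
        if len(ok) == 2:
            full_samples.append((sample, ok))
        elif len(ok) == 1:
            logger.info("sample %s has one validated haplotype; excluded from heterozygosity", sample)
    for p in paralogs:
        if not full_samples:
            het[p] = float("nan")
            continue
        disc = 0
        for sample, (h1, h2) in full_samples:
            if counts[(sample, h1)][p] != counts[(sample, h2)][p]:
                disc += 1
        het[p] = disc / len(full_samples)
    return CopyNumberTable(cn=cn_df, heterozygosity=het)
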