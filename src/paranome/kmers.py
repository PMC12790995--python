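"""Unique k-mer catalogs, detectable paralog groups, and expression tables.

Short RNA-seq reads cannot be aligned uniquely within a high-identity
gene family, but k-mers private to one paralog's gene models (and absent
from the rest of the genome) can tag reads.  Paralogs with too few
uniquely identifying k-mer positions are iteratively merged into
detectable groups; reads are classified by group-unique k-mer content
and summarized into per-tissue enrichment Z scores with permutation
p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("paranome")

_COMP = str.maketrans("ACGT", "TGCA")


def canonical(kmer: str) -> str:
    rc = kmer.translate(_COMP)[::-1]
    return min(kmer, rc)


# ---------------------------------------------------------------------------
# catalog
# ---------------------------------------------------------------------------


@dataclass
class KmerCatalog:
    k: int
    kmer_to_paralogs: dict[str, frozenset[str]]
    models: dict[str, list[str]]  # paralog -> model sequences
    n_background_excluded: int = 0

    @property
    def paralogs(self) -> list[str]:
        return sorted(self.models)

    def unique_position_count(self, group: frozenset[str] | set[str]) -> int:
        """Number of k-mer start positions in the group's models covered by
        k-mers whose paralog set lies within the group."""
        group = frozenset(group)
        n = 0
        for paralog in group:
            for seq in self.models[paralog]:
                for i in range(len(seq) - self.k + 1):
                    owners = self.kmer_to_paralogs.get(canonical(seq[i : i + self.k]))
                    if owners is not None and owners <= group:
                        n += 1
        return n

    def shared_kmers(self, g1: frozenset[str], g2: frozenset[str]) -> int:
        return sum(
            1
            for owners in self.kmer_to_paralogs.values()
            if owners & g1 and owners & g2
        )


def build_catalog(
    models: Mapping[str, Sequence[str] | str],
    genome: Mapping[str, str] | None = None,
    model_loci: Mapping[str, Sequence[tuple[int, int]]] | None = None,
    k: int = 31,
) -> KmerCatalog:
    """All model k-mers absent from the rest of the genome.

    ``models`` maps paralog -> gene-model sequence(s).  ``genome`` with
    ``model_loci`` (intervals per contig housing the gene models, which
    are not background) defines the background: any catalog candidate
    also present in the background is removed.  K-mers are canonicalized
    (lexicographic min of the strand pair).
    """
    norm: dict[str, list[str]] = {
        p: [s] if isinstance(s, str) else list(s) for p, s in models.items()
    }
    shortest = min(len(s) for seqs in norm.values() for s in seqs)
    if k > shortest:
        raise ValueError(f"k={k} exceeds the shortest gene model ({shortest} bp)")
    cat: dict[str, set[str]] = {}
    for paralog, seqs in norm.items():
        for seq in seqs:
            seq = seq.upper()
            for i in range(len(seq) - k + 1):
                cat.setdefault(canonical(seq[i : i + k]), set()).add(paralog)
    n_excluded = 0
    if genome:
        model_loci = model_loci or {}
        for contig, seq in genome.items():
            seq = seq.upper()
            loci = sorted(model_loci.get(contig, ()))
            for i in range(len(seq) - k + 1):
                # k-mers entirely inside a model locus are self-matches
                if any(s <= i and i + k <= e for s, e in loci):
                    continue
                km = canonical(seq[i : i + k])
                if km in cat:
                    del cat[km]
                    n_excluded += 1
    if n_excluded:
        logger.info("build_catalog: %d k-mers removed by background exclusion", n_excluded)
    return KmerCatalog(
        k=k,
        kmer_to_paralogs={km: frozenset(p) for km, p in cat.items()},
        models=norm,
        n_background_excluded=n_excluded,
    )


# ---------------------------------------------------------------------------
# detectable paralog groups
# ---------------------------------------------------------------------------


@dataclass
class ParalogGroups:
    groups: list[frozenset[str]]
    unique_positions: dict[frozenset[str], int]
    merges: list[tuple[str, str]] = field(default_factory=list)

    def group_of(self, paralog: str) -> frozenset[str]:
        for g in self.groups:
            if paralog in g:
                return g
        raise KeyError(paralog)

    @staticmethod
    def name(group: frozenset[str]) -> str:
        return "/".join(sorted(group))


def merge_groups(catalog: KmerCatalog, min_positions: int = 5) -> ParalogGroups:
    """Iteratively merge paralogs into detectable groups.

    Starting from singletons, any group with fewer than ``min_positions``
    group-unique k-mer positions is merged with the group sharing the
    most catalog k-mers with it (ties broken lexicographically);
    uniqueness is recomputed at group level after every merge.  If even
    the full union is deficient, a single all-paralog group is returned
    with a warning.
    """
    groups = [frozenset([p]) for p in catalog.paralogs]
    merges: list[tuple[str, str]] = []
    while True:
        counts = {g: catalog.unique_position_count(g) for g in groups}
        deficient = sorted(
            (g for g in groups if counts[g] < min_positions),
            key=lambda g: (counts[g], ParalogGroups.name(g)),
        )
        if not deficient or len(groups) == 1:
            break
        g = deficient[0]
        partners = [h for h in groups if h != g]
        best = max(
            partners,
            key=lambda h: (catalog.shared_kmers(g, h), ParalogGroups.name(h)),
        )
        merges.append((ParalogGroups.name(g), ParalogGroups.name(best)))
        logger.info("merge_groups: %s + %s", ParalogGroups.name(g), ParalogGroups.name(best))
        groups = [h for h in groups if h not in (g, best)] + [g | best]
    counts = {g: catalog.unique_position_count(g) for g in groups}
    if len(groups) == 1 and counts[groups[0]] < min_positions:
        logger.warning("merge_groups: global deficit of unique k-mer positions")
    return ParalogGroups(groups=sorted(groups, key=ParalogGroups.name), unique_positions=counts, merges=merges)


# ---------------------------------------------------------------------------
# read classification
# ---------------------------------------------------------------------------


@dataclass
class ReadClassification:
    assignments: dict[str, str]  # read -> group name (assigned reads only)
    ambiguous: list[str]
    unresolved: list[str]
    non_family: list[str]

    @property
    def tallies(self) -> dict[str, int]:
        return {
            "assigned": len(self.assignments),
            "ambiguous": len(self.ambiguous),
            "unresolved": len(self.unresolved),
            "non_family": len(self.non_family),
        }


def classify_reads(
    reads: Mapping[str, str], groups: ParalogGroups, catalog: KmerCatalog
) -> ReadClassification:
    """Assign reads by exclusive group-unique k-mer content.

    A read is assigned to a group when it contains at least one k-mer
    unique to that group and none unique to any other group; reads with
    unique k-mers of several groups are ambiguous, reads with only
    non-identifying family k-mers are unresolved, and reads with no
    catalog k-mer at all are non-family.
    """
    group_by_paralog: dict[str, frozenset[str]] = {}
    for g in groups.groups:
        for p in g:
            group_by_paralog[p] = g
    k = catalog.k
    assignments: dict[str, str] = {}
    ambiguous, unresolved, non_family = [], [], []
    for rid, seq in reads.items():
        seq = seq.upper()
        hit_groups: set[frozenset[str]] = set()
        any_catalog = False
        for i in range(len(seq) - k + 1):
            owners = catalog.kmer_to_paralogs.get(canonical(seq[i : i + k]))
            if owners is None:
                continue
            any_catalog = True
            containing = {group_by_paralog[p] for p in owners}
            if len(containing) == 1:
                g = next(iter(containing))
                if owners <= g:
                    hit_groups.add(g)
        if len(seq) < k or not any_catalog:
            non_family.append(rid)
        elif len(hit_groups) == 1:
            assignments[rid] = ParalogGroups.name(next(iter(hit_groups)))
        elif len(hit_groups) > 1:
            ambiguous.append(rid)
        else:
            unresolved.append(rid)
    return ReadClassification(assignments, ambiguous, unresolved, non_family)


def expression_table(
    classification: ReadClassification,
    read_to_sample: Mapping[str, str],
    groups: ParalogGroups,
) -> pd.DataFrame:
    """Raw group x sample read counts plus counts per million classified."""
    samples = sorted(set(read_to_sample.values()))
    names = [ParalogGroups.name(g) for g in groups.groups]
    raw = pd.DataFrame(0, index=names, columns=samples, dtype=int)
    for rid, gname in classification.assignments.items():
        raw.loc[gname, read_to_sample[rid]] += 1
    return raw


# ---------------------------------------------------------------------------
# tissue enrichment
# ---------------------------------------------------------------------------


def enrichment(
    counts: pd.DataFrame,
    sample_to_tissue: Mapping[str, str],
    n_perm: int = 1_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-(group, tissue) enrichment Z and permutation p.

    For each group, its proportion of classified family reads is computed
    per tissue; Z standardizes that proportion against the across-tissue
    mean and SD.  p-values come from permuting tissue labels over
    samples (one-sided, positive enrichment); tissues with a single
    sample are flagged unreliable.
    """
    tissues = sorted(set(sample_to_tissue.values()))
    if len(tissues) < 2:
        raise ValueError("need at least two tissues for enrichment")
    rng = np.random.default_rng(seed)
    samples = list(counts.columns)
    labels = np.array([sample_to_tissue[s] for s in samples])
    mat = counts.values.astype(float)

    def z_scores(lab: np.ndarray) -> np.ndarray:
        props = np.zeros((mat.shape[0], len(tissues)))
        for ti, t in enumerate(tissues):
            cols = mat[:, lab == t]
            tot = cols.sum()
            props[:, ti] = cols.sum(axis=1) / tot if tot > 0 else 0.0
        mu = props.mean(axis=1, keepdims=True)
        sd = props.std(axis=1, ddof=0, keepdims=True)
        sd[sd == 0] = 1.0
        return (props - mu) / sd

    z_obs = z_scores(labels)
    exceed = np.ones_like(z_obs)
    for _ in range(n_perm):
        perm = labels.copy()
        rng.shuffle(perm)
        exceed += z_scores(perm) >= z_obs
    pvals = exceed / (n_perm + 1)
    n_per_tissue = {t: int((labels == t).sum()) for t in tissues}
    rows = []
    for gi, gname in enumerate(counts.index):
        if mat[gi].sum() == 0:
            continue
        for ti, t in enumerate(tissues):
            rows.append(
                {
                    "group": gname,
                    "tissue": t,
                    "z": z_obs[gi, ti],
                    "p_perm": pvals[gi, ti],
                    "reliable": n_per_tissue[t] > 1,
                }
            )
    return pd.DataFrame(rows)
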