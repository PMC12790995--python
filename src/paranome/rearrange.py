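"""Signed-gene-order encoding of locus structures and DCJ-indel distances.

A locus configuration is the ordered, oriented list of gene-family
paralogs and unique marker genes on one haplotype.  The distance between
two configurations is the minimum number of double-cut-and-join (DCJ)
operations plus insertions/deletions of contiguous runs of
genome-unique content transforming one linear sequence into the other,
computed on the adjacency graph of the two sequences over their shared
markers with run-length-based indel accounting.  Marker names occurring
twice are resolved by exhaustive matching, taking the minimum.
"""

from __future__ import annotations

import itertools
import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .io import GeneRecord

logger = logging.getLogger("paranome")

D_MAX = 2  # maximum per-name multiplicity the matching model handles

Symbol = tuple[str, str]  # (name, orientation in {+,-})


@dataclass
class Configuration:
    """Signed symbol encoding of one locus structure."""

    locus_id: str
    symbols: tuple[Symbol, ...]
    haplotypes: tuple[str, ...] = ()
    frequency: float = 0.0

    def __post_init__(self) -> None:
        self.symbols = tuple((str(n), o) for n, o in self.symbols)
        for _, o in self.symbols:
            if o not in "+-":
                raise ValueError("orientation must be + or -")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.symbols)

    def reversed(self) -> "Configuration":
        sym = tuple((n, "-" if o == "+" else "+") for n, o in reversed(self.symbols))
        return Configuration(self.locus_id, sym, self.haplotypes, self.frequency)


def encode_configuration(
    genes: Sequence[GeneRecord],
    markers: Iterable[str],
    locus_id: str = "locus",
    haplotype: str | None = None,
) -> Configuration:
    """Encode one haplotype locus as ordered, oriented symbols.

    Family genes and the named marker genes are kept in coordinate order;
    anything else is dropped.  A locus without family genes is returned
    as an (empty-configuration) warning state, not an error.
    """
    markers = set(markers)
    rows = sorted(genes, key=lambda g: (g.start, g.end))
    symbols = []
    for g in rows:
        if g.gene_class == "family_gene" or (g.gene_class == "marker_gene" and g.name in markers):
            symbols.append((g.name, g.strand))
    if not any(True for g in rows if g.gene_class == "family_gene"):
        logger.warning("locus %s has no family genes: empty-configuration state", locus_id)
    return Configuration(
        locus_id, tuple(symbols), (haplotype,) if haplotype else (), 0.0
    )


# ---------------------------------------------------------------------------
# DCJ-indel distance
# ---------------------------------------------------------------------------


def _signed(symbols: Sequence[Symbol]) -> list[tuple[str, int]]:
    return [(n, 1 if o == "+" else -1) for n, o in symbols]


def _distance_relabelled(a: list[int], b: list[int]) -> int:
    """DCJ-indel distance for two linear sequences of signed integers with
    no duplicate magnitudes.  Magnitudes present in one sequence only are
    genome-unique content handled by run-based indel accounting."""
    set_a = {abs(x) for x in a}
    set_b = {abs(x) for x in b}
    shared = set_a & set_b
    if not shared:
        return (1 if a else 0) + (1 if b else 0)

    def reduce(seq: list[int]):
        """Vertices of the adjacency walk: (left_ext, right_ext, label).

        Vertex i sits between shared markers i and i+1; telomere vertices
        have one extremity.  The label records whether unique content
        lies on that adjacency."""
        kept = [x for x in seq if abs(x) in shared]
        labels = []
        run = False
        runs_between: list[bool] = []
        j = 0
        gap_has_content = [False] * (len(kept) + 1)
        gi = 0
        for x in seq:
            if abs(x) in shared:
                gi += 1
            else:
                gap_has_content[gi] = True
        verts = []
        for i in range(len(kept) + 1):
            left = None
            right = None
            if i > 0:
                m = kept[i - 1]
                left = (abs(m), "h" if m > 0 else "t")  # outgoing end of marker i-1
            if i < len(kept):
                m = kept[i]
                right = (abs(m), "t" if m > 0 else "h")  # incoming end of marker i
            verts.append({"exts": tuple(e for e in (left, right) if e), "label": gap_has_content[i]})
        return kept, verts

    kept_a, va = reduce(a)
    kept_b, vb = reduce(b)
    n = len(shared)

    ext_to_vertex = {"A": {}, "B": {}}
    for tag, verts in (("A", va), ("B", vb)):
        for i, v in enumerate(verts):
            for e in v["exts"]:
                ext_to_vertex[tag][e] = i

    visited = {"A": [False] * len(va), "B": [False] * len(vb)}

    def walk(tag, idx, in_ext):
        """Walk a component from vertex (tag, idx), entered via in_ext
        (None when starting at a path end).  Returns the component's
        ordered (genome, label) list and its endpoint genomes."""
        seq = []
        start = (tag, idx)
        while True:
            visited[tag][idx] = True
            v = (va if tag == "A" else vb)[idx]
            seq.append((tag, v["label"]))
            outs = [e for e in v["exts"] if e != in_ext]
            if in_ext is None and len(v["exts"]) == 2:
                # cycle start: pick one direction
                outs = [v["exts"][0]]
                # re-enter via the other later
            if not outs:
                return seq, ("path", tag)
            out = outs[0]
            other = "B" if tag == "A" else "A"
            nidx = ext_to_vertex[other][out]
            if visited[other][nidx]:
                return seq, ("cycle", None)
            tag, idx, in_ext = other, nidx, out

    components = []
    # paths first (start at telomere vertices)
    for tag, verts in (("A", va), ("B", vb)):
        for i, v in enumerate(verts):
            if len(v["exts"]) == 1 and not visited[tag][i]:
                seq, _ = walk(tag, i, None)
                end_tag = seq[-1][0]
                components.append(("path", tag + end_tag, seq))
    for tag, verts in (("A", va), ("B", vb)):
        for i, v in enumerate(verts):
            if not visited[tag][i]:
                seq, _ = walk(tag, i, None)
                components.append(("cycle", "", seq))

    c = sum(1 for k, _, _ in components if k == "cycle")
    ab_paths = sum(1 for k, t, _ in components if k == "path" and set(t) == {"A", "B"})
    d_dcj = n - c - ab_paths // 2

    lam = 0
    path_runs = []
    for kind, ptype, seq in components:
        runs: list[str] = []
        for tag, label in seq:
            if label:
                if not runs or runs[-1] != tag:
                    runs.append(tag)
        if kind == "cycle" and len(runs) > 1 and runs[0] == runs[-1]:
            runs = runs[:-1]
        L = len(runs)
        lam_c = math.ceil((L + 1) / 2) if L else 0
        lam += lam_c
        if kind == "path":
            path_runs.append((ptype, runs, lam_c))

    # path recombination: one extra DCJ joining the AA- and BB-path can
    # concatenate their run sequences, merging runs across the junction
    best = d_dcj + lam
    types = sorted(p[0] for p in path_runs)
    if types == ["AA", "BB"] or types == ["BB", "AA"]:
        (t1, r1, l1), (t2, r2, l2) = path_runs
        base = d_dcj + (lam - l1 - l2)
        # recombining costs 1 DCJ but turns {AA,BB} (no AB-path credit)
        # into {AB,AB} (credit 1): net DCJ cost unchanged; try every split
        # of each run word (runs can travel with either side of the cut)
        for i in range(len(r1) + 1):
            left1, right1 = r1[:i], r1[i:]
            for j in range(len(r2) + 1):
                for q_left, q_right in (
                    (r2[:j], r2[j:]),
                    (r2[j:][::-1], r2[:j][::-1]),
                ):
                    w1 = _merge_words(left1, q_left[::-1])
                    w2 = _merge_words(right1[::-1], q_right)
                    cand = base + _lam_word(w1) + _lam_word(w2)
                    if cand < best:
                        best = cand
    return best


def _merge_words(x: list[str], y: list[str]) -> list[str]:
    out = list(x)
    for t in y:
        if not out or out[-1] != t:
            out.append(t)
    return out


def _lam_word(runs: list[str]) -> int:
    return math.ceil((len(runs) + 1) / 2) if runs else 0


def _matchings(a_names: list[str], b_names: list[str]):
    """All injective per-name matchings (including partial ones).

    Every rearrangement scenario induces such a matching (unmatched
    occurrences are indel content), so minimizing over all of them gives
    the scenario minimum and keeps the distance a metric.
    """
    ca, cb = Counter(a_names), Counter(b_names)
    for name in set(ca) | set(cb):
        if ca.get(name, 0) > D_MAX or cb.get(name, 0) > D_MAX:
            raise ValueError(f"marker {name!r} occurs more than {D_MAX} times: out of model")
    per_name_opts = []
    for name in sorted(set(ca) | set(cb)):
        ia = [i for i, n in enumerate(a_names) if n == name]
        ib = [i for i, n in enumerate(b_names) if n == name]
        opts = set()
        kmax = min(len(ia), len(ib))
        for k in range(kmax + 1):
            for sub_a in itertools.permutations(ia, k):
                for sub_b in itertools.combinations(ib, k):
                    opts.add(tuple(zip(sub_a, sub_b)))
        per_name_opts.append(sorted(opts))
    for combo in itertools.product(*per_name_opts):
        yield [p for group in combo for p in group]


def dcj_indel_distance(a: Configuration | Sequence[Symbol], b: Configuration | Sequence[Symbol]) -> int:
    """Minimum DCJ + run-indel operations between two linear configurations."""
    sym_a = a.symbols if isinstance(a, Configuration) else tuple(a)
    sym_b = b.symbols if isinstance(b, Configuration) else tuple(b)
    sa = _signed(sym_a)
    sb = _signed(sym_b)
    a_names = [n for n, _ in sa]
    b_names = [n for n, _ in sb]
    best = None
    for pairs in _matchings(a_names, b_names):
        ids_a = [0] * len(sa)
        ids_b = [0] * len(sb)
        next_id = 1
        for ia, ib in pairs:
            ids_a[ia] = next_id
            ids_b[ib] = next_id
            next_id += 1
        for i in range(len(sa)):
            if ids_a[i] == 0:
                ids_a[i] = next_id
                next_id += 1
        for i in range(len(sb)):
            if ids_b[i] == 0:
                ids_b[i] = next_id
                next_id += 1
        ra = [ids_a[i] * sa[i][1] for i in range(len(sa))]
        rb = [ids_b[i] * sb[i][1] for i in range(len(sb))]
        d = _distance_relabelled(ra, rb)
        if best is None or d < best:
            best = d
    return best if best is not None else 0


# ---------------------------------------------------------------------------
# configuration tree
# ---------------------------------------------------------------------------


@dataclass
class RearrangementTree:
    distances: pd.DataFrame
    tree: TreeNode
    frequencies: dict[str, float]
    orientation: dict[str, str]  # direct | inverted vs the reference


def orientation_class(config: Configuration, reference: Configuration) -> str:
    """Direct/inverted call: majority orientation of shared markers vs reference."""
    ref_orient = {}
    for n, o in reference.symbols:
        ref_orient.setdefault(n, o)
    flipped = same = 0
    for n, o in config.symbols:
        if n in ref_orient:
            if o == ref_orient[n]:
                same += 1
            else:
                flipped += 1
    return "inverted" if flipped > same else "direct"


def config_tree(
    configs: Sequence[Configuration],
    reference: Configuration | None = None,
    min_haplotypes: int = 2,
) -> RearrangementTree:
    """Midpoint-rooted NJ tree over pairwise DCJ-indel distances.

    Configurations observed in fewer than ``min_haplotypes`` haplotypes
    are excluded (detectability rule); pre-aggregation is required, so
    duplicate symbol strings raise.
    """
    strings = [c.symbols for c in configs]
    if len(set(strings)) != len(strings):
        raise ValueError("duplicate configurations: aggregate haplotypes first")
    kept = [c for c in configs if len(c.haplotypes) >= min_haplotypes]
    dropped = len(configs) - len(kept)
    if dropped:
        logger.info("config_tree: excluded %d singleton configurations", dropped)
    if len(kept) < 2:
        raise ValueError("need at least 2 configurations after the detectability filter")
    ids = [c.locus_id for c in kept]
    m = np.zeros((len(kept), len(kept)))
    for i in range(len(kept)):
        for j in range(i + 1, len(kept)):
            m[i, j] = m[j, i] = dcj_indel_distance(kept[i], kept[j])
    if not m.any() or len(kept) == 2:
        root = TreeNode(name="root")
        for i, cid in enumerate(ids):
            root.append(TreeNode(name=cid, length=float(m[0, i]) / 2))
        tree = root
    else:
        tree = nj(DistanceMatrix(m, ids=ids))
        for node in tree.traverse(include_self=True):
            if node.length is not None and node.length < 0:
                node.length = 0.0
        tree = tree.root_at_midpoint()
    freqs = {c.locus_id: c.frequency for c in kept}
    ref = reference if reference is not None else kept[0]
    orient = {c.locus_id: orientation_class(c, ref) for c in kept}
    return RearrangementTree(
        distances=pd.DataFrame(m, index=ids, columns=ids),
        tree=tree,
        frequencies=freqs,
        orientation=orient,
    )


# ---------------------------------------------------------------------------
# inversion calls
# ---------------------------------------------------------------------------


@dataclass
class InversionCall:
    first_marker: str
    last_marker: str
    n_markers: int


def call_inversions(sample: Configuration, reference: Configuration) -> list[InversionCall]:
    """Maximal runs of shared markers in reversed order and flipped
    orientation relative to the reference, one call per run."""
    ref_names = [n for n, _ in reference.symbols]
    smp_names = [n for n, _ in sample.symbols]
    shared = {n for n in ref_names if ref_names.count(n) == 1} & {
        n for n in smp_names if smp_names.count(n) == 1
    }
    ref_idx = {n: i for i, (n, _) in enumerate(reference.symbols) if n in shared}
    ref_or = {n: o for n, o in reference.symbols if n in shared}
    seq = [(n, o) for n, o in sample.symbols if n in shared]
    calls = []
    i = 0
    while i < len(seq):
        n, o = seq[i]
        if o != ref_or[n]:
            j = i
            while (
                j + 1 < len(seq)
                and seq[j + 1][1] != ref_or[seq[j + 1][0]]
                and ref_idx[seq[j + 1][0]] == ref_idx[seq[j][0]] - 1
            ):
                j += 1
            span = [seq[k][0] for k in range(i, j + 1)]
            calls.append(InversionCall(span[-1], span[0], len(span)))
            i = j + 1
        else:
            i += 1
    return calls


def inversion_af(configs: Sequence[Configuration], reference: Configuration) -> float:
    """Allele frequency of inversion-carrying haplotypes at the locus.

    A configuration counts as inverted when it shows at least one
    inversion call against the reference configuration.
    """
    total = sum(len(c.haplotypes) for c in configs)
    if total == 0:
        return float("nan")
    inv = sum(len(c.haplotypes) for c in configs if call_inversions(c, reference))
    return inv / total


def aggregate_configurations(
    per_haplotype: Mapping[str, Sequence[Symbol]], locus_id: str = "locus"
) -> list[Configuration]:
    """Group identical symbol strings into Configurations with frequencies."""
    groups: dict[tuple[Symbol, ...], list[str]] = {}
    for hap, syms in per_haplotype.items():
        groups.setdefault(tuple(syms), []).append(hap)
    total = len(per_haplotype)
    out = []
    for i, (syms, haps) in enumerate(sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))):
        out.append(
            Configuration(
                locus_id=f"{locus_id}_cfg{i + 1}",
                symbols=syms,
                haplotypes=tuple(sorted(haps)),
                frequency=len(haps) / total,
            )
        )
    return out
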