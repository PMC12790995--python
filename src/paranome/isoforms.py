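"""Full-length cDNA paralog assignment, ORF/isoform models, and VNTR profiling.

A read is uniquely assigned to a copy only when its best alignment has
at least one fewer mismatch than the second best (the mismatch-delta
rule); mono-exonic reads never contribute to gene models.  ORFs are the
longest ATG-initiated forward-strand reading frames, classified by their
first four residues; isoform models require support from at least five
molecules.  The coding VNTR is profiled by counting SADD-frame and
MIISR-frame repeat units, and its genomic extent by a motif-seeded
tandem-array scan.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import edlib
from Bio.Seq import Seq

from .motifs import MIISR_UNIT, SADD_UNIT_19, SADD_UNIT_23

logger = logging.getLogger("paranome")

START_CLASSES = ("MFCC", "MVKL", "MRVR", "MRLR")


# ---------------------------------------------------------------------------
# read assignment
# ---------------------------------------------------------------------------


@dataclass
class IsoReadAssignment:
    read_id: str
    best_copy: str | None
    best_mismatches: int | None
    second_best_mismatches: int | None
    unique: bool
    mono_exonic: bool = False


def mismatch_table(
    reads: Mapping[str, str], references: Mapping[str, Sequence[str] | str]
) -> dict[str, list[tuple[str, int]]]:
    """Per-read (copy, mismatches) via global edit-distance alignment.

    ``references`` maps each copy/paralog to one or more reference
    transcript sequences; the per-copy mismatch count is the minimum over
    its sequences.  Stands in for a spliced aligner on synthetic data.
    """
    out: dict[str, list[tuple[str, int]]] = {}
    for rid, seq in reads.items():
        rows = []
        for copy_id, refs in references.items():
            if isinstance(refs, str):
                refs = [refs]
            d = min(
                edlib.align(seq, ref, task="distance", mode="NW")["editDistance"]
                for ref in refs
            )
            rows.append((copy_id, int(d)))
        out[rid] = rows
    return out


def assign_reads(
    alignments: Mapping[str, Sequence[tuple[str, int]]],
    delta: int = 1,
    mono_exonic: Mapping[str, bool] | None = None,
) -> list[IsoReadAssignment]:
    """Mismatch-delta assignment: unique iff the best copy beats the
    second best by at least ``delta`` mismatches; ties are ambiguous."""
    mono_exonic = mono_exonic or {}
    out = []
    for rid, rows in alignments.items():
        if not rows:
            out.append(IsoReadAssignment(rid, None, None, None, False, mono_exonic.get(rid, False)))
            continue
        ranked = sorted(rows, key=lambda r: (r[1], r[0]))
        best_copy, best = ranked[0]
        second = ranked[1][1] if len(ranked) > 1 else None
        unique = second is None or (second - best) >= delta
        out.append(
            IsoReadAssignment(
                read_id=rid,
                best_copy=best_copy,
                best_mismatches=best,
                second_best_mismatches=second,
                unique=unique,
                mono_exonic=bool(mono_exonic.get(rid, False)),
            )
        )
    return out


# ---------------------------------------------------------------------------
# ORFs
# ---------------------------------------------------------------------------


def longest_orf(cdna: str, min_codons: int = 50) -> tuple[str, str] | None:
    """Longest ATG-initiated, stop-terminated ORF on the forward strand.

    Returns (protein, start_class); equal-length ORFs break ties to the
    5'-most.  ORFs shorter than ``min_codons`` are rejected (None,
    logged) to suppress spurious short frames.
    """
    import bisect

    seq = cdna.upper()
    best: tuple[int, int, str] | None = None  # (-len, start, protein)
    for frame in range(3):
        translated = str(Seq(seq[frame : frame + (len(seq) - frame) // 3 * 3]).translate())
        starts = [k for k, aa in enumerate(translated) if aa == "M"]
        stops = [k for k, aa in enumerate(translated) if aa == "*"]
        for k in starts:
            j = bisect.bisect_left(stops, k)
            if j == len(stops):
                continue  # no in-frame stop: not a complete ORF
            prot = translated[k : stops[j]]
            cand = (-len(prot), frame + 3 * k, prot)
            if best is None or cand < best:
                best = cand
    if best is None or len(best[2]) < min_codons:
        logger.info("no ORF of >= %d codons found", min_codons)
        return None
    prot = best[2]
    start_class = prot[:4] if prot[:4] in START_CLASSES else "other"
    return prot, start_class


# ---------------------------------------------------------------------------
# isoform models
# ---------------------------------------------------------------------------


@dataclass
class IsoformModel:
    paralog: str
    protein: str
    start_class: str
    support: int
    rank: int  # 1 = most abundant for the paralog
    name: str  # "<paralog>_<rank>"
    longest: bool  # longest model of its paralog


def collapse_isoforms(
    molecules: Sequence[tuple[str, str]],
    min_support: int = 5,
) -> list[IsoformModel]:
    """Aggregate (paralog, protein) molecules into supported isoform models.

    Models with fewer than ``min_support`` molecules are dropped; models
    are ranked per paralog by abundance (suffix _1.._k) and the longest
    retained model is flagged alongside the most abundant.
    """
    counts: dict[tuple[str, str], int] = {}
    for paralog, protein in molecules:
        counts[(paralog, protein)] = counts.get((paralog, protein), 0) + 1
    by_paralog: dict[str, list[tuple[str, int]]] = {}
    for (paralog, protein), n in counts.items():
        if n >= min_support:
            by_paralog.setdefault(paralog, []).append((protein, n))
    out = []
    for paralog in sorted(by_paralog):
        models = sorted(by_paralog[paralog], key=lambda pn: (-pn[1], pn[0]))
        longest_len = max(len(p) for p, _ in models)
        for rank, (protein, n) in enumerate(models, start=1):
            start_class = protein[:4] if protein[:4] in START_CLASSES else "other"
            out.append(
                IsoformModel(
                    paralog=paralog,
                    protein=protein,
                    start_class=start_class,
                    support=n,
                    rank=rank,
                    name=f"{paralog}_{rank}",
                    longest=len(protein) == longest_len,
                )
            )
    return out


# ---------------------------------------------------------------------------
# VNTR profiling
# ---------------------------------------------------------------------------


@dataclass
class VntrProfile:
    n1: int  # SADD-frame units before the frame switch
    n2: int  # MIISR-frame units
    n3: int  # SADD-frame units after
    overflow: bool = False  # more than three alternation segments seen

    @property
    def total_units(self) -> int:
        return self.n1 + self.n2 + self.n3


def vntr_profile(protein: str) -> VntrProfile:
    """Count repeat units by the two frames of the coding VNTR.

    SADD-frame units are occurrences of "SADD"; MIISR-frame units are
    occurrences of "ISR" outside them (one per MIISR... unit).  Ordered
    occurrences are segmented into alternation runs; the expected pattern
    is SADD-run, MIISR-run, SADD-run (n1, n2, n3).
    """
    events = []
    i = protein.find("SADD")
    while i != -1:
        events.append((i, "S"))
        i = protein.find("SADD", i + 1)
    sadd_spans = [(p, p + 4) for p, _ in events]
    j = protein.find("ISR")
    while j != -1:
        if not any(s <= j < e for s, e in sadd_spans):
            events.append((j, "I"))
        j = protein.find("ISR", j + 1)
    events.sort()
    runs: list[tuple[str, int]] = []
    for _, kind in events:
        if runs and runs[-1][0] == kind:
            runs[-1] = (kind, runs[-1][1] + 1)
        else:
            runs.append((kind, 1))
    n1 = n2 = n3 = 0
    overflow = len(runs) > 3
    if runs:
        if runs[0][0] == "S":
            n1 = runs[0][1]
            rest = runs[1:]
        else:
            rest = runs
        if rest and rest[0][0] == "I":
            n2 = rest[0][1]
            rest = rest[1:]
        if rest and rest[0][0] == "S":
            n3 = rest[0][1]
    return VntrProfile(n1, n2, n3, overflow)


def vntr_unit_lengths(protein: str, max_unit: int = 40) -> list[int]:
    """Residue lengths of successive SADD-frame units, from anchor spacings.

    Each unit starts at a "SADD" anchor; the spacing between consecutive
    anchors within a run (<= ``max_unit`` residues apart) is the length
    of the earlier unit.
    """
    pos = []
    i = protein.find("SADD")
    while i != -1:
        pos.append(i)
        i = protein.find("SADD", i + 1)
    return [b - a for a, b in zip(pos, pos[1:]) if b - a <= max_unit]


def genomic_vntr_len(
    dna: str,
    min_period: int = 40,
    max_period: int = 300,
    k: int = 20,
    merge_gap: int = 30,
) -> int:
    """Length (bp) of the longest tandem repeat array with period >= 40 bp.

    Motif-seeded scan: each pair of consecutive occurrences of a k-mer at
    a spacing within [min_period, max_period] covers one repeat interval;
    overlapping or near-adjacent intervals (different seeds of the same
    region, or the two frames of a switching VNTR) are merged before
    taking the longest span.  Chance k-mer doublets are negligible at
    k = 20 within the bounded spacing window.
    """
    seq = dna.upper()
    occ: dict[str, list[int]] = {}
    for i in range(0, len(seq) - k + 1):
        occ.setdefault(seq[i : i + k], []).append(i)
    intervals = []
    for positions in occ.values():
        for p, q in zip(positions, positions[1:]):
            if min_period <= q - p <= max_period:
                intervals.append((p, q + k))
    if not intervals:
        return 0
    intervals.sort()
    merged = [list(intervals[0])]
    for a, b in intervals[1:]:
        if a <= merged[-1][1] + merge_gap:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return max(b - a for a, b in merged)
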