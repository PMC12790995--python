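"""Identify, extract, and validate gene-family copies in haplotype assemblies.

Discovery aligns a whole-locus query against each assembly contig.  Hits
can come from externally supplied PAF alignments, from the internal
anchor-chaining mapper, or both; overlapping hits are merged by interval
union (mirroring the union of two independent mappers) with strand taken
from the majority of merged block length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io import AlignmentRecord
from .simulate import revcomp

ANCHOR_K = 48
CHAIN_GAP = 5_000
MIN_QUERY_COVER = 0.60


@dataclass
class LocusCopy:
    """One extracted gene-family copy on a haplotype."""

    copy_id: str
    haplotype_id: str
    contig: str
    start: int
    end: int
    strand: str
    sequence: str = ""
    validation: str = "pass"
    flank_ok: bool = True

    @property
    def interval(self) -> tuple[str, int, int, str]:
        return (self.contig, self.start, self.end, self.strand)


def _anchor_hits(contig_seq: str, index: dict[str, int], qlen: int):
    """Exact ANCHOR_K-mer matches of the query in the contig, both strands.

    Yields (tpos, qpos, strand).  The query index maps each k-mer to one
    representative query offset (family k-mers are effectively unique at
    k=48).
    """
    k = ANCHOR_K
    for t in range(0, len(contig_seq) - k + 1):
        kmer = contig_seq[t : t + k]
        q = index.get(kmer)
        if q is not None:
            yield (t, q, "+")
        q = index.get(revcomp(kmer))
        if q is not None:
            yield (t, q, "-")


def _chain(anchors: list[tuple[int, int, str]], qlen: int, contig_len: int):
    """Greedy collinear chaining of anchors into candidate copy intervals."""
    out = []
    for strand in "+-":
        sub = sorted(a for a in anchors if a[2] == strand)
        chains: list[list[tuple[int, int, str]]] = []
        for a in sub:
            placed = False
            for ch in chains:
                last = ch[-1]
                if a[0] - last[0] <= CHAIN_GAP:
                    if strand == "+" and a[1] >= last[1] - ANCHOR_K:
                        ch.append(a)
                        placed = True
                        break
                    if strand == "-" and a[1] <= last[1] + ANCHOR_K:
                        ch.append(a)
                        placed = True
                        break
            if not placed:
                chains.append([a])
        for ch in chains:
            qmin = min(a[1] for a in ch)
            qmax = max(a[1] for a in ch) + ANCHOR_K
            if qmax - qmin < MIN_QUERY_COVER * qlen:
                continue
            if strand == "+":
                t_at_qmin = min(a[0] for a in ch if a[1] == qmin)
                t_at_qmax = max(a[0] for a in ch if a[1] + ANCHOR_K == qmax)
                start = t_at_qmin - qmin
                end = t_at_qmax + ANCHOR_K + (qlen - qmax)
            else:
                t_at_qmax = min(a[0] for a in ch if a[1] + ANCHOR_K == qmax)
                t_at_qmin = max(a[0] for a in ch if a[1] == qmin)
                start = t_at_qmax - (qlen - qmax)
                end = t_at_qmin + ANCHOR_K + qmin
            start = max(0, start)
            end = min(contig_len, end)
            if end > start:
                out.append((start, end, strand, end - start))
    return out


def map_query(assembly: Mapping[str, str], query: str) -> list[tuple[str, int, int, str, int]]:
    """Internal mapper: (contig, start, end, strand, block_len) candidate hits."""
    index: dict[str, int] = {}
    for q in range(0, len(query) - ANCHOR_K + 1):
        index.setdefault(query[q : q + ANCHOR_K], q)
    hits = []
    for contig, seq in assembly.items():
        anchors = list(_anchor_hits(seq, index, len(query)))
        for start, end, strand, blen in _chain(anchors, len(query), len(seq)):
            hits.append((contig, start, end, strand, blen))
    return hits


def _merge_hits(hits: list[tuple[str, int, int, str, int]]):
    """Union-merge hits overlapping by >= 1 bp; strand by majority block length."""
    merged = []
    for contig in sorted({h[0] for h in hits}):
        sub = sorted(h for h in hits if h[0] == contig)
        cur = None
        for _, s, e, strand, blen in sub:
            if cur is None or s > cur[1]:
                if cur is not None:
                    merged.append((contig, *cur[:1], cur[1], cur[2]))
                cur = [s, e, {strand: blen}]
            else:
                cur[1] = max(cur[1], e)
                cur[2][strand] = cur[2].get(strand, 0) + blen
        if cur is not None:
            merged.append((contig, cur[0], cur[1], cur[2]))
    out = []
    for contig, s, e, strands in merged:
        strand = max(sorted(strands), key=lambda k: strands[k])
        out.append((contig, s, e, strand))
    return out


def find_copies(
    assembly: Mapping[str, str],
    query_locus: str,
    haplotype_id: str = "hap",
    alignments: Sequence[AlignmentRecord] | None = None,
    min_len: int = 15_000,
    use_internal_mapper: bool = True,
) -> list[LocusCopy]:
    """Find gene-family copies of ``query_locus`` in an assembly.

    ``alignments`` (PAF records whose targets are assembly contigs) and the
    internal mapper hits are pooled, union-merged, and filtered to merged
    spans of at least ``min_len``.  Copies come back sorted by position
    with their sequence extracted in assembly orientation.
    """
    if len(query_locus) < min_len:
        raise ValueError(
            f"query locus ({len(query_locus)} bp) is shorter than min_len={min_len}"
        )
    hits: list[tuple[str, int, int, str, int]] = []
    if alignments:
        for rec in alignments:
            hits.append((rec.target_contig, rec.target_start, rec.target_end, rec.strand, rec.block_len))
    if use_internal_mapper:
        hits.extend(map_query(assembly, query_locus))
    copies = []
    for i, (contig, s, e, strand) in enumerate(sorted(_merge_hits(hits))):
        if e - s < min_len:
            continue
        seq = assembly[contig][s:e] if contig in assembly else ""
        copies.append(
            LocusCopy(
                copy_id=f"{haplotype_id}_c{len(copies) + 1}",
                haplotype_id=haplotype_id,
                contig=contig,
                start=s,
                end=e,
                strand=strand,
                sequence=seq,
            )
        )
    return copies


def validate_copy(
    copy: LocusCopy,
    mask: Iterable[tuple[str, int, int]] = (),
    contig_len: int | None = None,
    flank: int = 30_000,
) -> LocusCopy:
    """Assembly-validate a copy: unique flanks present and no unreliable blocks.

    Fails with reason ``flank_truncated`` when copy +/- ``flank`` runs off
    the contig, or ``unreliable_block`` when that span intersects a mask
    interval.  Validation failures are states, not errors.
    """
    lo = copy.start - flank
    hi = copy.end + flank
    if lo < 0 or (contig_len is not None and hi > contig_len):
        copy.validation = "fail:flank_truncated"
        copy.flank_ok = False
        return copy
    for contig, s, e in mask:
        if contig == copy.contig and s < hi and lo < e:
            copy.validation = "fail:unreliable_block"
            copy.flank_ok = True
            return copy
    copy.validation = "pass"
    copy.flank_ok = True
    return copy
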