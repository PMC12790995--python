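"""Read-depth copy-number estimation and population summaries.

Short reads are split into non-overlapping fixed-length segments and
placed at every reference position matching with at most two mismatches
(exact seed k-mers verified by Hamming check, both strands).  Window
depth is calibrated against known copy-number-2 regions, so
``cn = 2 * depth / calibration_depth``.  Windows overlapping a coding
VNTR are excluded from estimation to avoid repeat-length bias.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .simulate import revcomp

SEED_K = 12


@dataclass
class DepthWindow:
    contig: str
    start: int
    end: int
    raw_count: int = 0
    depth: float = 0.0  # segment starts per bp
    cn_estimate: float | None = None
    excluded: bool = False
    reason: str = ""


class _RefIndex:
    """Exact seed index over the reference with <=2-mismatch verification."""

    def __init__(self, reference: Mapping[str, str], frag_len: int, max_mismatch: int):
        self.frag_len = frag_len
        self.max_mismatch = max_mismatch
        self.arrays = {c: np.frombuffer(s.encode(), dtype=np.uint8) for c, s in reference.items()}
        self.seeds: dict[bytes, list[tuple[str, int]]] = {}
        self.offsets = list(range(0, frag_len - SEED_K + 1, SEED_K))
        for contig, seq in reference.items():
            b = seq.encode()
            for p in range(0, len(b) - SEED_K + 1):
                self.seeds.setdefault(b[p : p + SEED_K], []).append((contig, p))

    def match_positions(self, segment: str) -> set[tuple[str, int]]:
        """All (contig, pos) where the segment or its reverse complement
        matches with at most ``max_mismatch`` substitutions."""
        out: set[tuple[str, int]] = set()
        for seq in (segment, revcomp(segment)):
            b = seq.encode()
            arr = np.frombuffer(b, dtype=np.uint8)
            cands: set[tuple[str, int]] = set()
            for off in self.offsets:
                for contig, p in self.seeds.get(b[off : off + SEED_K], ()):
                    cands.add((contig, p - off))
            for contig, p in cands:
                ref = self.arrays[contig]
                if p < 0 or p + self.frag_len > ref.size:
                    continue
                if int(np.count_nonzero(ref[p : p + self.frag_len] != arr)) <= self.max_mismatch:
                    out.add((contig, p))
        return out


def depth_cn(
    reads: Mapping[str, str],
    reference: Mapping[str, str],
    windows: Sequence[tuple[str, int, int]],
    calibration: Sequence[tuple[str, int, int]],
    frag_len: int = 36,
    max_mismatch: int = 2,
    exclude: Sequence[tuple[str, int, int]] = (),
) -> list[DepthWindow]:
    """fastCN-style depth copy number over windows, calibrated to CN=2 regions.

    Each read is split into non-overlapping ``frag_len`` segments; a
    segment counts toward every window in which a <=``max_mismatch``
    match starts.  ``exclude`` intervals (e.g. the exon-8 VNTR) mark
    overlapping windows as excluded, with no estimate.
    """
    index = _RefIndex(reference, frag_len, max_mismatch)
    counts = {c: np.zeros(arr.size, dtype=np.int32) for c, arr in index.arrays.items()}
    for seq in reads.values():
        for i in range(0, len(seq) - frag_len + 1, frag_len):
            for contig, p in index.match_positions(seq[i : i + frag_len]):
                counts[contig][p] += 1

    def span_depth(contig: str, start: int, end: int) -> tuple[int, float]:
        # only positions that can host a full segment start carry counts
        valid_end = min(end, counts[contig].size - frag_len + 1)
        raw = int(counts[contig][start:valid_end].sum())
        return raw, raw / max(valid_end - start, 1)

    cal_depths = []
    for contig, s, e in calibration:
        cal_depths.append(span_depth(contig, s, e)[1])
    cal_mean = float(np.mean(cal_depths)) if cal_depths else 0.0
    if cal_mean <= 0:
        raise ValueError("zero calibration depth: cannot normalize")

    out = []
    for contig, s, e in windows:
        w = DepthWindow(contig, s, e)
        for xc, xs, xe in exclude:
            if xc == contig and xs < e and s < xe:
                w.excluded = True
                w.reason = "vntr_overlap"
                break
        w.raw_count, w.depth = span_depth(contig, s, e)
        if not w.excluded:
            w.cn_estimate = 2.0 * w.depth / cal_mean
        out.append(w)
    return out


def population_summary(
    cn_by_sample: Mapping[str, float],
    groups: Mapping[str, str],
) -> dict:
    """Per-group copy-number distributions plus pairwise rank-sum tests.

    Returns median/IQR per group and a two-sided Wilcoxon rank-sum
    (Mann-Whitney) p-value for every group pair; with a single group only
    the summary is produced.
    """
    by_group: dict[str, list[float]] = {}
    for sample, cn in cn_by_sample.items():
        by_group.setdefault(groups[sample], []).append(float(cn))
    for g, vals in by_group.items():
        if not vals:
            raise ValueError(f"group {g} has no samples")
    if not by_group:
        raise ValueError("no samples provided")
    summary = {}
    for g, vals in sorted(by_group.items()):
        arr = np.array(vals)
        summary[g] = {
            "n": int(arr.size),
            "median": float(np.median(arr)),
            "iqr": (float(np.percentile(arr, 25)), float(np.percentile(arr, 75))),
        }
    tests = {}
    names = sorted(by_group)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = by_group[names[i]], by_group[names[j]]
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            tests[(names[i], names[j])] = float(res.pvalue)
    return {"groups": summary, "rank_sum_p": tests}
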