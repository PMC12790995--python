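"""Interlocus gene-conversion (IGC) tract detection on gene-family copies.

High-identity paralogs exchange sequence non-reciprocally: an acceptor
copy carries a tract of donor-paralog sequence.  The scan slides a
window along a copy and flags windows whose Hamming distance to another
paralog's consensus beats the distance to the copy's own consensus by at
least ``min_sites`` diagnostic positions; adjacent same-donor windows
merge into tracts, summarized as a donor x acceptor matrix and an
acceptor hotspot ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("paranome")

GAP = frozenset(b"-.Nn")


@dataclass
class WindowFlag:
    copy_id: str
    acceptor_paralog: str
    start: int
    end: int
    donor: str
    n_diagnostic: int


@dataclass
class IGCTract:
    copy_id: str
    acceptor_paralog: str
    donor_paralog: str
    start: int
    end: int
    n_diagnostic_sites: int

    def __post_init__(self) -> None:
        if self.donor_paralog == self.acceptor_paralog:
            raise ValueError("IGC donor must differ from the acceptor paralog")


def scan_windows(
    copy_seq: str,
    own_paralog: str,
    consensus: Mapping[str, str],
    copy_id: str = "copy",
    window: int = 1_000,
    step: int = 100,
    min_sites: int = 3,
    max_gap_frac: float = 0.2,
) -> list[WindowFlag]:
    """Nearest-consensus sliding-window scan of one copy.

    Sequences must share the consensus coordinate frame (the
    substitution-only alignment of the family).  A window is flagged with
    donor P when d(copy, P) is smaller than d(copy, own) by at least
    ``min_sites``; windows with more than ``max_gap_frac`` gap/ambiguous
    characters are skipped and logged.
    """
    if own_paralog not in consensus:
        raise ValueError(f"consensus set lacks the copy's own paralog {own_paralog!r}")
    arr = np.frombuffer(copy_seq.upper().encode(), dtype=np.uint8)
    cons = {
        p: np.frombuffer(s.upper().encode(), dtype=np.uint8) for p, s in consensus.items()
    }
    own = cons[own_paralog]
    n = min(arr.size, own.size)
    gap_codes = np.array(sorted(GAP), dtype=np.uint8)
    is_gap = np.isin(arr[:n], gap_codes)
    flags = []
    n_skipped = 0
    for s in range(0, max(n - window, 0) + 1, step):
        e = min(s + window, n)
        if is_gap[s:e].mean() > max_gap_frac:
            n_skipped += 1
            continue
        d_own = int(np.count_nonzero(arr[s:e] != own[s:e]))
        best_donor = None
        best_d = None
        for p, cseq in cons.items():
            if p == own_paralog or cseq.size < e:
                continue
            dp = int(np.count_nonzero(arr[s:e] != cseq[s:e]))
            if best_d is None or dp < best_d or (dp == best_d and p < best_donor):
                best_d, best_donor = dp, p
        if best_donor is not None and d_own - best_d >= min_sites:
            flags.append(
                WindowFlag(copy_id, own_paralog, s, e, best_donor, d_own - best_d)
            )
    if n_skipped:
        logger.info("scan_windows(%s): skipped %d gappy windows", copy_id, n_skipped)
    return flags


def call_tracts(
    flags: Sequence[WindowFlag], step: int = 100
) -> tuple[list[IGCTract], pd.DataFrame, pd.DataFrame]:
    """Merge flagged windows into tracts; summarize directionality.

    Same-copy, same-donor windows whose intervals overlap or sit within
    one ``step`` merge into a single tract whose bounds are the union of
    member windows.  Returns (tracts, donor x acceptor matrix, hotspot
    table ranking acceptors by tract count).
    """
    tracts: list[IGCTract] = []
    keyed: dict[tuple[str, str], list[WindowFlag]] = {}
    for f in flags:
        keyed.setdefault((f.copy_id, f.donor), []).append(f)
    for (copy_id, donor), group in sorted(keyed.items()):
        group.sort(key=lambda f: f.start)
        cur = None
        for f in group:
            if cur is None or f.start > cur.end + step:
                if cur is not None:
                    tracts.append(cur)
                cur = IGCTract(copy_id, f.acceptor_paralog, donor, f.start, f.end, f.n_diagnostic)
            else:
                cur.end = max(cur.end, f.end)
                cur.n_diagnostic_sites = max(cur.n_diagnostic_sites, f.n_diagnostic)
        if cur is not None:
            tracts.append(cur)

    donors = sorted({t.donor_paralog for t in tracts})
    acceptors = sorted({t.acceptor_paralog for t in tracts})
    mat = pd.DataFrame(0, index=donors, columns=acceptors, dtype=int)
    for t in tracts:
        mat.loc[t.donor_paralog, t.acceptor_paralog] += 1
    hot = (
        pd.Series({a: int(mat[a].sum()) for a in acceptors}, dtype=int)
        .sort_values(ascending=False)
        .rename("n_tracts")
        .rename_axis("acceptor")
        .reset_index()
    )
    return tracts, mat, hot
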