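"""Diversity-based selection statistics: Tajima's D and nSL.

Tajima's D contrasts mean pairwise diversity (pi) with the
segregating-site estimator (S/a1) in sliding windows; an excess of rare
alleles (negative D) is consistent with positive selection.  nSL (number
of segregating sites by length) compares mean identity-run lengths, in
SNP units, between carriers of the ancestral and derived allele at each
site, is standardized within derived-allele-frequency bins, and is
aggregated per window; it needs no recombination map, which matters in
segmental-duplication regions where maps are unreliable.  The ancestral
allele is taken to be REF (polarity assumption, documented).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import VariantMatrix

logger = logging.getLogger("paranome")


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------


def _tajima_constants(n: int) -> tuple[float, float]:
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / (i * i) for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return a1, e1, e2


def tajimas_d(hap: np.ndarray) -> tuple[int, float, float | None]:
    """(S, pi, D) for a 0/1 haplotype matrix (haplotypes x sites).

    D = (pi - S/a1) / sqrt(e1*S + e2*S*(S-1)) with the standard 1989
    constants; undefined (None) when S = 0 or fewer than 4 haplotypes.
    """
    hap = np.asarray(hap)
    n = hap.shape[0]
    ac = hap.sum(axis=0)
    seg = (ac > 0) & (ac < n)
    S = int(seg.sum())
    acs = ac[seg]
    pi = float((2.0 * acs * (n - acs)).sum() / (n * (n - 1))) if S else 0.0
    if S == 0 or n < 4:
        return S, pi, None
    a1, e1, e2 = _tajima_constants(n)
    D = (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))
    return S, pi, D


# ---------------------------------------------------------------------------
# nSL
# ---------------------------------------------------------------------------


@dataclass
class NslScore:
    site: int  # index into the variant matrix
    position: int
    daf: float
    sl_ancestral: float | None
    sl_derived: float | None
    raw: float | None
    standardized: float | None = None
    bin_id: int | None = None


def _run_lengths(agree: np.ndarray) -> np.ndarray:
    """Length of the maximal run of consecutive True containing each site
    (0 where False)."""
    S = agree.size
    out = np.zeros(S, dtype=np.int64)
    if S == 0:
        return out
    # boundaries of runs of True
    padded = np.concatenate([[False], agree, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.nonzero(diff == 1)[0]
    ends = np.nonzero(diff == -1)[0]
    for s, e in zip(starts, ends):
        out[s:e] = e - s
    return out


def nsl_raw(vm: VariantMatrix) -> list[NslScore]:
    """Unstandardized nSL per segregating site.

    For every haplotype pair agreeing at the focal site, L counts the
    consecutive sites (focal included) over which the pair is identical,
    truncated at the chromosome edges; SL is the pool mean and
    raw = ln(SL_ancestral / SL_derived).  Sites with an allele pool of
    fewer than 2 haplotypes are skipped (raw None).
    """
    H = np.asarray(vm.haplotypes, dtype=np.int8)
    n, S = H.shape
    sl_sum = np.zeros((2, S))
    sl_cnt = np.zeros((2, S), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            agree = H[i] == H[j]
            runs = _run_lengths(agree)
            both0 = agree & (H[i] == 0)
            both1 = agree & (H[i] == 1)
            sl_sum[0, both0] += runs[both0]
            sl_cnt[0, both0] += 1
            sl_sum[1, both1] += runs[both1]
            sl_cnt[1, both1] += 1
    out = []
    ac = H.sum(axis=0)
    for s in range(S):
        daf = ac[s] / n
        sl_a = sl_sum[0, s] / sl_cnt[0, s] if sl_cnt[0, s] else None
        sl_d = sl_sum[1, s] / sl_cnt[1, s] if sl_cnt[1, s] else None
        raw = math.log(sl_a / sl_d) if sl_a and sl_d else None
        out.append(
            NslScore(
                site=s,
                position=int(vm.positions[s]),
                daf=float(daf),
                sl_ancestral=sl_a,
                sl_derived=sl_d,
                raw=raw,
            )
        )
    return out


def nsl_normalize(
    scores: Sequence[NslScore],
    n_bins: int = 100,
    reference: Sequence[NslScore] | None = None,
) -> list[NslScore]:
    """Standardize raw scores within equal-width derived-allele-frequency bins.

    Each defined score is assigned to one of ``n_bins`` bins over [0, 1];
    within a bin the mean is subtracted and the SD divided out.  Bins
    with a single score get SD = 1 (logged).  When ``reference`` scores
    are given, bin means/SDs are estimated from them instead — the joint
    normalization against a genome-scale (mostly neutral) cohort that
    keeps local sweeps from normalizing themselves away.
    """
    defined = [s for s in scores if s.raw is not None]
    fit_on = [s for s in (reference if reference is not None else scores) if s.raw is not None]
    for s in list(defined) + list(fit_on):
        s.bin_id = min(int(s.daf * n_bins), n_bins - 1)
    by_bin: dict[int, list[float]] = {}
    for s in fit_on:
        by_bin.setdefault(s.bin_id, []).append(s.raw)
    stats: dict[int, tuple[float, float]] = {}
    n_single = 0
    for b, vals in by_bin.items():
        arr = np.array(vals)
        mu = float(arr.mean())
        if arr.size >= 2:
            sd = float(arr.std(ddof=0)) or 1.0
        else:
            sd = 1.0
            n_single += 1
        stats[b] = (mu, sd)
    for s in defined:
        if s.bin_id in stats:
            mu, sd = stats[s.bin_id]
            s.standardized = (s.raw - mu) / sd
        else:
            s.standardized = None  # empty reference bin
    if n_single:
        logger.info("nsl_normalize: %d singleton bins given SD=1", n_single)
    return list(scores)


# ---------------------------------------------------------------------------
# window aggregation and percentile flags
# ---------------------------------------------------------------------------


def window_stats(
    vm: VariantMatrix,
    scores: Sequence[NslScore] | None = None,
    window: int = 30_000,
    step: int | None = None,
    region: tuple[int, int] | None = None,
    min_snps: int = 10,
    extreme_cut: float = 2.0,
    mask: Sequence[tuple[int, int]] = (),
    targets: Sequence[tuple[int, int]] = (),
    target_min_overlap: int = 5_000,
    n_bins: int = 100,
) -> pd.DataFrame:
    """Per-window S, pi, D and nSL summaries with chromosome-wide
    percentile ranks.

    Windows with fewer than ``min_snps`` SNPs are dropped before
    ranking.  Percentile ranks (0-100) are computed over the retained
    windows and, a second time, excluding windows that overlap ``mask``
    intervals (IGC exclusion reanalysis).  A window counts as
    overlapping a target when the overlap is at least
    ``target_min_overlap`` bp.
    """
    if step is None:
        step = window
    if scores is None:
        scores = nsl_normalize(nsl_raw(vm), n_bins=n_bins)
    std = np.array(
        [s.standardized if s.standardized is not None else np.nan for s in scores]
    )
    spos = np.array([s.position for s in scores], dtype=np.int64)
    lo = region[0] if region else (int(vm.positions[0]) if vm.n_sites else 0)
    hi = region[1] if region else (int(vm.positions[-1]) + 1 if vm.n_sites else window)
    rows = []
    for start in range(lo, max(hi - window, lo) + 1, step):
        end = start + window
        sub = vm.slice(start, end)
        S, pi, D = tajimas_d(sub.haplotypes)
        sel = (spos >= start) & (spos < end)
        vals = std[sel]
        vals = vals[~np.isnan(vals)]
        nsl_max = float(np.abs(vals).max()) if vals.size else np.nan
        nsl_frac = float((np.abs(vals) > extreme_cut).mean()) if vals.size else np.nan
        masked = any(ms < end and start < me for ms, me in mask)
        target = any(
            min(end, te) - max(start, ts) >= target_min_overlap for ts, te in targets
        )
        rows.append(
            {
                "start": start,
                "end": end,
                "n_snps": sub.n_sites,
                "S": S,
                "pi": pi,
                "D": np.nan if D is None else D,
                "nsl_max_abs": nsl_max,
                "nsl_frac_extreme": nsl_frac,
                "masked": masked,
                "target": target,
            }
        )
    df = pd.DataFrame(rows)
    df = df[df["n_snps"] >= min_snps].reset_index(drop=True)
    if df.empty:
        raise ValueError("no windows retained after the min_snps filter")

    def pct(series: pd.Series) -> pd.Series:
        # midrank percentile: a tail threshold of x% flags ~x% of windows
        ok = series.notna()
        out = pd.Series(np.nan, index=series.index)
        if ok.sum():
            out[ok] = 100.0 * (rankdata(series[ok]) - 0.5) / ok.sum()
        return out

    df["d_pct"] = pct(df["D"])
    df["nsl_pct"] = pct(df["nsl_max_abs"])
    df["nsl_frac_pct"] = pct(df["nsl_frac_extreme"])
    unmasked = ~df["masked"]
    for col, name in (
        ("D", "d_pct_nomask"),
        ("nsl_max_abs", "nsl_pct_nomask"),
        ("nsl_frac_extreme", "nsl_frac_pct_nomask"),
    ):
        out = pd.Series(np.nan, index=df.index)
        sub = df.loc[unmasked, col]
        ok = sub.notna()
        if ok.sum():
            out[sub[ok].index] = 100.0 * (rankdata(sub[ok]) - 0.5) / ok.sum()
        df[name] = out
    for tail in (1, 5):
        df[f"d_low{tail}"] = df["d_pct"] <= tail
        df[f"d_high{tail}"] = df["d_pct"] >= 100 - tail
        df[f"nsl_top{tail}"] = df["nsl_pct"] >= 100 - tail
    return df
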