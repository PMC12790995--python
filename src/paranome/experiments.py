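"""Replicated simulation experiments: neutral calibration and sweep power.

These drive the forward Wright-Fisher generator through the selection
statistics at study-condition scale: samples of 40 haplotypes (20
diploid genomes, the size of the African assembly panel used for
selection scans), 30 kbp windows, at least 10 SNPs per window, and
100-bin frequency normalization of nSL.  Problem sizes (region length,
population size, replicate counts) are desk-scale choices recorded in
the methods note.
"""

from __future__ import annotations

import logging

import numpy as np

from .selection import nsl_normalize, nsl_raw, tajimas_d, window_stats
from .simulate import simulate_sweep

logger = logging.getLogger("paranome")


def neutral_calibration(
    n_reps: int = 50,
    n_haplotypes: int = 40,
    L: int = 500_000,
    N: int = 200,
    mu: float = 1e-6,
    rho: float = 1e-6,
    window: int = 30_000,
    min_snps: int = 10,
    n_bins: int = 100,
    seed: int = 0,
) -> dict:
    """Neutral-null calibration of Tajima's D and standardized nSL.

    Runs ``n_reps`` neutral forward simulations; returns the across-rep
    mean of the per-replicate (whole-region) Tajima's D with its standard
    error, the window-mean variant for reference, and the pooled mean/SD
    of jointly bin-normalized nSL.
    """
    rep_D = []
    rep_win_D = []
    all_scores = []
    for r in range(n_reps):
        vm, _ = simulate_sweep(
            n_haplotypes=n_haplotypes, L=L, mu=mu, rho=rho, s=0.0, N=N, seed=seed + r
        )
        _, _, D = tajimas_d(vm.haplotypes)
        rep_D.append(float(D))
        ds = []
        for start in range(0, L - window + 1, window):
            sub = vm.slice(start, start + window)
            if sub.n_sites >= min_snps:
                _, _, d = tajimas_d(sub.haplotypes)
                if d is not None:
                    ds.append(d)
        rep_win_D.append(float(np.mean(ds)))
        all_scores.extend(nsl_raw(vm))
    nsl_normalize(all_scores, n_bins=n_bins)
    std = np.array([s.standardized for s in all_scores if s.standardized is not None])
    rep_D = np.array(rep_D)
    rep_win_D = np.array(rep_win_D)
    return {
        "n_reps": n_reps,
        "mean_D": float(rep_D.mean()),
        "se_D": float(rep_D.std(ddof=1) / np.sqrt(n_reps)),
        "mean_D_windowed": float(rep_win_D.mean()),
        "se_D_windowed": float(rep_win_D.std(ddof=1) / np.sqrt(n_reps)),
        "nsl_mean": float(std.mean()),
        "nsl_sd": float(std.std(ddof=0)),
        "n_scores": int(std.size),
    }


def sweep_power(
    n_reps: int = 50,
    s: float = 0.05,
    n_haplotypes: int = 40,
    L: int = 300_000,
    N: int = 200,
    mu: float = 1e-6,
    rho: float = 1e-6,
    window: int = 30_000,
    min_snps: int = 10,
    n_bins: int = 100,
    seed: int = 0,
) -> dict:
    """Power of the window-level |nSL| scan against matched neutral runs.

    Runs ``n_reps`` sweep replicates (selection ``s`` at L/2, sampled
    mid-sweep) and ``n_reps`` matched neutral replicates.  nSL is
    normalized against the pooled neutral background (the genome-scale
    cohort stand-in); the per-window statistic is max |standardized
    nSL|.  A replicate counts as detected when its sweep-site window
    reaches the top 1% of the pooled neutral window distribution; the
    matched-neutral rate of the same event calibrates the threshold.
    """
    sweep_vms, neut_vms, truths = [], [], []
    for r in range(n_reps):
        vm, tr = simulate_sweep(
            n_haplotypes=n_haplotypes, L=L, mu=mu, rho=rho, s=s, N=N, seed=seed + 10_000 + r
        )
        sweep_vms.append(vm)
        truths.append(tr)
    for r in range(n_reps):
        vm, _ = simulate_sweep(
            n_haplotypes=n_haplotypes, L=L, mu=mu, rho=rho, s=0.0, N=N, seed=seed + 20_000 + r
        )
        neut_vms.append(vm)

    neut_scores = [nsl_raw(vm) for vm in neut_vms]
    reference = [sc for rep in neut_scores for sc in rep]
    nsl_normalize(reference, n_bins=n_bins)
    sweep_scores = []
    for vm in sweep_vms:
        sc = nsl_raw(vm)
        nsl_normalize(sc, n_bins=n_bins, reference=reference)
        sweep_scores.append(sc)

    sweep_pos = L // 2

    def window_table(vm, scores):
        return window_stats(
            vm, scores=scores, window=window, step=window, region=(0, L), min_snps=min_snps
        )

    null_stats = []
    neut_site_hits = []
    neut_tables = []
    for vm, sc in zip(neut_vms, neut_scores):
        df = window_table(vm, sc)
        neut_tables.append(df)
        null_stats.extend(df.nsl_max_abs.dropna().tolist())
    threshold = float(np.percentile(null_stats, 99))

    hits = []
    for vm, sc in zip(sweep_vms, sweep_scores):
        df = window_table(vm, sc)
        w = df[(df.start <= sweep_pos) & (df.end > sweep_pos)]
        hits.append(bool(len(w) and (w.nsl_max_abs >= threshold).any()))
    for df in neut_tables:
        w = df[(df.start <= sweep_pos) & (df.end > sweep_pos)]
        neut_site_hits.append(bool(len(w) and (w.nsl_max_abs >= threshold).any()))

    return {
        "n_reps": n_reps,
        "s": s,
        "power": float(np.mean(hits)),
        "neutral_rate": float(np.mean(neut_site_hits)),
        "threshold": threshold,
        "n_null_windows": len(null_stats),
        "attempts": [t["attempts"] for t in truths],
    }
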