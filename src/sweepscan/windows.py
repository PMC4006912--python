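"""Sliding-window averaging and empirical-percentile outlier flagging.

Windows are runs of exactly ``size`` consecutive *valid* SNPs of one
chromosome, advanced one SNP at a time; an invalid SNP breaks the run
rather than widening the window, so every window averages exactly ``size``
informative markers.  Each window is labeled by its center SNP.

Thresholds are genome-wide empirical order statistics (type-1 quantile, no
interpolation): for the upper tail the cutoff is the k-th largest window
mean with k = floor(fraction * N), and all ties at the cutoff are flagged.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .io import SnpMap

__all__ = ["sliding_window_mean", "empirical_threshold", "flag_extremes"]


def sliding_window_mean(values, valid, snp_map: SnpMap, size: int = 9
                        ) -> pd.DataFrame:
    """Average a per-SNP statistic in sliding windows of ``size`` valid SNPs.

    Parameters
    ----------
    values, valid
        Per-SNP statistic and validity flag aligned to ``snp_map``.
    size
        Number of SNPs per window; must be odd so a center SNP exists.

    Returns
    -------
    DataFrame with one row per window: chrom, center_snp, center_pos,
    start, end (first/last member SNP positions), mean, n_members.
    Chromosomes (or valid runs) with fewer than ``size`` valid SNPs yield
    no windows.
    """
    if size % 2 == 0 or size < 1:
        raise ValueError("window size must be odd and positive")
    values = np.asarray(values, dtype=np.float64)
    valid = np.asarray(valid, dtype=bool)
    if len(values) != snp_map.n_snps or len(valid) != snp_map.n_snps:
        raise ValueError("track length does not match map")
    half = size // 2
    out = {k: [] for k in ("chrom", "center_snp", "center_pos",
                           "start", "end", "mean")}
    for chrom in snp_map.chromosomes:
        sl = snp_map.chrom_slice(chrom)
        idx = np.nonzero(valid[sl])[0]
        if idx.size < size:
            continue
        pos = snp_map.pos[sl]
        ids = snp_map.snp_id[sl]
        v = values[sl]
        # split the valid indices into maximal runs of consecutive SNPs
        breaks = np.nonzero(np.diff(idx) > 1)[0] + 1
        for run in np.split(idx, breaks):
            if run.size < size:
                continue
            w = np.lib.stride_tricks.sliding_window_view(v[run], size)
            means = w.mean(axis=1)
            centers = run[half:run.size - half]
            firsts = run[:run.size - size + 1]
            lasts = run[size - 1:]
            out["chrom"].extend([chrom] * means.size)
            out["center_snp"].extend(ids[centers])
            out["center_pos"].extend(pos[centers])
            out["start"].extend(pos[firsts])
            out["end"].extend(pos[lasts])
            out["mean"].extend(means)
    df = pd.DataFrame({"chrom": np.asarray(out["chrom"], dtype=object),
                       "center_snp": np.asarray(out["center_snp"], dtype=object),
                       "center_pos": np.asarray(out["center_pos"], dtype=np.int64),
                       "start": np.asarray(out["start"], dtype=np.int64),
                       "end": np.asarray(out["end"], dtype=np.int64),
                       "mean": np.asarray(out["mean"], dtype=np.float64)})
    df["n_members"] = size
    return df


def empirical_threshold(window_means, tail: str, fraction: float = 0.005
                        ) -> float:
    """Genome-wide empirical cutoff for the extreme ``fraction`` of windows.

    ``tail`` is "upper" (e.g. F_ST) or "lower" (e.g. ObsHtz).  The cutoff is
    the k-th most extreme order statistic, k = floor(fraction * N); flagging
    beyond-or-equal then yields at least k windows (ties included).

    Raises on an empty tail (too few windows for the requested fraction) and
    on a degenerate distribution (all values identical).
    """
    if tail not in ("upper", "lower"):
        raise ValueError("tail must be 'upper' or 'lower'")
    x = np.sort(np.asarray(window_means, dtype=np.float64))
    n = x.size
    k = math.floor(fraction * n)
    if k < 1:
        raise ValueError(
            f"too few windows ({n}) for a {fraction:g} tail; need at least "
            f"{math.ceil(1.0 / fraction)}")
    if x[0] == x[-1]:
        raise ValueError("degenerate distribution: all window means identical")
    return float(x[n - k] if tail == "upper" else x[k - 1])


def flag_extremes(window_track: pd.DataFrame, cutoff: float, tail: str
                  ) -> pd.DataFrame:
    """Windows at or beyond the cutoff, sorted by chromosome and position."""
    if tail == "upper":
        sel = window_track["mean"] >= cutoff
    elif tail == "lower":
        sel = window_track["mean"] <= cutoff
    else:
        raise ValueError("tail must be 'upper' or 'lower'")
    flagged = window_track[sel].copy()
    return flagged.sort_values(["chrom", "center_pos"],
                               kind="mergesort").reset_index(drop=True)
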