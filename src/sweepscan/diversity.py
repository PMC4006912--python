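"""Per-SNP diversity statistics.

Two-population unbiased F_ST after Weir & Cockerham (1984), computed from
the diploid variance components

    a  — among populations,
    b  — among individuals within populations,
    c  — within individuals (heterozygosity),

with per-SNP sample sizes recomputed after missing-data removal.  The
estimate is a/(a+b+c); a SNP is invalid when the denominator is exactly
zero (monomorphic with no heterozygotes in both samples) or when fewer
than two usable individuals remain in either population.  Negative
estimates are retained by default (window means stay unbiased); optional
truncation at zero replicates the convention of zeroing negatives.

Observed heterozygosity (ObsHtz) is the fraction of non-missing
individuals that are heterozygous, and the normalized variant (Rubin-style
Z_Hp) standardizes window means by their genome-wide mean and sample SD.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix, SnpMap

__all__ = ["fst_wc_values", "fst_wc_track", "snp_fst_wc",
           "obs_het_values", "obs_het_track", "snp_obs_het",
           "normalized_window_het"]


def _pop_summaries(calls: np.ndarray):
    """Per-SNP sample size, allele-A frequency and heterozygote proportion.

    ``calls`` is (individuals x SNPs) with -1 for missing.  SNPs with no
    usable individuals get frequency/het 0 with n = 0.
    """
    present = calls != MISSING
    n = present.sum(axis=0).astype(np.float64)
    ac = np.where(present, calls, 0).sum(axis=0, dtype=np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, ac / (2.0 * n), 0.0)
        h = np.where(n > 0, (calls == 1).sum(axis=0) / n, 0.0)
    return n, p, h


def fst_wc_values(calls1: np.ndarray, calls2: np.ndarray,
                  truncate_negative: bool = False
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-SNP Weir–Cockerham F_ST between two populations.

    Parameters
    ----------
    calls1, calls2
        Genotype call arrays (individuals x SNPs, -1 missing) on the same
        SNP columns.
    truncate_negative
        If true, clamp negative estimates to 0 (off by default).

    Returns
    -------
    fst, valid, n1, n2
        Estimate per SNP (NaN where invalid), validity flag, and per-SNP
        usable sample sizes.
    """
    if calls1.shape[1] != calls2.shape[1]:
        raise ValueError("populations disagree on SNP count")
    n1, p1, h1 = _pop_summaries(calls1)
    n2, p2, h2 = _pop_summaries(calls2)
    r = 2.0
    nbar = (n1 + n2) / r
    usable = (n1 >= 2) & (n2 >= 2)
    nbar_safe = np.where(usable, nbar, 2.0)  # avoid 0/0 in masked lanes
    n1s, n2s = np.where(usable, n1, 1.0), np.where(usable, n2, 1.0)

    nc = (r * nbar_safe - (n1s ** 2 + n2s ** 2) / (r * nbar_safe)) / (r - 1.0)
    # nc can be 0 only if n1 = n2 = 0; usable lanes have nc >= 2
    pbar = (n1s * p1 + n2s * p2) / (r * nbar_safe)
    s2 = (n1s * (p1 - pbar) ** 2 + n2s * (p2 - pbar) ** 2) / ((r - 1.0) * nbar_safe)
    hbar = (n1s * h1 + n2s * h2) / (r * nbar_safe)

    with np.errstate(invalid="ignore", divide="ignore"):
        inner = pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0
        a = (nbar_safe / nc) * (s2 - inner / (nbar_safe - 1.0))
        b = (nbar_safe / (nbar_safe - 1.0)) * (
            pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2
            - ((2.0 * nbar_safe - 1.0) / (4.0 * nbar_safe)) * hbar)
        c = hbar / 2.0
        denom = a + b + c
        fst = np.where(denom != 0.0, a / np.where(denom != 0.0, denom, 1.0),
                       np.nan)
    valid = usable & (denom != 0.0) & np.isfinite(fst)
    fst = np.where(valid, fst, np.nan)
    if truncate_negative:
        fst = np.where(valid & (fst < 0.0), 0.0, fst)
    return fst, valid, n1, n2


def fst_wc_track(pop1: GenotypeMatrix, pop2: GenotypeMatrix,
                 truncate_negative: bool = False) -> pd.DataFrame:
    """Per-SNP F_ST track aligned to the shared map.

    Columns: chrom, pos, snp_id, value, n1, n2, valid.
    """
    if pop1.snp_map is not pop2.snp_map and \
            pop1.snp_map.n_snps != pop2.snp_map.n_snps:
        raise ValueError("populations must share one SNP map")
    fst, valid, n1, n2 = fst_wc_values(pop1.calls, pop2.calls,
                                       truncate_negative)
    m = pop1.snp_map
    return pd.DataFrame({"chrom": m.chrom.astype(str),
                         "pos": m.pos, "snp_id": m.snp_id.astype(str),
                         "value": fst, "n1": n1.astype(int),
                         "n2": n2.astype(int), "valid": valid})


def snp_fst_wc(pop1: GenotypeMatrix, pop2: GenotypeMatrix,
               snp_index: int) -> tuple[float, bool]:
    """Single-SNP convenience wrapper; returns (estimate, valid)."""
    fst, valid, _, _ = fst_wc_values(pop1.calls[:, [snp_index]],
                                     pop2.calls[:, [snp_index]])
    return float(fst[0]), bool(valid[0])


def obs_het_values(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP observed heterozygosity; denominator excludes missing calls.

    Returns (het, valid, n); a SNP with no non-missing individuals is
    invalid (NaN), never silently zeroed.
    """
    present = calls != MISSING
    n = present.sum(axis=0).astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        het = np.where(n > 0, (calls == 1).sum(axis=0) / n, np.nan)
    valid = n > 0
    return het, valid, n


def obs_het_track(pop: GenotypeMatrix) -> pd.DataFrame:
    het, valid, n = obs_het_values(pop.calls)
    m = pop.snp_map
    return pd.DataFrame({"chrom": m.chrom.astype(str), "pos": m.pos,
                         "snp_id": m.snp_id.astype(str), "value": het,
                         "n1": n.astype(int), "valid": valid})


def snp_obs_het(pop: GenotypeMatrix, snp_index: int) -> tuple[float, bool]:
    het, valid, _ = obs_het_values(pop.calls[:, [snp_index]])
    return float(het[0]), bool(valid[0])


def normalized_window_het(window_means) -> np.ndarray:
    """Rubin-style Z-scores of per-window heterozygosity for one breed.

    Z_w = (H_w - mean(H)) / sd(H) over all windows genome-wide, with the
    sample standard deviation (ddof = 1).  Degenerate input (fewer than two
    windows, or zero SD) raises.
    """
    h = np.asarray(window_means, dtype=np.float64)
    if h.size < 2:
        raise ValueError("need at least two windows to normalize")
    sd = h.std(ddof=1)
    if sd == 0.0:
        raise ValueError("degenerate input: all window means identical")
    return (h - h.mean()) / sd
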