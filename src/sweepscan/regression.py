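"""Asymptotic-regression sweep statistic.

At a test position the per-SNP heterozygosity y is regressed on distance x
(Mb) with the asymptotic model

    y = A + B * R**x,        0 < R < 1,

where A is the asymptotic heterozygosity level, B the deficit at the test
position (fitted value at x = 0 minus A) and R the asymptotic rate.  A
significant fit with B < 0 — diversity recovering with distance — is the
pattern expected around a recently swept site.

Fitting uses variable projection: for fixed R the model is linear in
(A, B), so A and B are profiled out exactly and the residual sum of
squares is a 1-D function of R, minimized by a coarse grid plus bounded
Brent refinement.  Significance is the F statistic of the 3-parameter
model against the intercept-only model,

    F = ((SS0 - SS1) / 2) / (SS1 / (n - 3)),    p = Pr[F_{2, n-3} >= F],

charging two extra degrees of freedom for B and the estimated R; the
variance explained is 1 - SS1/SS0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import SnpMap

__all__ = ["AsymptoticFit", "fit_asymptotic", "scan_breed", "bracket_compare"]

_R_GRID = np.linspace(0.02, 0.98, 25)  # includes 0.1, 0.5, 0.9
_P_FLOOR = 1e-300
MIN_POINTS = 8


@dataclass(frozen=True)
class AsymptoticFit:
    """Result of one asymptotic regression at a test position."""

    A: float
    B: float
    R: float
    p: float
    varexp: float
    n_points: int
    converged: bool
    se_A: float = float("nan")
    se_B: float = float("nan")
    se_R: float = float("nan")

    @property
    def direction_ok(self) -> bool:
        """True when the fit has the shape predicted by positive selection
        (0 < R < 1 and B < 0: diversity increasing with distance)."""
        return bool(self.converged and 0.0 < self.R < 1.0 and self.B < 0.0)

    @property
    def neglog10p(self) -> float:
        return float(-np.log10(self.p))


def _linear_at_r(r: float, x: np.ndarray, y: np.ndarray,
                 sy: float, ybar: float, ss0: float):
    """Exact least-squares (A, B) and residual SS at fixed R."""
    w = np.power(r, x)
    n = x.size
    sw = w.sum()
    sww = w @ w
    swy = w @ y
    det = n * sww - sw * sw
    if det <= 1e-12 * max(n * sww, 1e-300):
        return ybar, 0.0, ss0, w  # basis collinear with intercept
    b = (n * swy - sw * sy) / det
    a = (sy - b * sw) / n
    resid = y - a - b * w
    return a, b, float(resid @ resid), w


def _grid_profile_ss(x, y, sy, syy, ss0):
    """Residual SS at every grid R, computed via the normal equations."""
    n = x.size
    w = np.power(_R_GRID[:, None], x[None, :])
    sw = w.sum(axis=1)
    sww = np.einsum("ij,ij->i", w, w)
    swy = w @ y
    det = n * sww - sw * sw
    safe = det > 1e-12 * np.maximum(n * sww, 1e-300)
    det_s = np.where(safe, det, 1.0)
    b = np.where(safe, (n * swy - sw * sy) / det_s, 0.0)
    a = np.where(safe, (sy - b * sw) / n, sy / n)
    ss = (syy + n * a * a + b * b * sww
          - 2.0 * a * sy - 2.0 * b * swy + 2.0 * a * b * sw)
    return np.where(safe, np.maximum(ss, 0.0), ss0)


def fit_asymptotic(x, y, xatol: float = 1e-12) -> AsymptoticFit:
    """Fit y = A + B*R**x by nonlinear least squares.

    Parameters
    ----------
    x
        Distances from the test position (Mb), all >= 0.
    y
        Heterozygosity values at those distances.
    xatol
        Absolute tolerance on R in the 1-D refinement; genome scans may
        loosen it for speed.

    Requires at least 8 points.  Non-convergence (including constant y)
    returns ``converged=False`` rather than raising.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size:
        raise ValueError("x and y differ in length")
    if x.size < MIN_POINTS:
        raise ValueError(f"need at least {MIN_POINTS} points, got {x.size}")
    if (x < 0).any():
        raise ValueError("distances must be non-negative")

    n = x.size
    sy = float(y.sum())
    syy = float(y @ y)
    ybar = sy / n
    ss0 = float(((y - ybar) ** 2).sum())
    if ss0 == 0.0 or np.ptp(y) == 0.0:
        return AsymptoticFit(A=ybar, B=0.0, R=float("nan"), p=1.0,
                             varexp=0.0, n_points=n, converged=False)

    # coarse profile over R, then Brent refinement in the bracketing cell
    ss_grid = _grid_profile_ss(x, y, sy, syy, ss0)
    i = int(np.argmin(ss_grid))
    lo = _R_GRID[i - 1] if i > 0 else 1e-6
    hi = _R_GRID[i + 1] if i + 1 < _R_GRID.size else 1.0 - 1e-9

    res = optimize.minimize_scalar(
        lambda r: _linear_at_r(r, x, y, sy, ybar, ss0)[2],
        bounds=(lo, hi), method="bounded",
        options={"xatol": xatol})
    r_hat = float(res.x)
    if ss_grid[i] < res.fun:  # guard: keep the better of grid and refine
        r_hat = float(_R_GRID[i])
    a_hat, b_hat, ss1, w = _linear_at_r(r_hat, x, y, sy, ybar, ss0)
    ss1 = min(ss1, ss0)

    converged = np.isfinite(a_hat) and np.isfinite(b_hat) and np.isfinite(r_hat)
    dfd = n - 3
    if ss1 <= 0.0:
        p = _P_FLOOR
    else:
        f_stat = ((ss0 - ss1) / 2.0) / (ss1 / dfd)
        p = float(stats.f.sf(f_stat, 2, dfd))
        p = min(max(p, _P_FLOOR), 1.0)
    varexp = 1.0 - ss1 / ss0

    se_a = se_b = se_r = float("nan")
    if converged and ss1 > 0.0 and 0.0 < r_hat < 1.0:
        with np.errstate(all="ignore"):
            dr = b_hat * x * np.power(r_hat, x - 1.0)
            jac = np.column_stack([np.ones(n), w, dr])
            jtj = jac.T @ jac
            try:
                cov = np.linalg.inv(jtj) * (ss1 / dfd)
                d = np.diag(cov)
                if (d >= 0).all():
                    se_a, se_b, se_r = np.sqrt(d)
            except np.linalg.LinAlgError:
                pass

    return AsymptoticFit(A=float(a_hat), B=float(b_hat), R=r_hat, p=p,
                         varexp=float(varexp), n_points=n,
                         converged=bool(converged),
                         se_A=float(se_a), se_B=float(se_b), se_R=float(se_r))


def scan_breed(het_values, valid, snp_map: SnpMap, grid_step: int = 50_000,
               bracket_mb: float = 10.0, min_points: int = MIN_POINTS,
               xatol: float = 1e-8) -> pd.DataFrame:
    """Genome scan of the asymptotic-regression statistic for one breed.

    Test positions run from the first to the last SNP of each chromosome in
    ``grid_step`` increments (a chromosome shorter than one step gets a
    single test position at its first SNP).  Each fit uses all valid SNPs
    within ``bracket_mb`` of the test position, distances in Mb.  Positions
    whose fit does not converge or is not in the predicted direction are
    recorded but carry no score (``scored`` False, NaN -log10 p), so they
    drop out of downstream percentile distributions.

    Returns a DataFrame: chrom, pos, A, B, R, p, neglog10p, varexp,
    n_points, direction_ok, scored.
    """
    het_values = np.asarray(het_values, dtype=np.float64)
    valid = np.asarray(valid, dtype=bool) & np.isfinite(het_values)
    bracket_bp = float(bracket_mb) * 1e6
    rows = []
    for chrom in snp_map.chromosomes:
        sl = snp_map.chrom_slice(chrom)
        ok = valid[sl]
        pos = snp_map.pos[sl][ok].astype(np.float64)
        ys = het_values[sl][ok]
        if pos.size == 0:
            continue
        grid = np.arange(pos[0], pos[-1] + 1, grid_step, dtype=np.float64)
        if grid.size == 0:
            grid = np.array([pos[0]])
        for t in grid:
            lo = np.searchsorted(pos, t - bracket_bp, side="left")
            hi = np.searchsorted(pos, t + bracket_bp, side="right")
            npts = hi - lo
            if npts < min_points:
                rows.append((chrom, int(t), np.nan, np.nan, np.nan, np.nan,
                             np.nan, np.nan, int(npts), False, False))
                continue
            xs = np.abs(pos[lo:hi] - t) / 1e6
            fit = fit_asymptotic(xs, ys[lo:hi], xatol=xatol)
            scored = fit.converged and fit.direction_ok
            rows.append((chrom, int(t), fit.A, fit.B, fit.R, fit.p,
                         fit.neglog10p if scored else np.nan, fit.varexp,
                         fit.n_points, fit.direction_ok, scored))
    return pd.DataFrame(rows, columns=["chrom", "pos", "A", "B", "R", "p",
                                       "neglog10p", "varexp", "n_points",
                                       "direction_ok", "scored"])


def _scan_flag_regions(scan: pd.DataFrame, fraction: float, gap: float,
                       method: str, label: str):
    """Top-``fraction`` scored positions of a scan, merged into regions."""
    from .regions import merge_flags

    scored = scan[scan["scored"]]
    n = len(scored)
    k = int(np.floor(fraction * n))
    if n == 0 or k < 1:
        return []
    cutoff = np.sort(scored["neglog10p"].to_numpy())[n - k]
    flagged = scored[scored["neglog10p"] >= cutoff]
    flags = pd.DataFrame({"chrom": flagged["chrom"],
                          "center_pos": flagged["pos"],
                          "start": flagged["pos"], "end": flagged["pos"]})
    return merge_flags(flags, gap=gap, method=method, label=label)


def bracket_compare(scans: dict[float, pd.DataFrame], fraction: float = 0.005,
                    near_fraction: float = 0.01, gap: float = 2e6,
                    label: str = "") -> dict:
    """Compare flagged regions across bracket sizes.

    ``scans`` maps bracket size (Mb) to a :func:`scan_breed` result.
    Returns per-bracket flagged regions (top ``fraction`` of scored
    positions), the near-miss set at ``near_fraction``, and a boolean
    overlap matrix whose (i, j) entry says whether some region flagged at
    bracket i overlaps (>= 1 bp) a region flagged at bracket j.
    """
    if len(scans) < 2:
        raise ValueError("need scans for at least two bracket sizes")
    regions = {br: _scan_flag_regions(s, fraction, gap, "REGRESSION", label)
               for br, s in scans.items()}
    near = {br: _scan_flag_regions(s, near_fraction, gap, "REGRESSION", label)
            for br, s in scans.items()}
    brackets = sorted(scans)
    mat = pd.DataFrame(False, index=brackets, columns=brackets)
    for bi in brackets:
        for bj in brackets:
            mat.loc[bi, bj] = any(
                ri.chrom == rj.chrom and ri.start <= rj.end and rj.start <= ri.end
                for ri in regions[bi] for rj in regions[bj])
    return {"regions": regions, "near_miss": near, "overlap": mat}
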