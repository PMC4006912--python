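"""Random-placement Monte-Carlo test of region/gene overlap enrichment.

Each replicate places every query region independently and uniformly over
all feasible genome positions: a chromosome is chosen with probability
proportional to its number of valid start positions (length - region
length + 1) and the start is uniform among them, so the region always fits
entirely.  The replicate's overlap count is the number of (region, gene)
pairs sharing at least one bp (optionally the number of distinct genes
hit).  The empirical p-value is the fraction of replicates whose count
reaches the observed count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["EnrichmentResult", "count_overlaps", "random_placement_test"]


@dataclass(frozen=True)
class EnrichmentResult:
    n_replicates: int
    observed: int
    p_value: float
    frac_any_overlap: float
    max_overlap: int
    seed: int
    count_mode: str
    histogram: dict  # overlap count -> number of replicates


def _as_interval_arrays(genes) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalize an interval set (DataFrame or (chrom, start, end[, label])
    tuples) to parallel arrays."""
    if isinstance(genes, pd.DataFrame):
        return (genes["chrom"].astype(str).to_numpy(),
                genes["start"].to_numpy(np.int64),
                genes["end"].to_numpy(np.int64))
    rows = list(genes)
    if not rows:
        return (np.empty(0, dtype=object), np.empty(0, np.int64),
                np.empty(0, np.int64))
    chrom = np.asarray([str(r[0]) for r in rows], dtype=object)
    start = np.asarray([int(r[1]) for r in rows], dtype=np.int64)
    end = np.asarray([int(r[2]) for r in rows], dtype=np.int64)
    return chrom, start, end


def count_overlaps(regions, genes, count_mode: str = "pairs") -> int:
    """Observed overlap count between two interval sets (1-based inclusive).

    ``count_mode`` "pairs" counts (region, gene) pairs sharing >= 1 bp;
    "genes" counts distinct genes hit by at least one region.
    """
    rc, rs, re = _as_interval_arrays(regions)
    gc, gs, ge = _as_interval_arrays(genes)
    hit = np.zeros(gc.size, dtype=np.int64)
    for c, s, e in zip(rc, rs, re):
        hit += (gc == c) & (gs <= e) & (ge >= s)
    return int((hit > 0).sum()) if count_mode == "genes" else int(hit.sum())


def random_placement_test(region_lengths, chrom_lengths: dict, genes,
                          observed: int, n_reps: int = 1_000_000,
                          seed: int = 0, count_mode: str = "pairs",
                          plus_one: bool = False) -> EnrichmentResult:
    """Monte-Carlo null distribution of region/gene overlap counts.

    Parameters
    ----------
    region_lengths
        bp length of each query region (regions are placed independently;
        collisions between placed regions are allowed).
    chrom_lengths
        Mapping chromosome -> length (bp) of the placement genome.
    genes
        Interval set to test against (DataFrame with chrom/start/end or
        tuples).
    observed
        Observed overlap count (see :func:`count_overlaps`).
    plus_one
        Apply (k+1)/(n+1) smoothing to the p-value (off by default).

    A region longer than every chromosome is an error.  Deterministic for a
    given seed.
    """
    if count_mode not in ("pairs", "genes"):
        raise ValueError("count_mode must be 'pairs' or 'genes'")
    region_lengths = [int(x) for x in region_lengths]
    if any(x < 1 for x in region_lengths):
        raise ValueError("region lengths must be >= 1 bp")
    chroms = list(chrom_lengths)
    clen = np.array([int(chrom_lengths[c]) for c in chroms], dtype=np.int64)
    gc, gs, ge = _as_interval_arrays(genes)
    gci = {c: np.nonzero(gc == c)[0] for c in chroms}

    rng = np.random.default_rng(seed)
    pair_counts = np.zeros(n_reps, dtype=np.int64)
    gene_hits = (np.zeros((gc.size, n_reps), dtype=bool)
                 if count_mode == "genes" and gc.size else None)

    for length in region_lengths:
        nstarts = clen - length + 1
        eligible = nstarts > 0
        if not eligible.any():
            raise ValueError(f"region of {length} bp fits on no chromosome")
        weights = np.where(eligible, nstarts, 0).astype(np.float64)
        weights /= weights.sum()
        chrom_idx = rng.choice(len(chroms), size=n_reps, p=weights)
        start = (rng.random(n_reps) * nstarts[chrom_idx]).astype(np.int64) + 1
        end = start + length - 1
        for ci, c in enumerate(chroms):
            on_c = chrom_idx == ci
            if not on_c.any():
                continue
            for g in gci.get(c, ()):
                ov = on_c & (start <= ge[g]) & (end >= gs[g])
                pair_counts += ov
                if gene_hits is not None:
                    gene_hits[g] |= ov

    counts = (gene_hits.sum(axis=0) if gene_hits is not None
              else pair_counts if count_mode == "pairs"
              else np.zeros(n_reps, dtype=np.int64))
    k = int((counts >= observed).sum())
    p = (k + 1) / (n_reps + 1) if plus_one else k / n_reps
    hist_vals = np.bincount(counts)
    return EnrichmentResult(
        n_replicates=n_reps, observed=int(observed), p_value=float(p),
        frac_any_overlap=float((counts > 0).mean()),
        max_overlap=int(counts.max()) if n_reps else 0,
        seed=int(seed), count_mode=count_mode,
        histogram={i: int(v) for i, v in enumerate(hist_vals) if v})
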