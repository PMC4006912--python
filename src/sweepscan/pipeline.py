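"""End-to-end scan orchestration: statistics -> windows -> thresholds ->
regions -> consensus -> CCR, with optional enrichment and TSV reports.

Default parameters are the scan protocol the package implements: 9-SNP
sliding windows, top/bottom 0.5th-percentile empirical thresholds computed
genome-wide per breed (heterozygosity) or breed pair (F_ST), a 50-kb
regression test grid with 5/10/20-Mb brackets (10 Mb feeding the CCR
step), a 2-Mb merge/consensus gap, and support from at least two dairy
breeds or two breed pairs sharing no breed.

Reruns with the same inputs and configuration produce byte-identical TSV
outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .diversity import fst_wc_track, normalized_window_het, obs_het_track
from .enrichment import EnrichmentResult, count_overlaps, random_placement_test
from .io import write_regions, write_table
from .regions import consensus, intersect_ccr, merge_flags, pair_label
from .regression import scan_breed
from .windows import empirical_threshold, flag_extremes, sliding_window_mean

log = logging.getLogger("sweepscan")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Protocol parameters for one full scan."""

    pairs: tuple[tuple[str, str], ...]  # (dairy breed, non-dairy partner)
    window_size: int = 9
    fraction: float = 0.005
    grid_step: int = 50_000
    brackets_mb: tuple[float, ...] = (5.0, 10.0, 20.0)
    ccr_bracket_mb: float = 10.0
    merge_gap: int = 2_000_000
    min_support: int = 2
    truncate_negative_fst: bool = False
    regression_breeds: str = "all"  # "all" breeds in the design, or "dairy"
    enrichment_reps: int = 1_000_000
    enrichment_seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "pairs", tuple(map(tuple, self.pairs)))
        object.__setattr__(self, "brackets_mb",
                           tuple(float(b) for b in self.brackets_mb))
        if not self.pairs:
            raise ValueError("need at least one breed pair")
        if self.ccr_bracket_mb not in self.brackets_mb:
            raise ValueError("ccr_bracket_mb must be one of brackets_mb")
        if self.regression_breeds not in ("all", "dairy"):
            raise ValueError("regression_breeds must be 'all' or 'dairy'")


@dataclass
class PipelineResult:
    """All tracks, region tables and counts one run produced."""

    config: PipelineConfig
    fst_windows: dict = field(default_factory=dict)      # pair label -> df
    het_windows: dict = field(default_factory=dict)      # breed -> df
    nobshtz: dict = field(default_factory=dict)          # breed -> df
    reg_scans: dict = field(default_factory=dict)        # (breed, bracket) -> df
    fst_regions: dict = field(default_factory=dict)      # label -> [CandidateRegion]
    obshtz_regions: dict = field(default_factory=dict)
    regression_regions: dict = field(default_factory=dict)
    fst_consensus: list = field(default_factory=list)
    obshtz_consensus: list = field(default_factory=list)
    regression_consensus: list = field(default_factory=list)
    ccrs: list = field(default_factory=list)
    enrichment: EnrichmentResult | None = None
    counts: dict = field(default_factory=dict)

    def manifest(self) -> dict:
        return {"package": "sweepscan", "version": __version__,
                "config": asdict(self.config), "counts": self.counts}


def _window_flag_merge(track_df, snp_map, cfg, tail, method, label):
    """Shared windows->threshold->flags->regions path for F_ST and ObsHtz."""
    windows = sliding_window_mean(track_df["value"].to_numpy(),
                                  track_df["valid"].to_numpy(),
                                  snp_map, size=cfg.window_size)
    cutoff = empirical_threshold(windows["mean"], tail, cfg.fraction)
    flagged = flag_extremes(windows, cutoff, tail)
    regs = merge_flags(flagged, gap=cfg.merge_gap, method=method, label=label)
    return windows, flagged, regs


def run_pipeline(dataset, config: PipelineConfig, outdir=None, genes=None,
                 chrom_lengths=None) -> PipelineResult:
    """Run the full scan on a dataset (simulated or read from files).

    ``dataset`` must expose ``snp_map``, ``genotypes`` (breed ->
    GenotypeMatrix) and ``dairy`` (breed -> bool) — both
    :class:`~sweepscan.simulate.SimulatedDataset` and the tuple returned by
    :func:`~sweepscan.io.read_genotypes` (via :func:`as_dataset`) qualify.
    When ``genes`` (an interval set) and ``chrom_lengths`` are given, the
    random-placement enrichment test runs on the emitted CCRs.

    Any stage failure aborts with an error naming the stage.
    """
    cfg = config
    res = PipelineResult(config=cfg)
    genotypes, snp_map, dairy = dataset.genotypes, dataset.snp_map, dataset.dairy
    dairy_breeds = {b for b, flag in dairy.items() if flag}

    for d, nd in cfg.pairs:
        for b in (d, nd):
            if b not in genotypes:
                raise ValueError(f"pair breed {b!r} not in dataset")

    # --- stage 1: pairwise F_ST ------------------------------------------
    try:
        for d, nd in cfg.pairs:
            lbl = pair_label(d, nd)
            track = fst_wc_track(genotypes[d], genotypes[nd],
                                 cfg.truncate_negative_fst)
            windows, flagged, regs = _window_flag_merge(
                track, snp_map, cfg, "upper", "FST", lbl)
            res.fst_windows[lbl] = windows
            res.fst_regions[lbl] = regs
            log.info("FST %s: %d windows, %d flagged, %d regions",
                     lbl, len(windows), len(flagged), len(regs))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'fst' failed: {exc}") from exc

    # --- stage 2: observed heterozygosity --------------------------------
    breeds_in_design = list(dict.fromkeys(b for pr in cfg.pairs for b in pr))
    het_tracks = {}
    try:
        for breed in breeds_in_design:
            track = obs_het_track(genotypes[breed])
            het_tracks[breed] = track
            windows, flagged, regs = _window_flag_merge(
                track, snp_map, cfg, "lower", "OBSHTZ", breed)
            zw = windows.copy()
            zw["z"] = normalized_window_het(windows["mean"].to_numpy())
            res.het_windows[breed] = windows
            res.nobshtz[breed] = zw
            res.obshtz_regions[breed] = regs
            log.info("ObsHtz %s: %d windows, %d flagged, %d regions",
                     breed, len(windows), len(flagged), len(regs))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'het' failed: {exc}") from exc

    # --- stage 3: asymptotic-regression scan ------------------------------
    reg_breeds = (breeds_in_design if cfg.regression_breeds == "all"
                  else [b for b in breeds_in_design if b in dairy_breeds])
    try:
        from .regression import _scan_flag_regions
        for breed in reg_breeds:
            track = het_tracks[breed]
            for bracket in cfg.brackets_mb:
                scan = scan_breed(track["value"].to_numpy(),
                                  track["valid"].to_numpy(), snp_map,
                                  grid_step=cfg.grid_step, bracket_mb=bracket)
                res.reg_scans[(breed, bracket)] = scan
                if bracket == cfg.ccr_bracket_mb:
                    regs = _scan_flag_regions(scan, cfg.fraction,
                                              cfg.merge_gap, "REGRESSION",
                                              breed)
                    res.regression_regions[breed] = regs
                    log.info("Regression %s (%g Mb): %d scored, %d regions",
                             breed, bracket, int(scan["scored"].sum()),
                             len(regs))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'regscan' failed: {exc}") from exc

    # --- stage 4: consensus and CCR ---------------------------------------
    try:
        all_fst = [r for regs in res.fst_regions.values() for r in regs]
        all_oh = [r for regs in res.obshtz_regions.values() for r in regs]
        all_rg = [r for regs in res.regression_regions.values() for r in regs]
        res.fst_consensus = consensus(all_fst, "FST",
                                      min_support=cfg.min_support,
                                      gap=cfg.merge_gap)
        res.obshtz_consensus = consensus(all_oh, "HET", dairy_breeds,
                                         cfg.min_support, cfg.merge_gap)
        res.regression_consensus = consensus(all_rg, "HET", dairy_breeds,
                                             cfg.min_support, cfg.merge_gap)
        res.ccrs = intersect_ccr(res.fst_consensus, res.obshtz_consensus,
                                 res.regression_consensus)
        log.info("consensus: %d FST, %d ObsHtz, %d Regression -> %d CCRs",
                 len(res.fst_consensus), len(res.obshtz_consensus),
                 len(res.regression_consensus), len(res.ccrs))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'regions' failed: {exc}") from exc

    # --- stage 5: optional enrichment -------------------------------------
    if genes is not None and res.ccrs:
        try:
            if chrom_lengths is None:
                chrom_lengths = getattr(dataset, "config", None) and \
                    dataset.config.chrom_lengths
            if chrom_lengths is None:
                raise ValueError("chrom_lengths required for enrichment")
            observed = count_overlaps(
                [(c.chrom, c.start, c.end) for c in res.ccrs], genes)
            res.enrichment = random_placement_test(
                [c.end - c.start + 1 for c in res.ccrs], chrom_lengths,
                genes, observed, n_reps=cfg.enrichment_reps,
                seed=cfg.enrichment_seed)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage 'enrich' failed: {exc}") from exc

    res.counts = {
        "snps": int(snp_map.n_snps),
        "fst_windows": {k: len(v) for k, v in res.fst_windows.items()},
        "het_windows": {k: len(v) for k, v in res.het_windows.items()},
        "fst_regions": {k: len(v) for k, v in res.fst_regions.items()},
        "obshtz_regions": {k: len(v) for k, v in res.obshtz_regions.items()},
        "regression_regions": {k: len(v)
                               for k, v in res.regression_regions.items()},
        "fst_consensus": len(res.fst_consensus),
        "obshtz_consensus": len(res.obshtz_consensus),
        "regression_consensus": len(res.regression_consensus),
        "ccrs": len(res.ccrs),
    }
    if outdir is not None:
        write_outputs(res, outdir)
    return res


def write_outputs(res: PipelineResult, outdir) -> None:
    """Write every track and region table as TSV plus a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for lbl, df in res.fst_windows.items():
        write_table(df, outdir / f"fst_windows.{lbl}.tsv")
    for breed, df in res.het_windows.items():
        write_table(df, outdir / f"obshtz_windows.{breed}.tsv")
    for breed, df in res.nobshtz.items():
        write_table(df, outdir / f"nobshtz_windows.{breed}.tsv")
    for (breed, bracket), df in res.reg_scans.items():
        write_table(df, outdir / f"regscan.{breed}.bracket{bracket:g}.tsv")
    for name, table in (("fst", res.fst_regions),
                        ("obshtz", res.obshtz_regions),
                        ("regression", res.regression_regions)):
        regs = [r for rr in table.values() for r in rr]
        write_regions(regs, outdir / f"candidate_regions.{name}.tsv")
    write_regions(res.fst_consensus, outdir / "consensus.fst.tsv")
    write_regions(res.obshtz_consensus, outdir / "consensus.obshtz.tsv")
    write_regions(res.regression_consensus, outdir / "consensus.regression.tsv")
    write_regions(res.ccrs, outdir / "ccr.tsv")
    write_regions(res.ccrs, outdir / "ccr.bed", dialect="bed")
    if res.enrichment is not None:
        e = res.enrichment
        write_table(pd.DataFrame([{
            "n_replicates": e.n_replicates, "observed": e.observed,
            "p_value": e.p_value, "frac_any_overlap": e.frac_any_overlap,
            "max_overlap": e.max_overlap, "seed": e.seed,
            "count_mode": e.count_mode}]), outdir / "enrichment.tsv")
        write_table(pd.DataFrame({"overlap_count": list(e.histogram),
                                  "replicates": list(e.histogram.values())}),
                    outdir / "enrichment_histogram.tsv")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(res.manifest(), fh, indent=2, sort_keys=True)
        fh.write("\n")


@dataclass
class Dataset:
    """Minimal dataset container for genotypes read from files."""

    snp_map: object
    genotypes: dict
    dairy: dict


def as_dataset(genotypes, snp_map, dairy) -> Dataset:
    """Wrap :func:`sweepscan.io.read_genotypes` output for the pipeline."""
    return Dataset(snp_map=snp_map, genotypes=genotypes, dairy=dairy)
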