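"""Synthetic multi-breed SNP-chip genotype datasets with implanted sweeps.

The generator emulates a medium-density array dataset over ~26 autosomes:
SNPs spaced ~50-60 kb apart, ancestral allele frequencies bounded away
from fixation (array ascertainment), breed-specific drift under the
Balding-Nichols model (each breed's frequency is Beta-distributed with
mean equal to the ancestral frequency and variance drift_f * p * (1 - p)),
Hardy-Weinberg genotype sampling within breed, and optional uniform
missingness.

A selective sweep is implanted directly on the frequency vector of its
carrier breeds: every SNP at distance d from the swept locus is pulled
toward the nearer of {0, 1} by the factor intensity * exp(-d / decay),
so expected heterozygosity collapses at the locus and recovers
asymptotically with distance — the signal class all three scan statistics
are designed to detect.  The implanted sweeps are the dataset's ground
truth and are emitted alongside the genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, SnpMap, write_chrom_lengths, write_genotypes

__all__ = ["BreedSpec", "SweepSpec", "SimulationConfig", "SimulatedDataset",
           "build_snp_map", "simulate_breed_frequencies", "apply_sweep",
           "sample_genotypes", "simulate_dataset", "write_dataset",
           "table1_breeds", "table1_pairs"]


@dataclass(frozen=True)
class BreedSpec:
    """One breed: sample size, drift from the ancestral pool, dairy flag."""

    name: str
    n_individuals: int
    drift_f: float
    is_dairy: bool = False

    def __post_init__(self):
        if self.n_individuals < 2:
            raise ValueError(f"breed {self.name!r}: need >= 2 individuals")
        if not 0.0 <= self.drift_f < 1.0:
            raise ValueError(f"breed {self.name!r}: drift_f must be in [0, 1)")


@dataclass(frozen=True)
class SweepSpec:
    """One implanted sweep: carriers, locus, pull strength, recovery scale."""

    breed_names: tuple[str, ...]
    chromosome: str
    locus_bp: int
    intensity: float
    decay_scale_bp: float

    def __post_init__(self):
        object.__setattr__(self, "breed_names", tuple(self.breed_names))
        object.__setattr__(self, "chromosome", str(self.chromosome))
        if not 0.0 <= self.intensity <= 1.0:
            raise ValueError("sweep intensity must be in [0, 1]")
        if self.decay_scale_bp <= 0:
            raise ValueError("decay_scale_bp must be positive")


def table1_breeds() -> tuple[BreedSpec, ...]:
    """The ten-breed study panel: five dairy breeds, each with a related
    non-dairy partner, at the study's sample sizes.

    The drift coefficients are generator choices tuned so that pairwise
    genome-wide differentiation falls in the 0.05-0.3 background range
    typical of related sheep breeds.
    """
    return (
        BreedSpec("Chios", 23, 0.09, True),
        BreedSpec("Churra", 96, 0.05, True),
        BreedSpec("Comisana", 24, 0.08, True),
        BreedSpec("EastFriesianBrown", 39, 0.15, True),
        BreedSpec("MilkLacaune", 103, 0.04, True),
        BreedSpec("AustralianPollMerino", 98, 0.08, False),
        BreedSpec("MeatLacaune", 78, 0.04, False),
        BreedSpec("Ojalada", 24, 0.06, False),
        BreedSpec("Sakiz", 22, 0.09, False),
        BreedSpec("Finnsheep", 99, 0.15, False),
    )


def table1_pairs() -> tuple[tuple[str, str], ...]:
    """The six dairy / non-dairy contrasts of the study design."""
    return (("Chios", "Sakiz"),
            ("Churra", "Ojalada"),
            ("Comisana", "AustralianPollMerino"),
            ("EastFriesianBrown", "Finnsheep"),
            ("MilkLacaune", "AustralianPollMerino"),
            ("MilkLacaune", "MeatLacaune"))


@dataclass(frozen=True)
class SimulationConfig:
    """Full generator configuration; defaults emulate the study dataset
    (26 autosomes, ~55-kb SNP spacing, the ten-breed panel, no sweeps)."""

    n_chromosomes: int = 26
    chrom_length_bp: int = 100_000_000
    snp_spacing_bp: int = 55_000
    breeds: tuple[BreedSpec, ...] = field(default_factory=table1_breeds)
    sweeps: tuple[SweepSpec, ...] = ()
    missing_rate: float = 0.0
    ancestral_range: tuple[float, float] = (0.05, 0.95)
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "breeds", tuple(self.breeds))
        object.__setattr__(self, "sweeps", tuple(self.sweeps))
        if self.n_chromosomes < 1:
            raise ValueError("need at least one chromosome")
        if self.chrom_length_bp < 1:
            raise ValueError("zero-length chromosome")
        if self.snp_spacing_bp <= 0:
            raise ValueError("snp_spacing_bp must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        names = [b.name for b in self.breeds]
        if len(set(names)) != len(names):
            raise ValueError("duplicate breed names")
        chrom_names = {str(i + 1) for i in range(self.n_chromosomes)}
        for sw in self.sweeps:
            if sw.chromosome not in chrom_names:
                raise ValueError(f"sweep on unknown chromosome {sw.chromosome!r}")
            if not 1 <= sw.locus_bp <= self.chrom_length_bp:
                raise ValueError("sweep locus outside its chromosome")
            unknown = set(sw.breed_names) - set(names)
            if unknown:
                raise ValueError(f"sweep names unknown breeds: {sorted(unknown)}")

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(str(i + 1) for i in range(self.n_chromosomes))

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.chrom_length_bp for c in self.chrom_names}


# ---------------------------------------------------------------------------
# generator stages
# ---------------------------------------------------------------------------

def build_snp_map(config: SimulationConfig) -> SnpMap:
    """Place SNPs along each chromosome with jittered spacing.

    Inter-SNP distances are uniform on [0.5, 1.5] x snp_spacing_bp (mean
    equal to the nominal spacing), the first SNP falls within one spacing
    of the chromosome start, and positions are strictly increasing.
    Deterministic given the config seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    chrom, snp_id, pos = [], [], []
    s = config.snp_spacing_bp
    for c in config.chrom_names:
        # generous draw, then truncate at chromosome end
        n_draw = int(config.chrom_length_bp / s * 1.2) + 16
        steps = np.maximum(1, np.round(
            rng.uniform(0.5, 1.5, size=n_draw) * s)).astype(np.int64)
        first = int(rng.integers(1, s + 1))
        p = first + np.concatenate([[0], np.cumsum(steps)])
        p = p[p <= config.chrom_length_bp]
        while p[-1] + steps.sum() <= config.chrom_length_bp:  # pragma: no cover
            extra = np.maximum(1, np.round(
                rng.uniform(0.5, 1.5, size=n_draw) * s)).astype(np.int64)
            p = np.concatenate([p, p[-1] + np.cumsum(extra)])
            p = p[p <= config.chrom_length_bp]
        chrom.extend([c] * len(p))
        snp_id.extend(f"OAR{c}_{int(x)}" for x in p)
        pos.extend(p)
    return SnpMap(chrom, snp_id, pos)


def simulate_breed_frequencies(snp_map: SnpMap, breeds, seed: int,
                               ancestral_range: tuple[float, float] = (0.05, 0.95)
                               ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Balding-Nichols allele frequencies for each breed.

    The ancestral frequency per SNP is uniform on [0.05, 0.95] (array SNPs
    are ascertained to be polymorphic); each breed then draws from
    Beta(p(1-F)/F, (1-p)(1-F)/F), which has mean p and variance
    F p (1-p).  A breed with drift_f = 0 keeps the ancestral frequencies
    exactly.
    """
    if snp_map.n_snps == 0:
        raise ValueError("empty SNP map")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    lo, hi = ancestral_range
    if not 0.0 < lo <= hi < 1.0:
        raise ValueError("ancestral_range must be inside (0, 1)")
    anc = rng.uniform(lo, hi, size=snp_map.n_snps)
    freqs: dict[str, np.ndarray] = {}
    for b in breeds:
        if b.drift_f == 0.0:
            freqs[b.name] = anc.copy()
            continue
        f = b.drift_f
        alpha = anc * (1.0 - f) / f
        beta = (1.0 - anc) * (1.0 - f) / f
        freqs[b.name] = rng.beta(alpha, beta)
    return anc, freqs


def apply_sweep(frequencies: dict[str, np.ndarray], sweep: SweepSpec,
                snp_map: SnpMap) -> dict[str, np.ndarray]:
    """Implant one sweep: pull carrier-breed frequencies toward fixation.

    At distance d from the locus the pull factor is
    intensity * exp(-d / decay_scale_bp) and each frequency moves that
    fraction of the way to the nearer of {0, 1} (ties at 0.5 go to 1).
    Returns a new frequency table; non-carrier breeds are untouched.
    """
    unknown = set(sweep.breed_names) - set(frequencies)
    if unknown:
        raise ValueError(f"sweep names unknown breeds: {sorted(unknown)}")
    if sweep.chromosome not in snp_map.chromosomes:
        raise ValueError(f"sweep chromosome {sweep.chromosome!r} not in map")
    sl = snp_map.chrom_slice(sweep.chromosome)
    d = np.abs(snp_map.pos[sl].astype(np.float64) - sweep.locus_bp)
    pull = sweep.intensity * np.exp(-d / sweep.decay_scale_bp)
    out = {name: p.copy() for name, p in frequencies.items()}
    for name in sweep.breed_names:
        p = out[name][sl]
        target = (p >= 0.5).astype(np.float64)
        out[name][sl] = p + pull * (target - p)
    return out


def sample_genotypes(frequencies: dict[str, np.ndarray], breeds, seed: int,
                     missing_rate: float = 0.0, snp_map: SnpMap | None = None
                     ) -> dict[str, GenotypeMatrix]:
    """Draw Binomial(2, p) genotypes per breed under Hardy-Weinberg.

    Missing calls (code -1) are applied uniformly at ``missing_rate``.
    Deterministic given the seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    out: dict[str, GenotypeMatrix] = {}
    for b in breeds:
        p = np.asarray(frequencies[b.name], dtype=np.float64)
        if (p < 0).any() or (p > 1).any():
            raise ValueError("frequencies outside [0, 1]")
        calls = rng.binomial(2, p, size=(b.n_individuals, p.size)).astype(np.int8)
        if missing_rate > 0.0:
            mask = rng.random(calls.shape) < missing_rate
            calls[mask] = -1
        ids = [f"{b.name}_{i + 1:04d}" for i in range(b.n_individuals)]
        out[b.name] = GenotypeMatrix(calls, ids, snp_map) if snp_map is not None \
            else GenotypeMatrix(calls, ids, _bare_map(p.size))
    return out


def _bare_map(n: int) -> SnpMap:
    """Placeholder single-chromosome map for map-less frequency tables."""
    return SnpMap(["1"] * n, [f"snp{i}" for i in range(n)],
                  np.arange(1, n + 1) * 1000)


@dataclass
class SimulatedDataset:
    """Everything one simulation run produced, ground truth included."""

    config: SimulationConfig
    snp_map: SnpMap
    ancestral: np.ndarray
    frequencies: dict[str, np.ndarray]
    genotypes: dict[str, GenotypeMatrix]

    @property
    def dairy(self) -> dict[str, bool]:
        return {b.name: b.is_dairy for b in self.config.breeds}

    @property
    def truth(self) -> pd.DataFrame:
        rows = [(" +".join(sw.breed_names).replace(" ", ""), sw.chromosome,
                 sw.locus_bp, sw.intensity, sw.decay_scale_bp)
                for sw in self.config.sweeps]
        return pd.DataFrame(rows, columns=["breeds", "chrom", "locus_bp",
                                           "intensity", "decay_scale_bp"])


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the full generator: map, drift, sweeps, genotype sampling."""
    snp_map = build_snp_map(config)
    anc, freqs = simulate_breed_frequencies(snp_map, config.breeds, config.seed,
                                            config.ancestral_range)
    for sw in config.sweeps:
        freqs = apply_sweep(freqs, sw, snp_map)
    genotypes = sample_genotypes(freqs, config.breeds, config.seed,
                                 config.missing_rate, snp_map)
    return SimulatedDataset(config=config, snp_map=snp_map, ancestral=anc,
                            frequencies=freqs, genotypes=genotypes)


def write_dataset(dataset: SimulatedDataset, prefix) -> None:
    """Write PLINK text genotypes, breed table, chromosome lengths and the
    sweep-truth TSV under ``<prefix>.*``."""
    prefix = Path(prefix)
    write_genotypes(dataset.genotypes, dataset.dairy, prefix)
    write_chrom_lengths(dataset.config.chrom_lengths,
                        f"{prefix}.chrom_lengths.tsv")
    dataset.truth.to_csv(f"{prefix}.truth.tsv", sep="\t", index=False)


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Convenience: same generator conditions, different seed."""
    return replace(config, seed=seed)
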