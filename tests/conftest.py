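"""Shared fixtures: small simulated datasets with known ground truth."""

from __future__ import annotations

import numpy as np
import pytest

from sweepscan import (BreedSpec, PipelineConfig, SimulationConfig, SweepSpec,
                       simulate_dataset)

SWEEP_LOCUS = 10_000_000
SWEEP_CHROM = "1"


def four_breed_config(seed: int, sweep: bool = True,
                      chrom_length: int = 20_000_000,
                      n_individuals: int = 40) -> SimulationConfig:
    """Two dairy + two non-dairy breeds on two chromosomes; one strong
    dairy sweep on chromosome 1 when ``sweep`` is set."""
    breeds = (BreedSpec("D1", n_individuals, 0.06, True),
              BreedSpec("N1", n_individuals, 0.06, False),
              BreedSpec("D2", n_individuals, 0.06, True),
              BreedSpec("N2", n_individuals, 0.06, False))
    sweeps = (SweepSpec(("D1", "D2"), SWEEP_CHROM, SWEEP_LOCUS, 0.9,
                        1_000_000),) if sweep else ()
    return SimulationConfig(n_chromosomes=2, chrom_length_bp=chrom_length,
                            snp_spacing_bp=50_000, breeds=breeds,
                            sweeps=sweeps, seed=seed)


@pytest.fixture(scope="session")
def sweep_dataset():
    """One simulated dataset with an implanted dairy sweep at 10 Mb."""
    return simulate_dataset(four_breed_config(seed=3))


@pytest.fixture(scope="session")
def pipeline_config() -> PipelineConfig:
    return PipelineConfig(pairs=(("D1", "N1"), ("D2", "N2")),
                          brackets_mb=(10.0,), ccr_bracket_mb=10.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20140501)
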