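"""Synthetic-data generator: maps, drift, sweeps, genotype sampling."""

import numpy as np
import pytest

from sweepscan import (BreedSpec, SimulationConfig, SnpMap, SweepSpec,
                       apply_sweep, build_snp_map, fst_wc_values,
                       sample_genotypes, simulate_breed_frequencies,
                       simulate_dataset, sliding_window_mean, obs_het_values)

from conftest import four_breed_config


def small_map(n_chrom=1, length=10_000_000, spacing=50_000, seed=0):
    return build_snp_map(SimulationConfig(
        n_chromosomes=n_chrom, chrom_length_bp=length, snp_spacing_bp=spacing,
        breeds=(BreedSpec("b1", 5, 0.0), BreedSpec("b2", 5, 0.0)), seed=seed))


class TestSnpMap:
    def test_positions_increasing_and_in_range(self):
        m = small_map()
        assert m.pos[0] >= 1 and m.pos[-1] <= 10_000_000
        assert (np.diff(m.pos) > 0).all()
        # ~200 SNPs forced by length/spacing
        assert 150 <= m.n_snps <= 250

    def test_seed_determinism(self):
        a, b = small_map(seed=7), small_map(seed=7)
        assert np.array_equal(a.pos, b.pos)
        assert np.array_equal(a.snp_id, b.snp_id)

    def test_genome_wide_count_matches_spacing_expectation(self):
        m = build_snp_map(SimulationConfig(
            n_chromosomes=26, chrom_length_bp=100_000_000,
            snp_spacing_bp=60_000,
            breeds=(BreedSpec("b1", 5, 0.0), BreedSpec("b2", 5, 0.0)),
            seed=1))
        expected = 26 * 100_000_000 / 60_000
        assert abs(m.n_snps - expected) / expected < 0.05

    def test_zero_length_chromosome_rejected(self):
        with pytest.raises(ValueError, match="length"):
            SimulationConfig(n_chromosomes=1, chrom_length_bp=0,
                             breeds=(BreedSpec("b1", 5, 0.0),
                                     BreedSpec("b2", 5, 0.0)))

    def test_sweep_outside_chromosome_rejected(self):
        with pytest.raises(ValueError, match="locus"):
            SimulationConfig(
                n_chromosomes=1, chrom_length_bp=1_000_000,
                breeds=(BreedSpec("b1", 5, 0.0),),
                sweeps=(SweepSpec(("b1",), "1", 2_000_000, 0.5, 1e5),))


class TestDrift:
    def test_zero_drift_equals_ancestral(self):
        m = small_map()
        anc, freqs = simulate_breed_frequencies(
            m, [BreedSpec("b", 10, 0.0)], seed=5)
        assert np.array_equal(freqs["b"], anc)
        assert anc.min() >= 0.05 and anc.max() <= 0.95

    def test_balding_nichols_fst_scale(self):
        """Mean WC F_ST between two drift-F breeds sits on the F scale and
        agrees with a large-sample frequency-level oracle, averaged over
        replicate simulations.

        The oracle plugs the drawn frequencies into the infinite-sample
        limit of the variance components (a -> s2, b -> pq - s2/2 - h/2,
        c -> h/2 with HWE heterozygosity), bypassing genotype sampling.
        """
        drift = 0.05
        breeds = [BreedSpec("b1", 200, drift), BreedSpec("b2", 200, drift)]
        m = small_map(length=50_000_000, spacing=2_500)  # ~20k SNPs
        est_means, oracle_means = [], []
        for rep in range(10):
            _, freqs = simulate_breed_frequencies(m, breeds, seed=100 + rep)
            genos = sample_genotypes(freqs, breeds, seed=100 + rep, snp_map=m)
            fst, valid, _, _ = fst_wc_values(genos["b1"].calls,
                                             genos["b2"].calls)
            est_means.append(np.nanmean(fst[valid]))
            p1, p2 = freqs["b1"], freqs["b2"]
            s2 = (p1 - p2) ** 2 / 2.0
            pbar = (p1 + p2) / 2.0
            hbar = p1 * (1 - p1) + p2 * (1 - p2)  # HWE het, 2-pop average
            denom = s2 + (pbar * (1 - pbar) - s2 / 2.0 - hbar / 2.0) + hbar / 2.0
            poly = denom > 0
            oracle_means.append(np.mean(s2[poly] / denom[poly]))
        assert abs(np.mean(est_means) - np.mean(oracle_means)) <= 0.02
        assert abs(np.mean(est_means) - drift) <= 0.02

    def test_fst_monotone_in_drift(self):
        breeds = [BreedSpec("hi1", 150, 0.3), BreedSpec("hi2", 150, 0.3),
                  BreedSpec("lo1", 150, 0.05), BreedSpec("lo2", 150, 0.05)]
        m = small_map(length=25_000_000, spacing=5_000)
        _, freqs = simulate_breed_frequencies(m, breeds, seed=11)
        genos = sample_genotypes(freqs, breeds, seed=11, snp_map=m)
        hi, v1, _, _ = fst_wc_values(genos["hi1"].calls, genos["hi2"].calls)
        lo, v2, _, _ = fst_wc_values(genos["lo1"].calls, genos["lo2"].calls)
        assert np.nanmean(hi[v1]) > np.nanmean(lo[v2])


class TestSweep:
    def _setup(self, decay=500_000, intensity=0.9):
        m = small_map(length=10_000_000, spacing=5_000, seed=2)
        anc, freqs = simulate_breed_frequencies(
            m, [BreedSpec("b", 10, 0.05)], seed=2)
        sweep = SweepSpec(("b",), "1", 5_000_000, intensity, decay)
        return m, freqs, apply_sweep(freqs, sweep, m), sweep

    def test_intensity_zero_is_identity(self):
        m, freqs, _, _ = self._setup()
        swept = apply_sweep(freqs, SweepSpec(("b",), "1", 5_000_000, 0.0,
                                             5e5), m)
        assert np.array_equal(swept["b"], freqs["b"])

    def test_full_intensity_fixes_locus(self):
        m = SnpMap(["1"] * 3, ["s1", "s2", "s3"], [1_000, 5_000, 9_000])
        freqs = {"b": np.array([0.4, 0.7, 0.2])}
        swept = apply_sweep(freqs, SweepSpec(("b",), "1", 5_000, 1.0, 1e5), m)
        p = swept["b"][1]
        assert p in (0.0, 1.0)
        assert 2 * p * (1 - p) == 0.0

    def test_het_recovery_monotone_with_distance(self):
        """Brute-force 1-Mb binning: the swept/unswept expected-het ratio
        is non-decreasing with distance from the locus."""
        m, freqs, swept, sweep = self._setup()
        d = np.abs(m.pos - sweep.locus_bp)
        p0, p1 = freqs["b"], swept["b"]
        ratio = (2 * p1 * (1 - p1)) / (2 * p0 * (1 - p0))
        bins = (d // 1_000_000).astype(int)
        bin_means = [ratio[bins == b].mean() for b in range(bins.max() + 1)]
        assert all(np.diff(bin_means) >= -1e-3)
        # het near the locus is reduced by at least the pull^2 fraction
        nearest = int(np.argmin(d))
        pull = sweep.intensity * np.exp(-d[nearest] / sweep.decay_scale_bp)
        assert ratio[nearest] <= 1 - pull ** 2 + 1e-9

    def test_unknown_carrier_breed_rejected(self):
        m, freqs, _, _ = self._setup()
        with pytest.raises(ValueError, match="unknown"):
            apply_sweep(freqs, SweepSpec(("nope",), "1", 5_000_000, 0.5, 1e5),
                        m)


class TestGenotypes:
    def test_fixed_frequency_gives_uniform_genotypes(self):
        breeds = [BreedSpec("b", 50, 0.0)]
        genos = sample_genotypes({"b": np.zeros(20)}, breeds, seed=1)
        assert (genos["b"].calls == 0).all()

    def test_het_fraction_at_half(self):
        breeds = [BreedSpec("b", 1000, 0.0)]
        genos = sample_genotypes({"b": np.full(1, 0.5)}, breeds, seed=9)
        het = (genos["b"].calls == 1).mean()
        assert abs(het - 0.5) <= 0.03

    def test_missing_rate_applied(self):
        breeds = [BreedSpec("b", 200, 0.0)]
        genos = sample_genotypes({"b": np.full(200, 0.5)}, breeds, seed=4,
                                 missing_rate=0.1)
        frac = (genos["b"].calls == -1).mean()
        assert 0.07 <= frac <= 0.13

    def test_full_generator_seed_determinism(self):
        a = simulate_dataset(four_breed_config(seed=17))
        b = simulate_dataset(four_breed_config(seed=17))
        for breed in a.genotypes:
            assert np.array_equal(a.genotypes[breed].calls,
                                  b.genotypes[breed].calls)
        assert np.array_equal(a.snp_map.pos, b.snp_map.pos)


def test_truth_table_lists_implanted_sweeps(sweep_dataset):
    truth = sweep_dataset.truth
    assert len(truth) == 1
    row = truth.iloc[0]
    assert row["chrom"] == "1" and row["locus_bp"] == 10_000_000
    assert row["intensity"] == 0.9


def test_neutral_window_het_has_no_position_trend():
    """Without sweeps, window heterozygosity is flat along the chromosome:
    the across-replicate mean slope of het vs position is consistent with
    zero."""
    from scipy import stats

    slopes = []
    for rep in range(20):
        cfg = SimulationConfig(
            n_chromosomes=1, chrom_length_bp=10_000_000, snp_spacing_bp=50_000,
            breeds=(BreedSpec("b", 40, 0.06, True),
                    BreedSpec("c", 40, 0.06, False)),
            seed=500 + rep)
        ds = simulate_dataset(cfg)
        het, valid, _ = obs_het_values(ds.genotypes["b"].calls)
        win = sliding_window_mean(het, valid, ds.snp_map)
        slopes.append(np.polyfit(win["center_pos"] / 1e6, win["mean"], 1)[0])
    t = stats.ttest_1samp(slopes, 0.0)
    assert t.pvalue > 1e-3
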