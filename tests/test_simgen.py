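"""Founder generation, Wright-Fisher evolution, pool sampling, phenotypes."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from evoreseq import simgen
from evoreseq.simgen import SimConfig, SimConfigError

from oracles import ols_slope_oracle


def small_config(**overrides):
    base = dict(
        genome_size_mb=10.0,
        n_sites_standing=100,
        ems_rate_per_mb=2.0,
        n_founders=20,
        n_populations=2,
        pop_size=50,
        n_generations=7,
        seed=11,
    )
    base.update(overrides)
    return SimConfig(**base)


def make_founders_with_freq(p0: float, n_sites: int, config: SimConfig):
    """Founder set whose realized frequency is exactly p0 at every site."""
    n_copies = int(round(p0 * 2 * config.n_founders))
    genotypes = np.zeros((n_sites, config.n_founders), dtype=np.int8)
    dosage = np.zeros(config.n_founders, dtype=np.int8)
    full, rem = divmod(n_copies, 2)
    dosage[:full] = 2
    if rem:
        dosage[full] = 1
    genotypes[:, :] = dosage[None, :]
    sites = pd.DataFrame(
        {
            "chrom": "2L",
            "pos": np.arange(1, n_sites + 1),
            "ref": "A",
            "alt": "T",
            "origin": "standing",
            "carrier": -1,
        }
    )
    return simgen.FounderSet(
        sites=sites,
        genotypes=genotypes,
        ems_counts=np.zeros(config.n_founders, dtype=np.int64),
        config=config,
    )


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("pop_size", 0),
            ("n_founders", -1),
            ("genome_size_mb", 0),
            ("ems_rate_per_mb", -0.1),
            ("mean_depth", -1.0),
        ],
    )
    def test_invalid_field_named_in_error(self, field, value):
        with pytest.raises(SimConfigError, match=field):
            small_config(**{field: value})

    def test_selected_site_index_checked_against_registry(self):
        config = small_config(selected_sites=((10**9, 0.1),))
        founders = simgen.simulate_founders(config)
        with pytest.raises(SimConfigError, match="selected_sites"):
            simgen.evolve_population(founders, config, 0)


class TestFounders:
    def test_zero_rate_means_no_ems_mutations(self):
        founders = simgen.simulate_founders(small_config(ems_rate_per_mb=0.0))
        assert founders.ems_counts.sum() == 0
        assert (founders.sites["origin"] == "standing").all()

    def test_poisson_mean_of_ems_counts(self):
        # rate 3/Mb over 20 Mb: per-founder counts ~ Poisson(60)
        config = small_config(
            genome_size_mb=20.0, ems_rate_per_mb=3.0, n_founders=100, seed=5
        )
        founders = simgen.simulate_founders(config)
        mean = founders.ems_counts.mean()
        se = np.sqrt(60.0 / 100)
        assert abs(mean - 60.0) <= 3 * se

    def test_ems_sites_are_single_founder_heterozygotes(self):
        founders = simgen.simulate_founders(small_config())
        ems = founders.sites["origin"].to_numpy() == "ems"
        g = founders.genotypes[ems]
        assert np.all(g.sum(axis=1) == 1)
        assert np.all(g.max(axis=1) == 1)

    def test_standing_frequencies_strictly_inside_unit_interval(self):
        founders = simgen.simulate_founders(small_config())
        # Beta draws are in (0,1); realized founder frequencies stay in [0,1]
        standing = founders.sites["origin"].to_numpy() == "standing"
        f = founders.frequencies()[standing]
        assert np.all((f >= 0) & (f <= 1))

    def test_determinism_under_fixed_seed(self):
        config = small_config()
        a = simgen.simulate_founders(config)
        b = simgen.simulate_founders(config)
        assert a.sites.equals(b.sites)
        assert np.array_equal(a.genotypes, b.genotypes)
        assert np.array_equal(a.ems_counts, b.ems_counts)


class TestEvolution:
    def test_neutral_deterministic_mode_is_a_fixed_point(self):
        config = small_config()
        founders = simgen.simulate_founders(config)
        traj = simgen.evolve_population(founders, config, 0, deterministic=True)
        assert np.allclose(traj.freq[0, 0], traj.freq[0, -1])

    def test_selection_moves_deterministic_frequency_as_expected(self):
        config = small_config(selected_sites=((0, 0.5),))
        founders = simgen.simulate_founders(config)
        p0 = founders.frequencies()[0]
        traj = simgen.evolve_population(founders, config, 0, deterministic=True)
        expected = p0 * 1.5 / (1 + 0.5 * p0)
        assert traj.freq[0, 1, 0] == pytest.approx(expected)

    def test_neutral_fixation_probability_equals_initial_frequency(self):
        # diffusion-limit check: p0 = 0.1, N = 50, 2000 replicate sites
        config = small_config(
            n_founders=5, pop_size=50, n_generations=800, n_sites_standing=2000
        )
        founders = make_founders_with_freq(0.1, 2000, config)
        traj = simgen.evolve_population(founders, config, 0)
        final = traj.freq[0, -1]
        absorbed = (final == 0.0) | (final == 1.0)
        assert absorbed.mean() > 0.99
        frac_fixed = (final == 1.0).mean()
        se = np.sqrt(0.1 * 0.9 / 2000)
        assert abs(frac_fixed - 0.1) <= 3 * se

    def test_heterozygosity_decays_at_the_drift_rate(self):
        # classical result: E[2p(1-p)] shrinks by (1 - 1/2N) per generation
        config = small_config(
            n_founders=10, pop_size=50, n_generations=30, seed=3
        )
        founders = make_founders_with_freq(0.5, 2000, config)
        traj = simgen.evolve_population(founders, config, 0)
        p = traj.freq[0, -1]
        het = 2 * p * (1 - p)
        expected = 0.5 * (1 - 1 / 100) ** 30
        se = het.std(ddof=1) / np.sqrt(len(het))
        assert abs(het.mean() - expected) <= 4 * se

    def test_absorbed_frequencies_stay_absorbed(self):
        config = small_config(n_founders=5, pop_size=20, n_generations=100)
        founders = make_founders_with_freq(0.2, 500, config)
        traj = simgen.evolve_population(founders, config, 0)
        f = traj.freq[0]
        for g in range(1, f.shape[0]):
            prev_lost = f[g - 1] == 0.0
            prev_fixed = f[g - 1] == 1.0
            assert np.all(f[g][prev_lost] == 0.0)
            assert np.all(f[g][prev_fixed] == 1.0)

    def test_neutral_mean_frequency_change_is_centred_on_zero(self):
        config = small_config(n_founders=10, pop_size=100, n_generations=7)
        founders = make_founders_with_freq(0.5, 2500, config)
        traj = simgen.evolve_population(founders, config, 0)
        delta = traj.freq[0, 7] - traj.freq[0, 3]
        se = delta.std(ddof=1) / np.sqrt(len(delta))
        assert abs(delta.mean()) <= 3 * se


class TestPoolSampling:
    def test_boundary_frequencies_yield_pure_depths(self):
        config = small_config(n_founders=4, mean_depth=30.0)
        founders = make_founders_with_freq(0.5, 10, config)
        traj = simgen.evolve_population(founders, config, 0, deterministic=True)
        traj.freq[:, :, :5] = 0.0
        traj.freq[:, :, 5:] = 1.0
        table = simgen.sample_pool_reads(traj, config, 3)
        assert np.all(table.alt_depth[:5] == 0)
        assert np.all(table.ref_depth[5:] == 0)

    def test_pooled_alt_fraction_matches_binomial_mean(self):
        config = small_config(
            n_founders=10, n_sites_standing=5000, mean_depth=30.0,
            depth_dispersion=0.0,
        )
        founders = make_founders_with_freq(0.3, 5000, config)
        traj = simgen.evolve_population(founders, config, 0, deterministic=True)
        table = simgen.sample_pool_reads(traj, config, 2)
        total = table.ref_depth + table.alt_depth
        frac = table.alt_depth.sum() / total.sum()
        se = np.sqrt(0.3 * 0.7 / total.sum())
        assert abs(frac - 0.3) <= 3 * se

    def test_depths_are_consistent_and_reproducible(self):
        config = small_config()
        founders = simgen.simulate_founders(config)
        traj = simgen.evolve_all(founders, config)
        t1 = simgen.sample_pool_reads(traj, config, 3)
        t2 = simgen.sample_pool_reads(traj, config, 3)
        assert np.array_equal(t1.ref_depth, t2.ref_depth)
        assert np.array_equal(t1.alt_depth, t2.alt_depth)
        assert np.all(t1.ref_depth >= 0) and np.all(t1.alt_depth >= 0)

    def test_generation_sampling_independent_of_batching(self):
        config = small_config()
        founders = simgen.simulate_founders(config)
        traj = simgen.evolve_all(founders, config)
        single = simgen.sample_pool_reads(traj, config, 7)
        batch = simgen.sample_pool_generations(traj, config, (3, 7))
        j = [i for i, g in enumerate(batch.samples["generation"]) if g == 7]
        assert np.array_equal(batch.alt_depth[:, j], single.alt_depth)


class TestPhenotypes:
    def test_zero_effects_zero_noise_gives_baseline_everywhere(self):
        config = small_config(pheno_noise_sd_um=0.0)
        founders = simgen.simulate_founders(config)
        traj = simgen.evolve_all(founders, config)
        records = simgen.simulate_phenotypes(traj, config, 3, 10)
        assert all(r.length_um == pytest.approx(550.0) for r in records)

    def test_single_effect_recovered_exactly_by_least_squares(self):
        config = small_config(
            n_founders=10, pheno_noise_sd_um=0.0, pheno_effects=((0, 8.0),)
        )
        founders = make_founders_with_freq(0.5, 100, config)
        traj = simgen.evolve_population(founders, config, 0, deterministic=True)
        records, dosages = simgen.simulate_phenotypes(
            traj, config, 3, 200, return_dosages=True
        )
        lengths = np.array([r.length_um for r in records])
        d = dosages[:, 0].astype(float)
        assert len(np.unique(d)) == 3  # high contrast in dosage
        assert ols_slope_oracle(d, lengths) == pytest.approx(8.0, abs=1e-9)

    def test_stripe_coordinates_respect_record_invariants(self):
        config = small_config()
        founders = simgen.simulate_founders(config)
        traj = simgen.evolve_all(founders, config)
        for r in simgen.simulate_phenotypes(traj, config, 7, 5):
            assert np.all(r.stripes_um >= 0)
            assert np.all(r.stripes_um <= r.length_um)
            assert np.all(np.diff(r.stripes_um) >= 0)
            assert r.nuclei_um.shape[0] >= 2

    def test_length_position_coupling_sets_the_scaled_position_slope(self):
        # with stripe noise off, scaled stripe 1 is an exact linear function
        # of length deviation with slope equal to the configured coupling
        config = small_config(
            n_founders=10, pheno_noise_sd_um=15.0, stripe_scaled_sd_pct=0.0
        )
        founders = make_founders_with_freq(0.5, 10, config)
        traj = simgen.evolve_population(founders, config, 0, deterministic=True)
        records = simgen.simulate_phenotypes(traj, config, 1, 100)
        lengths = np.array([r.length_um for r in records])
        scaled1 = np.array(
            [100 * r.stripes_um[0] / r.length_um for r in records]
        )
        slope = ols_slope_oracle(lengths, scaled1)
        assert slope == pytest.approx(
            config.length_coupling_pct_per_um, rel=1e-6
        )

    def test_phenotype_tables_reproducible_and_guarded(self):
        config = small_config()
        founders = simgen.simulate_founders(config)
        traj = simgen.evolve_all(founders, config)
        a = simgen.simulate_phenotypes(traj, config, 3, 4)
        b = simgen.simulate_phenotypes(traj, config, 3, 4)
        assert all(
            x.length_um == y.length_um
            and np.array_equal(x.stripes_um, y.stripes_um)
            and np.array_equal(x.nuclei_um, y.nuclei_um)
            for x, y in zip(a, b)
        )
        with pytest.raises(SimConfigError):
            simgen.simulate_phenotypes(traj, config, 3, 0)
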