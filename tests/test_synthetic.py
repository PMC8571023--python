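"""Synthetic generators: planted ground truth, determinism, calibration."""

import numpy as np
import pytest

from scaffold_screen.library_io import ScaffoldQuery, scaffold_filter
from scaffold_screen.regression import pearson_regression
from scaffold_screen.synthetic import (SimulationConfig,
                                       simulate_decomposition,
                                       simulate_library,
                                       simulate_regression_data)
from scaffold_screen.thermo import hot_residues


class TestLibraryGenerator:
    def test_planted_fraction_recovered_exactly(self):
        sim = simulate_library(SimulationConfig(seed=1, n_molecules=20,
                                                frac_scaffold=0.3))
        hits = scaffold_filter(sim.records, ScaffoldQuery())
        assert len(hits) == 6
        assert {h.id for h in hits} == sim.scaffold_ids

    @pytest.mark.parametrize("frac,expected", [(0.0, 0), (1.0, 30)])
    def test_fraction_extremes(self, frac, expected):
        sim = simulate_library(SimulationConfig(seed=5, n_molecules=30,
                                                frac_scaffold=frac))
        hits = scaffold_filter(sim.records, ScaffoldQuery())
        assert len(hits) == expected

    def test_default_config_mirrors_screen_scale(self):
        config = SimulationConfig()
        assert config.n_molecules == 4642
        assert round(config.n_molecules * config.frac_scaffold) == 13

    def test_byte_identical_across_runs(self):
        config = SimulationConfig(seed=9, n_molecules=40, frac_scaffold=0.2)
        a = simulate_library(config)
        b = simulate_library(config)
        assert [r.smiles for r in a.records] == [r.smiles for r in b.records]
        assert a.scaffold_ids == b.scaffold_ids

    def test_seed_changes_output(self):
        a = simulate_library(SimulationConfig(seed=1, n_molecules=40))
        b = simulate_library(SimulationConfig(seed=2, n_molecules=40))
        assert [r.smiles for r in a.records] != [r.smiles for r in b.records]

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            simulate_library(SimulationConfig(n_molecules=0))
        with pytest.raises(ValueError):
            simulate_library(SimulationConfig(n_molecules=5, frac_scaffold=1.5))


class TestRegressionGenerator:
    def test_noise_free_recovery_is_exact(self):
        config = SimulationConfig(seed=3, n_points=10, noise_sd=0.0,
                                  slope=0.25, intercept=1.5)
        x, y = simulate_regression_data(config)
        fit = pearson_regression(x, y)
        assert fit.slope == pytest.approx(0.25)
        assert fit.intercept == pytest.approx(1.5)
        assert fit.r2 == pytest.approx(1.0)

    def test_parameter_recovery_within_three_se(self):
        config = SimulationConfig(seed=7, n_points=50, slope=0.1,
                                  intercept=0.0, noise_sd=0.2)
        x, y = simulate_regression_data(config)
        fit = pearson_regression(x, y)
        xa = np.asarray(x)
        resid_var = np.sum((np.asarray(y) - fit.intercept - fit.slope * xa) ** 2) / (50 - 2)
        se_slope = np.sqrt(resid_var / np.sum((xa - xa.mean()) ** 2))
        assert abs(fit.slope - 0.1) < 3 * se_slope

    def test_reproducible(self):
        config = SimulationConfig(seed=12, n_points=20)
        assert simulate_regression_data(config) == simulate_regression_data(config)

    def test_null_rejection_rate_is_nominal(self):
        # type-I error calibration: under slope = 0 the t-test should
        # reject at the 5% level about 5% of the time
        rejections = 0
        n_trials = 500
        for seed in range(n_trials):
            config = SimulationConfig(seed=seed, n_points=200, slope=0.0,
                                      intercept=0.0, noise_sd=1.0)
            x, y = simulate_regression_data(config)
            if pearson_regression(x, y).p_two_tailed < 0.05:
                rejections += 1
        rate = rejections / n_trials
        # 3-sigma binomial band around 0.05 for 500 trials
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_trials)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            simulate_regression_data(SimulationConfig(noise_sd=-0.1))


class TestDecompositionGenerator:
    def test_planted_hot_set_recovered(self):
        sim = simulate_decomposition(SimulationConfig(seed=2, n_residues=42,
                                                      n_hot=3))
        hot = hot_residues(sim.entries, threshold=-3.0)
        assert {e.label for e in hot} == sim.hot_labels
        assert len(sim.hot_labels) == 3

    def test_no_hot_residues(self):
        sim = simulate_decomposition(SimulationConfig(seed=4, n_hot=0))
        assert sim.hot_labels == set()
        assert hot_residues(sim.entries, threshold=-3.0) == []

    def test_zero_effect_sits_on_threshold_and_is_included(self):
        sim = simulate_decomposition(SimulationConfig(seed=6, n_residues=10,
                                                      n_hot=2, hot_effect=0.0))
        hot = hot_residues(sim.entries, threshold=-3.0)
        assert {e.label for e in hot} == sim.hot_labels
        planted = [e for e in sim.entries if e.label in sim.hot_labels]
        assert all(e.dg_pb_contrib == -3.0 for e in planted)

    def test_deterministic(self):
        config = SimulationConfig(seed=8, n_residues=30, n_hot=4)
        a = simulate_decomposition(config)
        b = simulate_decomposition(config)
        assert a.entries == b.entries
        assert a.hot_labels == b.hot_labels

    def test_impossible_config(self):
        with pytest.raises(ValueError):
            simulate_decomposition(SimulationConfig(n_hot=500, n_residues=10))
        with pytest.raises(ValueError):
            simulate_decomposition(SimulationConfig(n_residues=1000))

    def test_generators_use_independent_streams(self):
        # drawing the library must not perturb the decomposition stream
        config = SimulationConfig(seed=13, n_molecules=10, n_residues=20)
        before = simulate_decomposition(config)
        simulate_library(config)
        after = simulate_decomposition(config)
        assert before.entries == after.entries
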