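"""Synthetic cohorts, log-log exponent fitting, and recovery experiments."""

import math

import numpy as np
import pytest

from adescale import (
    DomainError,
    SimulationConfig,
    cohort_to_records,
    fit_allometric_exponent,
    recovery_experiment,
    simulate_cohort,
    simulation_bands,
    summarize,
)


def test_band_expansion_covers_schedule():
    bands = simulation_bands()
    labels = [b.label for b in bands]
    assert labels == [
        "preterm_neonate",
        "term_neonate",
        "infant_toddler",
        "preschool",
        "older_child",
    ]
    assert [b.exponent for b in bands] == [1.2, 1.1, 1.0, 0.9, 0.75]


class TestSimulateCohort:
    def test_noise_free_cohort_follows_power_law_exactly(self, growth):
        config = SimulationConfig(n_per_band=10, weight_cv=0.0, residual_cv=0.0, seed=3)
        for s in simulate_cohort(config, growth):
            expected = 100.0 * (s.weight / 70.0) ** s.true_exponent
            assert s.observed_clearance == pytest.approx(expected, rel=1e-12)
            assert s.observed_clearance == s.true_clearance

    def test_same_seed_same_cohort(self, growth):
        config = SimulationConfig(n_per_band=25, seed=11)
        assert simulate_cohort(config, growth) == simulate_cohort(config, growth)

    def test_different_seed_different_cohort(self, growth):
        a = simulate_cohort(SimulationConfig(n_per_band=25, seed=1), growth)
        b = simulate_cohort(SimulationConfig(n_per_band=25, seed=2), growth)
        assert a != b

    def test_residual_cv_recovered_empirically(self, growth):
        """With residual CV 0.3 the empirical CV of observed/true
        clearance lands within Monte-Carlo error of 0.3."""
        config = SimulationConfig(
            n_per_band=200, weight_cv=0.0, residual_cv=0.3, seed=5
        )
        ratios = np.array(
            [s.observed_clearance / s.true_clearance for s in simulate_cohort(config, growth)]
        )
        assert ratios.std() / ratios.mean() == pytest.approx(0.3, abs=0.03)

    def test_ages_stay_inside_bands(self, growth):
        config = SimulationConfig(n_per_band=100, seed=9)
        for band, subjects in zip(
            simulation_bands(), np.array_split(simulate_cohort(config, growth), 5)
        ):
            for s in subjects:
                assert band.lower_age < s.age <= band.upper_age

    def test_invalid_config_rejected(self):
        with pytest.raises(DomainError):
            SimulationConfig(n_per_band=1)
        with pytest.raises(DomainError):
            SimulationConfig(residual_cv=-0.1)


class TestAllometricFit:
    def test_two_point_closed_form(self):
        # slope log(16/2)/log(4/1) = 1.5, coefficient 2
        fit = fit_allometric_exponent([(1.0, 2.0), (4.0, 16.0)])
        assert fit.exponent_b == pytest.approx(1.5, rel=1e-12)
        assert fit.coefficient_a == pytest.approx(2.0, rel=1e-12)

    def test_exact_on_noise_free_power_law(self):
        weights = np.linspace(3.0, 60.0, 30)
        pairs = [(w, 5.0 * w**0.75) for w in weights]
        fit = fit_allometric_exponent(pairs)
        assert fit.exponent_b == pytest.approx(0.75, abs=1e-12)
        assert fit.standard_error_b == pytest.approx(0.0, abs=1e-10)

    def test_degenerate_designs_rejected(self):
        with pytest.raises(DomainError):
            fit_allometric_exponent([(5.0, 2.0)])
        with pytest.raises(DomainError):
            fit_allometric_exponent([(5.0, 2.0), (5.0, 3.0)])
        with pytest.raises(DomainError):
            fit_allometric_exponent([(5.0, -2.0), (6.0, 3.0)])


class TestRecovery:
    def test_noise_free_recovery_is_exact(self, growth):
        config = SimulationConfig(n_per_band=20, weight_cv=0.0, residual_cv=0.0, seed=2)
        table = recovery_experiment(config, replicates=3, growth=growth)
        assert np.allclose(table["mean_bias"], 0.0, atol=1e-10)
        assert np.allclose(table["rmse"], 0.0, atol=1e-10)

    def test_deterministic_under_seed(self, growth):
        config = SimulationConfig(n_per_band=30, seed=17)
        t1 = recovery_experiment(config, replicates=2, growth=growth)
        t2 = recovery_experiment(config, replicates=2, growth=growth)
        assert t1.equals(t2)

    def test_neonatal_exponent_distinguishable_from_075(self, growth):
        """With n=200 and residual CV 0.3, the mean fitted preterm
        exponent sits far closer to the true 1.2 than to 0.75."""
        config = SimulationConfig(n_per_band=200, residual_cv=0.3, seed=42)
        table = recovery_experiment(config, replicates=20, growth=growth)
        preterm = table.set_index("band").loc["preterm_neonate"]
        assert abs(preterm["mean_bias"]) < 0.1  # far below the 0.45 gap to 0.75
        assert preterm["mean_fitted_exponent"] > 1.0


def test_noise_free_pipeline_all_within_30(growth):
    """With zero simulation noise the full simulate -> predict ->
    evaluate pipeline puts 100% of observations in the <=30% bin."""
    config = SimulationConfig(n_per_band=40, weight_cv=0.0, residual_cv=0.0, seed=8)
    records = cohort_to_records(simulate_cohort(config, growth), config)
    summary = next(
        s
        for s in summarize(records, "model_predictions", growth=growth)
        if s.class_or_overall == "overall"
    )
    assert summary.n_within_30 == summary.n_observations
    assert summary.max_abs_error == pytest.approx(0.0, abs=1e-9)
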