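"""Synthetic-data generators: moments, distributional agreement, determinism."""

import logging

import numpy as np
import pytest
from scipy import stats

from burstnoise import (
    CouplingSpec,
    KineticRates,
    TelegraphParams,
    calibrate,
    compound_moments,
    gillespie_telegraph,
    integrate_copy_numbers,
    negbinom_pmf,
    permutation_significance,
    sample_compound,
    simulate_coupled_pair,
    simulate_spot_table,
)


def _chisq_gof_pvalue(counts, pmf_fn, min_expected=5):
    """Chi-squared goodness of fit with tail bins pooled to >= min_expected."""
    n = len(counts)
    n_max = int(counts.max())
    observed = np.bincount(counts, minlength=n_max + 1).astype(float)
    expected = pmf_fn(np.arange(n_max + 1)) * n
    expected = np.append(expected, max(n - expected.sum(), 0.0))
    observed = np.append(observed, 0.0)
    # pool sparse cells from the right
    while len(expected) > 2 and expected[-2:].sum() < min_expected * 2:
        expected[-2] += expected[-1]
        observed[-2] += observed[-1]
        expected, observed = expected[:-1], observed[:-1]
    keep = expected > 0
    stat = ((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum()
    dof = keep.sum() - 1
    return stats.chi2.sf(stat, dof)


class TestSampleCompound:
    def test_moments_match_closed_form(self):
        params = TelegraphParams(2.0, 5.0, 0.0)
        counts = sample_compound(params, 100_000, seed=7)
        mean, var = compound_moments(params)
        se_mean = np.sqrt(var / len(counts))
        assert abs(counts.mean() - mean) < 3 * se_mean
        assert abs(counts.var() - var) / var < 0.05

    def test_extrinsic_variation_inflates_variance(self):
        base = sample_compound(TelegraphParams(2.0, 5.0, 0.0), 50_000, seed=8)
        noisy = sample_compound(TelegraphParams(2.0, 5.0, 2.0), 50_000, seed=8)
        assert noisy.var() > 1.5 * base.var()

    def test_pure_negbinom_distribution_agreement(self):
        counts = sample_compound(TelegraphParams(2.0, 5.0, 0.0), 10_000, seed=9)
        p = _chisq_gof_pvalue(counts, lambda ns: negbinom_pmf(ns, 2.0, 5.0))
        assert p > 0.01

    def test_empty_draw_rejected(self):
        with pytest.raises(ValueError):
            sample_compound(TelegraphParams(1.0, 1.0), 0)

    def test_seeded_determinism(self):
        params = TelegraphParams(2.0, 5.0, 1.0)
        a = sample_compound(params, 1000, seed=5)
        b = sample_compound(params, 1000, seed=5)
        np.testing.assert_array_equal(a, b)


class TestGillespieTelegraph:
    def test_constitutive_limit_is_poissonian(self):
        # always-active promoter: mean K/delta, Fano factor 1
        rates = KineticRates(activation=1e4, deactivation=0.0,
                             transcription=10.0, degradation=1.0)
        counts = gillespie_telegraph(rates, 4000, t_end=12.0, seed=1)
        fano = counts.var() / counts.mean()
        assert counts.mean() == pytest.approx(10.0, rel=0.05)
        assert 0.9 <= fano <= 1.1

    def test_stationary_mean_matches_occupancy_balance(self):
        rates = KineticRates(activation=2.0, deactivation=6.0,
                             transcription=40.0, degradation=1.0)
        counts = gillespie_telegraph(rates, 3000, t_end=15.0, seed=2)
        expected = 40.0 * 2.0 / (2.0 + 6.0)  # K/delta * lambda/(lambda+nu)
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - expected) < 3 * se

    def test_zero_degradation_rejected(self):
        with pytest.raises(ValueError):
            KineticRates(activation=1.0, deactivation=1.0,
                         transcription=1.0, degradation=0.0)

    def test_short_run_warns(self, caplog):
        rates = KineticRates(1.0, 1.0, 1.0, 1.0)
        with caplog.at_level(logging.WARNING, logger="burstnoise.simulate"):
            gillespie_telegraph(rates, 5, t_end=1.0, seed=3)
        assert any("steady state" in r.message for r in caplog.records)

    def test_nonbursty_conversion_warns(self, caplog):
        rates = KineticRates(1.0, 2.0, 5.0, 1.0)
        with caplog.at_level(logging.WARNING, logger="burstnoise.simulate"):
            rates.telegraph_params()
        assert any("bursty" in r.message for r in caplog.records)

    def test_seeded_determinism(self):
        rates = KineticRates(1.0, 10.0, 100.0, 1.0)
        a = gillespie_telegraph(rates, 50, t_end=12.0, seed=4)
        b = gillespie_telegraph(rates, 50, t_end=12.0, seed=4)
        np.testing.assert_array_equal(a, b)


UP = TelegraphParams(2.0, 5.0, 1.0)
DOWN = TelegraphParams(2.0, 10.0, 0.5)


class TestSimulateCoupledPair:
    def test_uncoupled_downstream_marginal_matches_compound(self):
        pair = simulate_coupled_pair(UP, DOWN, CouplingSpec(exponent=0.0), 10_000, seed=6)
        from burstnoise.model import DEFAULT_QUAD, compound_pmf

        p = _chisq_gof_pvalue(pair.y, lambda ns: compound_pmf(ns, DOWN, DEFAULT_QUAD))
        assert p > 0.01

    def test_coupling_detected_by_permutation_test(self):
        pair = simulate_coupled_pair(
            UP, DOWN, CouplingSpec(exponent=1.0, reference_count=10.0), 500, seed=7
        )
        res = permutation_significance(pair, n_shuffles=1000, seed=0)
        assert res.p_value < 0.01

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            simulate_coupled_pair(UP, DOWN, CouplingSpec(), 1)

    def test_seeded_determinism(self):
        a = simulate_coupled_pair(UP, DOWN, CouplingSpec(1.0), 500, seed=8)
        b = simulate_coupled_pair(UP, DOWN, CouplingSpec(1.0), 500, seed=8)
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.y, b.y)


class TestSimulateSpotTable:
    def test_all_zero_counts_no_false_positives_empty_sample_block(self):
        table = simulate_spot_table(
            np.zeros(50, dtype=int), false_positive_rate=0.0, seed=9
        )
        assert (table.frame["sample_class"] != "sample").all()

    def test_round_trip_recovers_counts(self):
        truth = sample_compound(TelegraphParams(2.0, 5.0, 1.0), 500, seed=10)
        table = simulate_spot_table(truth, intensity_cv=0.1,
                                    false_positive_rate=0.2, seed=11)
        calib = calibrate(table.zero_intensities, table.low_intensities)
        counts = integrate_copy_numbers(table, calib)
        recovered = counts.reindex(
            [f"cell_{i:05d}" for i in range(len(truth))], fill_value=0
        ).to_numpy()
        assert (np.abs(recovered - truth) <= 1).mean() >= 0.95

    def test_scale_equivariance_with_matched_calibration(self):
        truth = np.array([0, 1, 2, 5, 10] * 20)
        t1 = simulate_spot_table(truth, unit_intensity=100.0, seed=12)
        t2 = simulate_spot_table(truth, unit_intensity=1000.0, seed=12)
        from burstnoise import CalibrationResult

        c1 = integrate_copy_numbers(t1, CalibrationResult(50.0, 100.0, 10.0))
        c2 = integrate_copy_numbers(t2, CalibrationResult(500.0, 1000.0, 100.0))
        assert (c1.to_numpy() == c2.to_numpy()).all()

    def test_negative_cv_rejected(self):
        with pytest.raises(ValueError):
            simulate_spot_table(np.ones(5, dtype=int), intensity_cv=-0.1, seed=0)

    def test_control_blocks_large_enough_for_calibration(self):
        table = simulate_spot_table(np.ones(100, dtype=int), seed=13)
        assert len(table.zero_intensities) >= 100
        assert len(table.low_intensities) >= 200
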