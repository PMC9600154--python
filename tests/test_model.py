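"""Core probability model: negative binomial, log-normal compound, likelihood."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from burstnoise import (
    NumericalSupportError,
    QuadratureConfig,
    TelegraphParams,
    compound_moments,
    compound_pmf,
    compound_pmf_vector,
    log_likelihood,
    negbinom_pmf,
    sample_compound,
)
from burstnoise.model import lognormal_log_params, moment_support_bound, support_bound


class TestNegbinomPmf:
    @pytest.mark.parametrize(
        "n, r, b, expected",
        [
            (0, 1.0, 1.0, 0.5),        # (1+b)^-r = 2^-1
            (2, 1.0, 1.0, 0.125),      # geometric: (1-p) p^2, p = 1/2
            (5, 2.5, 4.0, 0.06876070027706235),  # scipy.stats.nbinom oracle
        ],
    )
    def test_known_values(self, n, r, b, expected):
        assert negbinom_pmf(n, r, b) == pytest.approx(expected, rel=1e-12)

    def test_matches_scipy_across_grid(self):
        ns = np.arange(0, 200)
        for r in (0.3, 1.0, 7.5):
            for b in (0.5, 2.0, 30.0):
                ours = negbinom_pmf(ns, r, b)
                ref = stats.nbinom.pmf(ns, r, 1.0 / (1.0 + b))
                np.testing.assert_allclose(ours, ref, rtol=1e-10, atol=1e-300)

    def test_mean_is_burst_freq_times_burst_size(self):
        ns = np.arange(0, 3000)
        p = negbinom_pmf(ns, 2.0, 5.0)
        assert (ns * p).sum() == pytest.approx(10.0, rel=1e-9)

    @pytest.mark.parametrize("bad_n", [-1, 1.5, np.nan])
    def test_invalid_count_rejected(self, bad_n):
        with pytest.raises(ValueError):
            negbinom_pmf(bad_n, 1.0, 1.0)

    @pytest.mark.parametrize("r, b", [(0.0, 1.0), (-1.0, 1.0), (1.0, 0.0), (1.0, -2.0)])
    def test_invalid_params_rejected(self, r, b):
        with pytest.raises(ValueError):
            negbinom_pmf(0, r, b)


class TestCompoundPmf:
    def test_degenerate_mixing_reduces_to_negbinom(self):
        ns = np.arange(0, 501)
        for m in (0.1, 2.0, 50.0):
            for b in (0.5, 5.0, 50.0):
                params = TelegraphParams(m, b, 0.0)
                np.testing.assert_allclose(
                    compound_pmf(ns, params), negbinom_pmf(ns, m, b), atol=1e-10
                )

    def test_near_degenerate_sd_converges_to_negbinom(self):
        # tiny but nonzero extrinsic spread exercises the quadrature path
        ns = np.arange(0, 300)
        params = TelegraphParams(2.0, 5.0, 1e-5)
        diff = np.abs(compound_pmf(ns, params) - negbinom_pmf(ns, 2.0, 5.0))
        assert diff.max() < 1e-8

    def test_normalization(self):
        params = TelegraphParams(2.0, 5.0, 1.0)
        total = compound_pmf_vector(2000, params).sum()
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_monte_carlo_mixture_oracle(self):
        # independent oracle: average NB pmf over explicit log-normal draws
        params = TelegraphParams(1.0, 10.0, 0.5)
        rng = np.random.default_rng(2024)
        mu, s_log = lognormal_log_params(1.0, 0.5)
        r = np.exp(rng.normal(mu, s_log, 10**6))
        draws = stats.nbinom.pmf(3, r, 1.0 / 11.0)
        mc, se = draws.mean(), draws.std(ddof=1) / 1000.0
        assert abs(compound_pmf(3, params) - mc) < 3 * se

    def test_quadrature_convergence_on_node_doubling(self):
        ns = np.arange(0, 400)
        for m, b, s in [(2.0, 5.0, 1.0), (0.5, 20.0, 1.0), (1.0, 10.0, 1.5)]:
            params = TelegraphParams(m, b, s)
            p128 = compound_pmf(ns, params, QuadratureConfig(n_nodes=128))
            p256 = compound_pmf(ns, params, QuadratureConfig(n_nodes=256))
            assert np.abs(p128 - p256).max() < 1e-8

    def test_deterministic_for_fixed_config(self):
        params = TelegraphParams(2.0, 5.0, 1.0)
        a = compound_pmf_vector(100, params)
        b = compound_pmf_vector(100, params)
        np.testing.assert_array_equal(a, b)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            TelegraphParams(1.0, 1.0, -0.1)

    def test_too_few_nodes_for_tail_budget_rejected(self):
        with pytest.raises(ValueError, match="nodes"):
            compound_pmf(0, TelegraphParams(1.0, 1.0, 1.0), QuadratureConfig(n_nodes=2))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        m=st.floats(0.1, 50),
        b=st.floats(0.5, 50),
        s=st.floats(0, 20),
        n=st.integers(0, 200),
    )
    def test_pmf_is_a_probability(self, m, b, s, n):
        p = compound_pmf(n, TelegraphParams(m, b, s))
        assert 0.0 <= p <= 1.0


class TestCompoundMoments:
    @pytest.mark.parametrize(
        "m, b, s, mean, var",
        [
            (2.0, 5.0, 0.0, 10.0, 60.0),
            (2.0, 5.0, 1.0, 10.0, 85.0),
            (1.0, 1.0, 0.0, 1.0, 2.0),
        ],
    )
    def test_closed_form(self, m, b, s, mean, var):
        assert compound_moments(TelegraphParams(m, b, s)) == (mean, var)

    @pytest.mark.parametrize(
        "m, b, s", [(2.0, 5.0, 1.0), (0.5, 10.0, 0.25), (10.0, 2.0, 10.0)]
    )
    def test_quadrature_pmf_moments_match_closed_form(self, m, b, s):
        params = TelegraphParams(m, b, s)
        mean_cf, var_cf = compound_moments(params)
        n_max = moment_support_bound(params)
        ns = np.arange(n_max + 1)
        p = compound_pmf(ns, params)
        mean_q = float(ns @ p)
        var_q = float((ns.astype(float) ** 2) @ p) - mean_q**2
        assert mean_q == pytest.approx(mean_cf, rel=1e-6)
        assert var_q == pytest.approx(var_cf, rel=1e-6)

    def test_normalization_within_chebyshev_bound(self):
        params = TelegraphParams(2.0, 5.0, 1.0)
        n_max = support_bound(params, mass=1e-8)
        assert compound_pmf_vector(n_max, params).sum() >= 1 - 1e-6


class TestLogLikelihood:
    def test_single_zero_count(self):
        params = TelegraphParams(1.0, 1.0, 0.0)
        assert log_likelihood([0], params) == pytest.approx(np.log(0.5))

    def test_additivity(self):
        params = TelegraphParams(1.0, 1.0, 0.0)
        assert log_likelihood([0, 2], params) == pytest.approx(
            np.log(0.5) + np.log(0.125)
        )

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            log_likelihood([], TelegraphParams(1.0, 1.0))

    def test_underflow_at_observed_count_is_flagged(self):
        # a count absurdly far in the tail underflows the pmf to exactly 0
        with pytest.raises(NumericalSupportError):
            log_likelihood([500_000], TelegraphParams(0.1, 0.5, 0.0))

    def test_likelihood_peaks_near_truth(self):
        # simulated data should prefer the generating parameters over a
        # doubled burst frequency in nearly every replicate
        truth = TelegraphParams(2.0, 10.0, 1.0)
        wrong = TelegraphParams(4.0, 10.0, 1.0)
        wins = 0
        for seed in range(50):
            counts = sample_compound(truth, 500, seed=9000 + seed)
            wins += log_likelihood(counts, truth) > log_likelihood(counts, wrong)
        assert wins >= 48  # >= 95% of 50 replicates


class TestTelegraphParams:
    def test_json_round_trip(self):
        params = TelegraphParams(2.0, 5.0, 1.0)
        assert TelegraphParams.from_json(params.to_json()) == params

    @pytest.mark.parametrize("kwargs", [
        {"burst_freq": 0.0, "burst_size": 1.0},
        {"burst_freq": 1.0, "burst_size": -1.0},
        {"burst_freq": float("inf"), "burst_size": 1.0},
    ])
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TelegraphParams(**kwargs)
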