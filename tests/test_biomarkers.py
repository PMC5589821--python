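"""Censored log-normal fitting, conditional-expectation imputation and
quantile normalization."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import integrate, stats

from sepsisphase.biomarkers import (
    ABOVE_ULOD, BELOW_LLOD, OBSERVED, BiomarkerMeasurement, CensoredFit,
    conditional_expectation, fit_censored_lognormal, impute_censored,
    quantile_normalize,
)


def panel(values, censor=None, marker="IL-6"):
    censor = censor or [OBSERVED] * len(values)
    return [BiomarkerMeasurement(marker, float(v), c) for v, c in zip(values, censor)]


class TestCensoredFit:
    def test_uncensored_mle_recovers_parameters(self):
        rng = np.random.default_rng(7)
        x = np.exp(rng.normal(1.0, 0.5, 1000))
        fit = fit_censored_lognormal(panel(x))
        assert fit.mu == pytest.approx(1.0, abs=0.05)
        assert fit.sigma == pytest.approx(0.5, abs=0.05)
        assert fit.n_censored_low == 0

    def test_left_censored_mle_recovers_mu(self):
        """20% left-censoring at the empirical 0.2-quantile barely biases mu."""
        rng = np.random.default_rng(8)
        x = np.exp(rng.normal(1.0, 0.5, 1000))
        llod = np.quantile(x, 0.2)
        censor = [BELOW_LLOD if v < llod else OBSERVED for v in x]
        values = [llod if v < llod else v for v in x]
        fit = fit_censored_lognormal(panel(values, censor))
        assert fit.mu == pytest.approx(1.0, abs=0.08)
        assert fit.n_censored_low == sum(c == BELOW_LLOD for c in censor)

    def test_degenerate_identical_values_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_censored_lognormal(panel([2.0] * 10))

    def test_too_few_observed_instructs_fallback(self):
        with pytest.raises(ValueError, match="fall back"):
            fit_censored_lognormal(panel([1.0, 2.0], [OBSERVED, BELOW_LLOD]))


class TestConditionalExpectation:
    FIT = CensoredFit(mu=0.0, sigma=1.0, n_observed=10)

    def test_infinite_bound_gives_unconditional_mean(self):
        assert conditional_expectation(self.FIT, 1e12, "below") == pytest.approx(
            np.exp(0.5), abs=1e-6)

    def test_matches_numeric_truncated_mean(self):
        """Closed form vs independent quadrature of x f(x) / F(b) on (0, b)."""
        dist = stats.lognorm(s=1.0)
        num, _ = integrate.quad(lambda x: x * dist.pdf(x), 0, 1.0)
        expected = num / dist.cdf(1.0)  # = 0.52316 for mu=0, sigma=1, b=1
        assert conditional_expectation(self.FIT, 1.0, "below") == pytest.approx(
            expected, rel=1e-8)
        assert expected == pytest.approx(0.523157, abs=1e-5)

    @pytest.mark.parametrize("bound", [0.01, 0.5, 1.0, 5.0, 1e4])
    def test_truncation_ordering(self, bound):
        assert 0 < conditional_expectation(self.FIT, bound, "below") < bound
        assert conditional_expectation(self.FIT, bound, "above") > bound

    def test_monotone_in_bound_below(self):
        bounds = [0.1, 0.5, 1.0, 2.0, 10.0]
        values = [conditional_expectation(self.FIT, b, "below") for b in bounds]
        assert all(a < b for a, b in zip(values, values[1:]))

    def test_extreme_tail_bound_stays_finite_and_ordered(self):
        v = conditional_expectation(self.FIT, 1e-12, "below")
        assert 0 < v < 1e-12
        v = conditional_expectation(self.FIT, 1e12, "above")
        assert np.isfinite(v) and v > 1e12


class TestImputation:
    def test_identity_without_censoring(self):
        p = panel([1.0, 2.0, 3.0])
        assert impute_censored(p, {}) == p

    def test_below_llod_imputed_inside_interval(self):
        fits = {"IL-6": CensoredFit(mu=1.0, sigma=0.5, n_observed=10)}
        p = panel([0.5], [BELOW_LLOD])
        out = impute_censored(p, fits)
        assert 0 < out[0].concentration < 0.5
        assert out[0].censor == BELOW_LLOD  # provenance preserved

    def test_imputed_value_equals_conditional_expectation(self):
        fit = CensoredFit(mu=1.0, sigma=0.5, n_observed=10)
        p = panel([7.0], [ABOVE_ULOD])
        out = impute_censored(p, {"IL-6": fit})
        assert out[0].concentration == conditional_expectation(fit, 7.0, "above")

    def test_missing_fit_names_marker(self):
        with pytest.raises(KeyError, match="PCT"):
            impute_censored(panel([0.5], [BELOW_LLOD], marker="PCT"), {})

    def test_imputed_censored_values_stay_in_lowest_ranks(self):
        rng = np.random.default_rng(5)
        x = np.exp(rng.normal(0, 1, 200))
        llod = np.quantile(x, 0.15)
        censor = [BELOW_LLOD if v < llod else OBSERVED for v in x]
        values = [llod if v < llod else v for v in x]
        p = panel(values, censor)
        fit = fit_censored_lognormal(p)
        out = impute_censored(p, {"IL-6": fit})
        q = quantile_normalize([m.concentration for m in out])
        censored_max = q[[c == BELOW_LLOD for c in censor]].max()
        observed_min = q[[c == OBSERVED for c in censor]].min()
        assert censored_max < observed_min  # no rank inversion at the boundary


class TestQuantileNormalize:
    def test_hand_computed_example(self):
        assert quantile_normalize([5, 2, 9]).tolist() == [0.50, 0.25, 0.75]

    def test_tie_symmetry(self):
        assert quantile_normalize([3, 3]).tolist() == [0.50, 0.50]

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=50))
    def test_output_in_open_unit_interval(self, values):
        q = quantile_normalize(values)
        assert np.all((q > 0) & (q < 1))
        assert q.mean() == pytest.approx(0.5, abs=1e-9)

    @given(st.lists(st.integers(0, 500), min_size=2, max_size=30, unique=True))
    def test_monotone_transform_invariance(self, grid):
        values = np.asarray(grid, dtype=float) / 10.0
        before = quantile_normalize(values)
        after = quantile_normalize(np.exp(values / 10.0))
        assert np.allclose(before, after)
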