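"""Weibull survival curves, medians, fitting, and transition probabilities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nsclc_cea import (
    FitError,
    KMCurve,
    WeibullParams,
    annual_prob_to_period,
    cycle_transition_prob,
    cycles_to_months,
    fit_weibull,
    rate_to_prob,
    read_km_csv,
    transition_schedule,
    weibull_median,
    weibull_survival,
)

# realistic extrapolation regimes: survival stays representable over the
# 10-year horizon (extreme scale/shape combinations underflow to exactly 0)
valid_params = st.builds(
    WeibullParams,
    scale=st.floats(1e-4, 0.1),
    shape=st.floats(0.5, 1.6),
)


class TestSurvivalFunction:
    def test_starts_at_one_and_known_tail(self):
        p = WeibullParams(scale=0.010970, shape=1.216254)
        assert weibull_survival(p, 0.0) == 1.0
        # direct evaluation exp(-0.01097 * 174^1.216254): nearly everyone
        # has died by the 10-year horizon
        assert weibull_survival(p, 174.0) == pytest.approx(0.0029533, rel=1e-4)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            weibull_survival(WeibullParams(scale=0.1, shape=1.0), -1.0)

    @settings(max_examples=50, derandomize=True)
    @given(params=valid_params)
    def test_monotone_nonincreasing(self, params):
        t = np.linspace(0.0, 174.0, 400)
        s = weibull_survival(params, t)
        assert np.all(np.diff(s) <= 1e-15)
        assert np.all((s > 0) & (s <= 1.0))

    @settings(max_examples=50, derandomize=True)
    @given(params=valid_params)
    def test_median_definition(self, params):
        assert weibull_survival(params, weibull_median(params)) == pytest.approx(0.5)


class TestMedians:
    def test_exponential_closed_form(self):
        assert weibull_median(WeibullParams(scale=math.log(2.0), shape=1.0)) == pytest.approx(1.0)

    # fitted curves vs the trial's reported medians (months)
    @pytest.mark.parametrize(
        "scale,shape,cycles,months,trial_months",
        [
            (0.021350, 1.210605, 17.7211, 12.2264, 11.3),  # combo PFS
            (0.057642, 1.019433, 11.4683, 7.9124, 8.3),    # chemo PFS
            (0.006578, 1.263333, 39.9123, 27.5371, 27.9),  # combo OS
            (0.010970, 1.216254, 30.2317, 20.8580, 20.5),  # chemo OS
        ],
    )
    def test_fitted_medians_near_trial(self, scale, shape, cycles, months, trial_months):
        med = weibull_median(WeibullParams(scale=scale, shape=shape))
        assert med == pytest.approx(cycles, rel=1e-4)
        med_months = cycles_to_months(med)
        assert med_months == pytest.approx(months, rel=1e-4)
        assert abs(med_months - trial_months) / trial_months < 0.10


class TestFitting:
    def test_exact_recovery_on_noise_free_points(self):
        truth = WeibullParams(scale=0.021350, shape=1.210605)
        t = np.linspace(1.0, 60.0, 50)
        curve = KMCurve(times=t, survival=weibull_survival(truth, t))
        fit = fit_weibull(curve)
        assert fit.scale == pytest.approx(truth.scale, rel=1e-3)
        assert fit.shape == pytest.approx(truth.shape, rel=1e-3)

    def test_linearization_alone_is_exact(self):
        truth = WeibullParams(scale=0.0105, shape=1.4)
        t = np.linspace(2.0, 80.0, 40)
        curve = KMCurve(times=t, survival=weibull_survival(truth, t))
        fit = fit_weibull(curve, refine=False)
        assert fit.scale == pytest.approx(truth.scale, rel=1e-6)
        assert fit.shape == pytest.approx(truth.shape, rel=1e-6)

    def test_degenerate_input_rejected(self):
        flat = KMCurve(times=np.arange(5.0), survival=np.ones(5))
        with pytest.raises(FitError):
            fit_weibull(flat)
        with pytest.raises(FitError):
            fit_weibull(KMCurve(times=np.array([1.0, 2.0]), survival=np.array([0.9, 0.8])))

    def test_non_monotone_curve_rejected(self):
        with pytest.raises(ValueError):
            KMCurve(times=np.array([1.0, 2.0, 3.0]), survival=np.array([0.9, 0.95, 0.8]))


class TestTransitionProbabilities:
    def test_exponential_limit_is_constant(self):
        p = WeibullParams(scale=0.08, shape=1.0)
        expected = 1.0 - math.exp(-0.08)
        for u in (1, 7, 100):
            assert cycle_transition_prob(p, u) == pytest.approx(expected)

    def test_first_cycle_value(self):
        p = WeibullParams(scale=0.057642, shape=1.019433)
        assert cycle_transition_prob(p, 1) == pytest.approx(1.0 - math.exp(-0.057642))

    def test_cycle_zero_rejected(self):
        with pytest.raises(ValueError):
            cycle_transition_prob(WeibullParams(scale=0.1, shape=1.0), 0)

    @settings(max_examples=50, derandomize=True)
    @given(params=valid_params)
    def test_product_reconstructs_survival(self, params):
        """Pi(1 - p_u) over cycles 1..t must equal S(t) to machine precision."""
        sched = transition_schedule(params, 120)
        recon = np.cumprod(1.0 - sched.probs)
        t = np.arange(1, 121, dtype=float)
        np.testing.assert_allclose(recon, weibull_survival(params, t), rtol=1e-12)


class TestRateConversions:
    def test_zero_rate(self):
        assert rate_to_prob(0.0, 21.0) == 0.0

    def test_annual_round_trip(self):
        r = -math.log(0.5)  # annual probability 0.5
        assert rate_to_prob(r, 365.25) == pytest.approx(0.5)

    def test_annual_probability_compounding(self):
        # 1 - (1 - 0.00707)^(21/365.25)
        assert annual_prob_to_period(0.00707, 21.0) == pytest.approx(4.0785e-4, rel=1e-4)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            rate_to_prob(-0.1, 21.0)


class TestKMReader:
    def test_unit_conversion(self, tmp_path):
        p = tmp_path / "km.csv"
        p.write_text("time,survival\n0,1.0\n63,0.8\n126,0.5\n")
        curve = read_km_csv(p, time_unit="days")
        np.testing.assert_allclose(curve.times, [0.0, 3.0, 6.0])

    def test_unknown_unit(self, tmp_path):
        p = tmp_path / "km.csv"
        p.write_text("time,survival\n1,0.9\n")
        with pytest.raises(ValueError):
            read_km_csv(p, time_unit="fortnights")
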