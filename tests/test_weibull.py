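"""The Weibull curve, its derivatives, and the two key-point methods."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hvcurve import (
    PeriodLabel,
    WeibullParams,
    classify_period,
    dm_key_points,
    lc_quantile,
    numeric_key_points,
    tm_points,
    weibull_derivatives,
    weibull_lc,
)
from hvcurve.exceptions import DomainError

PARAM_GRID = [
    WeibullParams(a, b)
    for a in (0.5, 1.0, 2.23, 5.0)
    for b in (2.1, 2.5, 3.0, 4.0, 6.0)
]

params_strategy = st.builds(
    WeibullParams,
    a=st.floats(0.5, 5.0),
    b=st.floats(1.2, 6.0),
)


def bisect_quantile(params: WeibullParams, p: float) -> float:
    """Independent CDF inversion by bisection (oracle for the closed forms)."""
    lo, hi = 0.0, 100.0 * params.a
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if weibull_lc(params, mid) < p:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class TestCurve:
    def test_origin_and_scale_definition(self, fitted_params):
        assert weibull_lc(fitted_params, 0.0) == 0.0
        # at psi = a the loss is 1 - 1/e regardless of shape
        for p in PARAM_GRID:
            assert weibull_lc(p, p.a) == pytest.approx(1 - math.exp(-1), abs=1e-12)

    def test_value_at_lethal_tension(self, fitted_params):
        assert weibull_lc(fitted_params, 2.77709) == pytest.approx(0.82283, abs=5e-5)

    def test_negative_tension_rejected(self, fitted_params):
        with pytest.raises(DomainError):
            weibull_lc(fitted_params, -0.1)

    def test_monotone_and_bounded(self, fitted_params):
        psi = np.linspace(0.0, 6.0, 200)  # within the measured injection range
        lc = weibull_lc(fitted_params, psi)
        assert np.all(np.diff(lc) > 0)
        assert lc[0] == 0.0 and lc[-1] < 1.0

    @pytest.mark.parametrize("bad", [(-1.0, 2.0), (0.0, 2.0), (2.0, -1.0), (2.0, 0.0)])
    def test_parameter_validation(self, bad):
        with pytest.raises(DomainError):
            WeibullParams(*bad)


class TestDerivatives:
    @pytest.mark.parametrize("params", PARAM_GRID)
    @pytest.mark.parametrize("psi", [0.3, 1.0, 2.0, 4.0])
    def test_match_finite_differences(self, params, psi):
        """Analytic derivatives agree with 4th-order central differences."""
        h = 1e-4 * max(psi, 1.0)

        def f(x):
            return weibull_lc(params, x)

        fd1 = (-f(psi + 2 * h) + 8 * f(psi + h) - 8 * f(psi - h) + f(psi - 2 * h)) / (12 * h)
        fd2 = (
            -f(psi + 2 * h) + 16 * f(psi + h) - 30 * f(psi) + 16 * f(psi - h) - f(psi - 2 * h)
        ) / (12 * h**2)
        fd3 = (f(psi + 2 * h) - 2 * f(psi + h) + 2 * f(psi - h) - f(psi - 2 * h)) / (2 * h**3)
        d1, d2, d3 = weibull_derivatives(params, psi)
        scale = max(abs(d1), 1e-3)
        assert d1 == pytest.approx(fd1, rel=1e-6, abs=1e-8 * scale)
        assert d2 == pytest.approx(fd2, rel=1e-5, abs=1e-6)
        assert d3 == pytest.approx(fd3, rel=1e-3, abs=1e-4)

    def test_zero_at_key_points_by_construction(self, fitted_params):
        kp = dm_key_points(fitted_params)
        assert abs(weibull_derivatives(fitted_params, kp.psi_m)[1]) < 1e-10
        assert abs(weibull_derivatives(fitted_params, kp.psi_l)[2]) < 1e-10
        assert abs(weibull_derivatives(fitted_params, kp.psi_e)[2]) < 1e-10

    def test_rejects_origin(self, fitted_params):
        with pytest.raises(DomainError):
            weibull_derivatives(fitted_params, 0.0)


class TestDifferentialMethod:
    def test_fitted_curve_key_points(self, fitted_params):
        kp = dm_key_points(fitted_params)
        assert kp.psi_l == pytest.approx(2.777, abs=5e-4)
        assert kp.lc_l == pytest.approx(0.823, abs=5e-4)
        assert kp.psi_e == pytest.approx(0.7668, abs=1e-4)
        assert kp.psi_m == pytest.approx(1.8179, abs=1e-4)
        assert kp.lc_e == pytest.approx(0.0670, abs=1e-4)
        assert kp.lc_m == pytest.approx(0.4512, abs=1e-4)
        # human-readable rounding matches the conventional presentation
        assert round(kp.lc_l, 2) == 0.82

    def test_air_entry_absent_at_shape_two(self):
        kp = dm_key_points(WeibullParams(1.0, 2.0))
        assert kp.psi_e is None and kp.lc_e is None
        assert not kp.complete
        assert kp.psi_m == pytest.approx(0.5**0.5, abs=1e-12)

    def test_shape_at_most_one_rejected(self):
        with pytest.raises(DomainError, match="inflection"):
            dm_key_points(WeibullParams(1.0, 1.0))

    @pytest.mark.parametrize("params", PARAM_GRID)
    def test_matches_numeric_oracle(self, params):
        """Closed forms agree with bracketed root finding to 1e-8 MPa."""
        closed = dm_key_points(params)
        numeric = numeric_key_points(params)
        assert abs(closed.psi_m - numeric.psi_m) < 1e-8
        assert abs(closed.psi_l - numeric.psi_l) < 1e-8
        assert abs(closed.psi_e - numeric.psi_e) < 1e-8

    def test_numeric_oracle_without_lower_root(self):
        """For 1 < b <= 2 a fine sign scan confirms no lower turning point."""
        params = WeibullParams(1.0, 1.5)
        numeric = numeric_key_points(params)
        assert numeric.psi_e is None
        grid = np.linspace(1e-6, numeric.psi_m, 2000)
        d3 = weibull_derivatives(params, grid)[2]
        assert np.all(d3 < 0)  # no sign change below the inflection

    def test_numeric_matches_closed_inflection(self):
        params = WeibullParams(1.0, 3.0)
        assert numeric_key_points(params).psi_m == pytest.approx(
            (2.0 / 3.0) ** (1.0 / 3.0), abs=1e-10
        )

    @pytest.mark.parametrize("params", [p for p in PARAM_GRID if p.b > 2])
    def test_ordering(self, params):
        kp = dm_key_points(params)
        assert 0 < kp.psi_e < kp.psi_m < kp.psi_l
        assert 0 < kp.lc_e < kp.lc_m < kp.lc_l < 1

    @given(b=st.floats(2.05, 8.0), scale=st.floats(0.2, 10.0))
    def test_scale_equivariance(self, b, scale):
        """Key tensions scale linearly with a; loss values depend on b only."""
        base = dm_key_points(WeibullParams(1.0, b))
        scaled = dm_key_points(WeibullParams(scale, b))
        assert scaled.psi_m == pytest.approx(scale * base.psi_m, rel=1e-12)
        assert scaled.psi_l == pytest.approx(scale * base.psi_l, rel=1e-12)
        assert scaled.psi_e == pytest.approx(scale * base.psi_e, rel=1e-10)
        assert scaled.lc_m == pytest.approx(base.lc_m, rel=1e-12)
        assert scaled.lc_l == pytest.approx(base.lc_l, rel=1e-12)

    @given(b=st.floats(1.05, 50.0))
    def test_inflection_loss_closed_form(self, b):
        """LC at the inflection is 1 - exp(-(b-1)/b), tending to 1 - 1/e."""
        kp = dm_key_points(WeibullParams(1.0, b))
        assert kp.lc_m == pytest.approx(1 - math.exp(-(b - 1) / b), rel=1e-10)
        assert kp.lc_m < 1 - math.exp(-1)


class TestTraditionalMethod:
    def test_fitted_curve_quantiles_vs_bisection(self, fitted_params):
        tm = tm_points(fitted_params)
        assert tm.psi_50 == pytest.approx(1.9259, abs=2e-4)
        assert tm.psi_12 == pytest.approx(0.9794, abs=2e-4)
        assert tm.psi_88 == pytest.approx(3.0120, abs=2e-4)
        for point, p in ((tm.psi_12, 0.12), (tm.psi_50, 0.50), (tm.psi_88, 0.88)):
            assert point == pytest.approx(bisect_quantile(fitted_params, p), abs=1e-9)

    def test_exponential_special_case(self):
        assert tm_points(WeibullParams(3.0, 1.0)).psi_50 == pytest.approx(
            3.0 * math.log(2), rel=1e-12
        )

    @given(params=params_strategy, p=st.floats(1e-3, 1 - 1e-3))
    def test_quantile_round_trip(self, params, p):
        assert weibull_lc(params, lc_quantile(params, p)) == pytest.approx(p, abs=1e-10)

    def test_quantile_at_scale_and_limits(self, fitted_params):
        assert lc_quantile(fitted_params, 1 - math.exp(-1)) == pytest.approx(
            fitted_params.a, rel=1e-12
        )
        ps = [10.0 ** (-k) for k in range(1, 8)]
        qs = [lc_quantile(fitted_params, p) for p in ps]
        assert all(q2 < q1 for q1, q2 in zip(qs, qs[1:]))  # monotone to 0
        assert qs[-1] < 1e-2
        for bad in (0.0, 1.0, -0.2, 1.3):
            with pytest.raises(DomainError):
                lc_quantile(fitted_params, bad)

    def test_traditional_exceeds_differential_at_fitted_curve(self, fitted_params):
        """At the fitted parameters the quantile points overshoot all three
        differential-method points (the overestimation the method corrects)."""
        kp = dm_key_points(fitted_params)
        tm = tm_points(fitted_params)
        assert tm.psi_12 > kp.psi_e
        assert tm.psi_50 > kp.psi_m
        assert tm.psi_88 > kp.psi_l


class TestPeriods:
    def test_boundaries_belong_to_higher_period(self, fitted_params):
        kp = dm_key_points(fitted_params)
        assert classify_period(kp, 0.0) is PeriodLabel.STATIONARY
        assert classify_period(kp, kp.psi_e) is PeriodLabel.ACCELERATED_DECLINE
        assert classify_period(kp, 1.0) is PeriodLabel.ACCELERATED_DECLINE
        assert classify_period(kp, kp.psi_m) is PeriodLabel.DECELERATED_DECLINE
        assert classify_period(kp, kp.psi_l) is PeriodLabel.PLATFORM
        assert classify_period(kp, 3.5) is PeriodLabel.PLATFORM

    def test_partition_is_exhaustive(self, fitted_params):
        kp = dm_key_points(fitted_params)
        for psi in np.linspace(0, 8, 97):
            assert classify_period(kp, psi) in PeriodLabel

    def test_requires_air_entry_point(self):
        kp = dm_key_points(WeibullParams(1.0, 1.8))
        with pytest.raises(DomainError, match="b > 2"):
            classify_period(kp, 1.0)

    def test_rejects_negative_tension(self, fitted_params):
        with pytest.raises(DomainError):
            classify_period(dm_key_points(fitted_params), -1.0)
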