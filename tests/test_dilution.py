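"""Dilution envelope curves, NNI and the power-law fit."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cndc._exceptions import FitError
from cndc.dilution import (
    DilutionCurveModel,
    DilutionParams,
    classify_status,
    critical_n,
    fit_dilution,
    n_max_curve,
    n_min_curve,
    nni,
)

DEFAULTS = DilutionParams()
CONTINUOUS = DilutionParams(mode="continuous")


def brute_force_loglog_fit(dw, n_pct):
    """Independent oracle: normal equations of the log-log regression."""
    x, y = np.log(dw), np.log(n_pct)
    slope = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
    intercept = y.mean() - slope * x.mean()
    return float(np.exp(intercept)), float(-slope)


class TestCriticalN:
    def test_plateau_value_is_published_constant(self):
        assert round(critical_n(1.0, DEFAULTS), 2) == 4.78

    def test_breakpoint_belongs_to_plateau(self):
        assert critical_n(1.5, DEFAULTS) == critical_n(1.0, DEFAULTS)

    def test_decline_above_breakpoint(self):
        # 4.78 * 3^-0.33, evaluated both directly and in log space
        direct = critical_n(3.0, DEFAULTS)
        log_space = np.exp(np.log(DEFAULTS.plateau_c) - 0.33 * np.log(3.0))
        assert direct == pytest.approx(log_space, rel=1e-12)
        assert round(direct, 2) == 3.33

    def test_as_printed_mode_jumps_at_breakpoint(self):
        eps = 1e-9
        below = critical_n(1.5, DEFAULTS)
        above = critical_n(1.5 + eps, DEFAULTS)
        assert below - above == pytest.approx(
            DEFAULTS.plateau_c * (1 - 1.5**-0.33), rel=1e-6
        )

    def test_continuous_mode_is_continuous_at_breakpoint(self):
        eps = 1e-9
        assert critical_n(1.5 + eps, CONTINUOUS) == pytest.approx(
            critical_n(1.5, CONTINUOUS), rel=1e-8
        )

    def test_mode_ratio_above_breakpoint_is_dw_break_to_the_b(self):
        dw = np.array([1.6, 2.5, 4.0])
        ratio = critical_n(dw, CONTINUOUS) / critical_n(dw, DEFAULTS)
        assert np.allclose(ratio, 1.5**0.33)

    @given(st.floats(0.01, 50, allow_nan=False))
    @settings(deadline=None)
    def test_non_increasing_in_dw(self, dw):
        for params in (DEFAULTS, CONTINUOUS):
            assert critical_n(dw, params) >= critical_n(dw * 1.01, params) - 1e-12

    def test_non_positive_dw_rejected(self):
        with pytest.raises(ValueError):
            critical_n(0.0, DEFAULTS)


class TestEnvelope:
    @pytest.mark.parametrize(
        "func, dw, expected",
        [
            (n_max_curve, 2.0, 6.83),   # join point, both branches equal
            (n_max_curve, 1.0, 6.83),   # plateau
            (n_max_curve, 4.0, 6.83 * 2.0**-0.33),
            (n_min_curve, 0.5, 2.732),  # join point = 0.4 * Nmax
            (n_min_curve, 0.25, 2.732),
            (n_min_curve, 1.0, 0.4 * 6.83 * 0.5**0.33),
        ],
    )
    def test_envelope_values(self, func, dw, expected):
        assert func(dw, DEFAULTS) == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize("params", [DEFAULTS, CONTINUOUS])
    def test_envelope_ordering_over_grid(self, params):
        dw = np.geomspace(0.05, 20.0, 300)
        n_min = n_min_curve(dw, params)
        nc = critical_n(dw, params)
        n_max = n_max_curve(dw, params)
        assert np.all(n_min <= nc + 1e-12)
        assert np.all(nc <= n_max + 1e-12)

    def test_fw_breakpoint_derived_from_ratio(self):
        assert DEFAULTS.fw_break(25.64) == pytest.approx(25.64 * 1.5)


class TestNni:
    def test_identity_and_halving(self):
        assert nni(4.78, 4.78) == 1.0
        assert nni(2.39, 4.78) == 0.5
        assert nni(0.0, 3.2) == 0.0

    @given(
        st.floats(0.01, 10, allow_nan=False),
        st.floats(0.01, 10, allow_nan=False),
        st.floats(0.01, 100, allow_nan=False),
    )
    @settings(deadline=None)
    def test_homogeneous_of_degree_zero(self, na, nc, k):
        assert nni(k * na, k * nc) == pytest.approx(nni(na, nc), rel=1e-9)

    def test_non_positive_critical_rejected(self):
        with pytest.raises(ValueError):
            nni(1.0, 0.0)


class TestClassifyStatus:
    @pytest.mark.parametrize(
        "value, label",
        [(1.0, "optimal"), (0.5, "deficient"), (1.5, "excess"),
         (0.95, "optimal"), (1.05, "optimal"),
         (0.95 - 1e-9, "deficient"), (1.05 + 1e-9, "excess")],
    )
    def test_boundaries(self, value, label):
        assert classify_status(value, tolerance=0.05).label == label

    def test_invariant_optimal_iff_within_tolerance(self):
        for v in np.linspace(0, 2, 101):
            s = classify_status(v, 0.07)
            assert (s.label == "optimal") == (abs(v - 1) <= 0.07)


class TestDilutionFit:
    def test_exact_recovery_from_noiseless_points(self):
        dw = np.array([2.0, 3.0, 4.0, 5.0])
        a, b, r2 = fit_dilution(list(zip(dw, 4.78 * dw**-0.33)))
        assert a == pytest.approx(4.78, abs=1e-9)
        assert b == pytest.approx(0.33, abs=1e-9)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_normal_equations_on_noisy_data(self):
        rng = np.random.default_rng(11)
        dw = np.linspace(1.6, 6.0, 12)
        n_pct = 4.78 * dw**-0.33 * np.exp(rng.normal(0, 0.02, size=12))
        res = DilutionCurveModel(dw, n_pct, dw_break=1.5).fit()
        a_ref, b_ref = brute_force_loglog_fit(dw, n_pct)
        assert res.a == pytest.approx(a_ref, rel=1e-10)
        assert res.b == pytest.approx(b_ref, rel=1e-10)
        assert res.b == pytest.approx(0.33, abs=0.03)

    def test_plateau_points_excluded(self):
        dw = np.array([0.5, 1.0, 2.0, 3.0, 4.0])
        n_pct = np.where(dw <= 1.5, 4.781, 4.781 * dw**-0.33)
        res = DilutionCurveModel(dw, n_pct, dw_break=1.5).fit()
        assert res.nobs == 3
        assert res.model.n_excluded == 2
        assert res.b == pytest.approx(0.33, abs=1e-9)

    def test_too_few_points_above_breakpoint(self):
        with pytest.raises(FitError, match="at least 3"):
            fit_dilution([(2.0, 3.8), (3.0, 3.3), (1.0, 4.78)])
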