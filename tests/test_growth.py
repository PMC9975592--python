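"""Exponential growth fitting, the b(F) quadratic and unit conversions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cndc._exceptions import ConfigError, FitError
from cndc.growth import (
    BQuadratic,
    ConversionParams,
    DW_QUADRATIC,
    ExponentialGrowth,
    FW_QUADRATIC,
    N_UPTAKE_QUADRATIC,
    YIELD_MODEL,
    area_to_per_plant,
    b_response,
    dw_to_fw,
    fit_b_quadratic,
    fit_growth,
    fw_to_dw,
    optimal_n_rate,
    per_plant_to_area,
    predict_growth,
)


class TestPredictGrowth:
    def test_intercept_at_zero_ltf(self):
        assert predict_growth(0.0, YIELD_MODEL) == 0.2816

    def test_published_yield_model_at_ltf_ten(self):
        assert predict_growth(10.0, YIELD_MODEL) == pytest.approx(
            0.2816 * np.exp(1.21), rel=1e-12
        )

    def test_zero_rate_is_constant(self):
        from cndc.growth import GrowthFit

        flat = GrowthFit(2.0, 0.0, 1.0, 1.0, 5)
        assert predict_growth(37.0, flat) == 2.0


class TestExponentialFit:
    def test_exact_recovery(self):
        ltf = np.array([0.0, 5.0, 10.0, 15.0, 20.0])
        res = ExponentialGrowth(ltf, 0.2816 * np.exp(0.121 * ltf)).fit()
        assert res.intercept_a == pytest.approx(0.2816, abs=1e-8)
        assert res.rate_b == pytest.approx(0.121, abs=1e-8)
        assert res.r2_adj == pytest.approx(1.0, abs=1e-10)

    def test_loglinear_agrees_with_nonlinear_on_noiseless_data(self):
        ltf = np.linspace(0, 25, 8)
        res = ExponentialGrowth(ltf, 1.7 * np.exp(0.09 * ltf)).fit()
        a0, b0 = res.loglinear_params
        assert a0 == pytest.approx(res.intercept_a, rel=1e-8)
        assert b0 == pytest.approx(res.rate_b, rel=1e-8)

    def test_f_statistic_has_anova_structure(self):
        rng = np.random.default_rng(5)
        ltf = np.linspace(0, 20, 30)
        y = 0.3 * np.exp(0.12 * ltf) * np.exp(rng.normal(0, 0.05, 30))
        res = ExponentialGrowth(ltf, y).fit()
        yhat = res.predict(ltf)
        ss_res = np.sum((y - yhat) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        expected_f = (ss_tot - ss_res) / (ss_res / (30 - 2))
        assert res.f_stat == pytest.approx(expected_f, rel=1e-10)
        assert res.f_stat > 0

    def test_too_few_points_rejected(self):
        with pytest.raises(FitError):
            fit_growth([(0.0, 1.0), (1.0, 2.0)])

    def test_non_positive_response_rejected(self):
        with pytest.raises(FitError):
            fit_growth([(0.0, 1.0), (1.0, 0.0), (2.0, 2.0)])

    def test_summary_mentions_estimates(self):
        ltf = np.array([0.0, 5.0, 10.0, 15.0])
        res = ExponentialGrowth(ltf, 0.5 * np.exp(0.1 * ltf), "dw").fit()
        text = res.summary()
        assert "dw" in text and "adj R2" in text


class TestBQuadratic:
    @pytest.mark.parametrize(
        "quad, f, expected",
        [
            (FW_QUADRATIC, 0.2, 0.1202),
            (FW_QUADRATIC, 0.0, 0.0665),
            (DW_QUADRATIC, 0.2, 0.0980),
        ],
    )
    def test_response_values(self, quad, f, expected):
        assert b_response(f, quad) == pytest.approx(expected, abs=5e-5)

    @pytest.mark.parametrize(
        "quad, b_max_printed",
        [(FW_QUADRATIC, 0.121), (DW_QUADRATIC, 0.099), (N_UPTAKE_QUADRATIC, 0.112)],
    )
    def test_vertex_maxima_round_to_published_values(self, quad, b_max_printed):
        _, b_max = optimal_n_rate(quad)
        assert round(b_max, 3) == b_max_printed

    def test_symmetric_toy_vertex(self):
        assert optimal_n_rate(BQuadratic(0.0, 2.0, -1.0)) == (1.0, 1.0)

    @pytest.mark.parametrize("quad", [FW_QUADRATIC, DW_QUADRATIC, N_UPTAKE_QUADRATIC])
    def test_first_order_condition(self, quad):
        f_star, b_max = optimal_n_rate(quad)
        assert quad.c1 + 2 * quad.c2 * f_star == pytest.approx(0.0, abs=1e-12)
        assert b_response(f_star, quad) == pytest.approx(b_max, abs=1e-12)

    def test_interval_constrained_maximum(self):
        # FW vertex is at F* = 0.23, outside the tested 0-0.2 range
        f_star, _ = optimal_n_rate(FW_QUADRATIC)
        assert f_star > 0.2
        f_c, b_c = optimal_n_rate(FW_QUADRATIC, interval=(0.0, 0.2))
        assert f_c == 0.2
        assert b_c == pytest.approx(b_response(0.2, FW_QUADRATIC))

    def test_no_interior_maximum_rejected(self):
        with pytest.raises(ValueError):
            optimal_n_rate(BQuadratic(0.0, 1.0, 0.5))


class TestFitBQuadratic:
    def test_exact_recovery_from_printed_coefficients(self):
        f = np.array([0.0, 0.05, 0.1, 0.2])
        quad = fit_b_quadratic(list(zip(f, b_response(f, FW_QUADRATIC))))
        assert quad.c0 == pytest.approx(FW_QUADRATIC.c0, abs=1e-9)
        assert quad.c1 == pytest.approx(FW_QUADRATIC.c1, abs=1e-9)
        assert quad.c2 == pytest.approx(FW_QUADRATIC.c2, abs=1e-9)
        assert quad.r2 == pytest.approx(1.0, abs=1e-12)

    def test_three_distinct_rates_fit_exactly(self):
        pts = [(0.0, 0.05), (0.1, 0.09), (0.2, 0.1), (0.1, 0.09)]
        quad = fit_b_quadratic(pts)
        for f, b in pts:
            assert b_response(f, quad) == pytest.approx(b, abs=1e-10)

    def test_noisy_recovery_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        f = np.repeat([0.0, 0.05, 0.1, 0.15, 0.2], 3)
        b = b_response(f, FW_QUADRATIC) + rng.normal(0, 0.003, size=len(f))
        quad = fit_b_quadratic(list(zip(f, b)))
        X = np.column_stack([np.ones_like(f), f, f**2])
        beta = np.linalg.solve(X.T @ X, X.T @ b)
        assert quad.c0 == pytest.approx(beta[0], rel=1e-8)
        assert quad.c1 == pytest.approx(beta[1], rel=1e-8)
        assert quad.c2 == pytest.approx(beta[2], rel=1e-8)

    def test_insufficient_design_rejected(self):
        with pytest.raises(FitError):
            fit_b_quadratic([(0.0, 1.0), (0.0, 1.1), (0.1, 1.2), (0.1, 1.3)])
        with pytest.raises(FitError):
            fit_b_quadratic([(0.0, 1.0), (0.1, 1.1), (0.2, 1.2)])


class TestConversions:
    def test_published_fw_dw_ratio(self):
        assert dw_to_fw(1.0) == pytest.approx(25.64)
        assert dw_to_fw(1.5) == pytest.approx(38.46)

    @given(st.floats(0, 1e4, allow_nan=False))
    @settings(deadline=None)
    def test_round_trips(self, x):
        conv = ConversionParams(plant_density=6.5e5)
        assert fw_to_dw(dw_to_fw(x, conv), conv) == pytest.approx(x, rel=1e-12, abs=1e-12)
        assert area_to_per_plant(per_plant_to_area(x, conv), conv) == pytest.approx(
            x, rel=1e-12, abs=1e-12
        )

    def test_unit_arithmetic(self):
        conv = ConversionParams(plant_density=1e6)
        assert per_plant_to_area(1.0, conv) == pytest.approx(1.0)

    def test_conversions_commute_with_areal_ratio(self):
        conv = ConversionParams(plant_density=4.2e5)
        dw = 2.3
        assert per_plant_to_area(dw_to_fw(dw, conv), conv) == pytest.approx(
            dw_to_fw(per_plant_to_area(dw, conv), conv)
        )

    def test_missing_density_is_a_config_error(self):
        with pytest.raises(ConfigError):
            per_plant_to_area(1.0, ConversionParams())
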