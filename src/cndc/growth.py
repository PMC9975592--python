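"""LTF-driven exponential growth models and the N-rate response of their rate.

Aboveground fresh weight (FW, g/plant), dry weight (DW, g/plant) and N
uptake (mg/plant) of pakchoi all follow

    Y(LTF) = a * exp(b * LTF)

where LTF is the cumulative photothermal effect (see
:mod:`cndc.photothermal`), ``a`` is the value at the start of
accumulation and ``b`` the relative growth rate per unit LTF.  For the
fresh-weight yield model the published parameters are a = 0.2816
g/plant and b = 0.121.

The rate parameter responds quadratically to the nitrogen application
rate F (g N per kg substrate), b(F) = c0 + c1*F + c2*F^2 with c2 < 0,
so an interior optimum exists at F* = -c1 / (2 c2).

Fitting follows the statsmodels Model/Results pattern:
``ExponentialGrowth(ltf, y).fit()`` returns an
:class:`ExponentialGrowthResults` with estimates, standard errors,
adjusted R^2 and the regression F statistic, all computed on the
natural (not log) scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import optimize

from ._exceptions import ConfigError, FitError

__all__ = [
    "GrowthFit",
    "BQuadratic",
    "ConversionParams",
    "ExponentialGrowth",
    "ExponentialGrowthResults",
    "predict_growth",
    "fit_growth",
    "b_response",
    "optimal_n_rate",
    "fit_b_quadratic",
    "dw_to_fw",
    "fw_to_dw",
    "per_plant_to_area",
    "area_to_per_plant",
    "FW_QUADRATIC",
    "DW_QUADRATIC",
    "N_UPTAKE_QUADRATIC",
]

Response = Literal["fw", "dw", "n_uptake"]


@dataclass(frozen=True)
class GrowthFit:
    """Parameters and diagnostics of one fitted exponential growth model.

    ``intercept_a`` is in g/plant for fw/dw and mg/plant for n_uptake;
    ``rate_b`` is per unit LTF.
    """

    intercept_a: float
    rate_b: float
    r2_adj: float
    f_stat: float
    n_obs: int
    response: Response = "fw"

    def __post_init__(self) -> None:
        if self.intercept_a <= 0:
            raise ValueError("intercept_a must be positive")
        if self.n_obs < 3:
            raise ValueError("n_obs must be at least 3")


#: Published FW-at-transplant yield model: FW = 0.2816 * exp(0.121 * LTF).
YIELD_MODEL = GrowthFit(
    intercept_a=0.2816, rate_b=0.121, r2_adj=float("nan"), f_stat=float("nan"),
    n_obs=3, response="fw",
)


def predict_growth(ltf, fit: GrowthFit | "ExponentialGrowthResults"):
    """Evaluate Y = a * exp(b * LTF); vectorised over ``ltf``."""
    arr = np.asarray(ltf, dtype=float)
    out = fit.intercept_a * np.exp(fit.rate_b * arr)
    return float(out) if np.isscalar(ltf) else out


class ExponentialGrowth:
    """Nonlinear least-squares model for Y = a * exp(b * LTF).

    The fit minimises residuals on the natural scale, initialised from
    the closed-form log-linear OLS solution; the log-scale estimates are
    kept on the results for comparison.  Deterministic and seed-free.

    Parameters
    ----------
    ltf : array-like
        Cumulative photothermal effect at each observation (>= 0).
    y : array-like
        Response values, strictly positive.
    response : {"fw", "dw", "n_uptake"}
        Which trajectory the data measure (labels the results).
    """

    def __init__(self, ltf, y, response: Response = "fw"):
        self.ltf = np.asarray(ltf, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.response = response
        if self.ltf.shape != self.y.shape:
            raise ValueError("ltf and y must have the same length")
        if len(self.y) < 3:
            raise FitError(f"need at least 3 points, got {len(self.y)}")
        if np.any(self.y <= 0):
            raise FitError("all response values must be positive")
        if np.any(self.ltf < 0):
            raise ValueError("ltf values must be non-negative")

    def _loglinear_start(self) -> tuple[float, float]:
        slope, intercept = np.polyfit(self.ltf, np.log(self.y), 1)
        return float(np.exp(intercept)), float(slope)

    def fit(self, xtol: float = 1e-10) -> "ExponentialGrowthResults":
        a0, b0 = self._loglinear_start()

        def residuals(theta):
            a, b = theta
            return a * np.exp(b * self.ltf) - self.y

        sol = optimize.least_squares(
            residuals, x0=[a0, b0], method="lm", xtol=xtol, ftol=1e-12, gtol=1e-12
        )
        if not sol.success:
            raise FitError(f"exponential fit did not converge: {sol.message}")
        return ExponentialGrowthResults(self, sol, loglinear=(a0, b0))


class ExponentialGrowthResults:
    """Fitted exponential growth model.

    Carries the :class:`GrowthFit` fields (``intercept_a``, ``rate_b``,
    ``r2_adj``, ``f_stat``, ``n_obs``, ``response``) plus standard
    errors, predictions and a text summary; ``loglinear_params`` holds
    the (a, b) from the log-scale OLS used as the starting point.
    """

    def __init__(self, model: ExponentialGrowth, sol, loglinear):
        a, b = (float(v) for v in sol.x)
        y, yhat = model.y, a * np.exp(b * model.ltf)
        n = len(y)
        ss_res = float(np.sum((y - yhat) ** 2))
        ss_tot = float(np.sum((y - np.mean(y)) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        # regression ANOVA with 1 model df (the rate) and n-2 residual df
        ss_reg = ss_tot - ss_res
        self.model = model
        self.intercept_a = a
        self.rate_b = b
        self.rsquared = r2
        self.r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        self.f_stat = np.inf if ss_res == 0 else (ss_reg / 1.0) / (ss_res / (n - 2))
        self.n_obs = n
        self.response = model.response
        self.loglinear_params = loglinear
        # Gauss-Newton covariance of (a, b) on the natural scale
        dof = n - 2
        if dof > 0 and ss_res > 0:
            try:
                cov = np.linalg.inv(sol.jac.T @ sol.jac) * ss_res / dof
                self.bse = tuple(float(s) for s in np.sqrt(np.diag(cov)))
            except np.linalg.LinAlgError:
                self.bse = (float("nan"), float("nan"))
        else:
            self.bse = (0.0, 0.0)

    def to_growth_fit(self) -> GrowthFit:
        """The estimates as an immutable :class:`GrowthFit` record."""
        return GrowthFit(
            intercept_a=self.intercept_a,
            rate_b=self.rate_b,
            r2_adj=self.r2_adj,
            f_stat=self.f_stat,
            n_obs=self.n_obs,
            response=self.response,
        )

    def predict(self, ltf):
        return predict_growth(ltf, self)

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "a": self.intercept_a,
            "b": self.rate_b,
            "adj_r2": self.r2_adj,
            "f_value": self.f_stat,
            "n": self.n_obs,
        }

    def summary(self) -> str:
        se_a, se_b = self.bse
        return "\n".join(
            [
                f"Exponential growth fit ({self.response}):  Y = a * exp(b * LTF)",
                f"  a = {self.intercept_a:.4f} (se {se_a:.4f})   "
                f"b = {self.rate_b:.4f} (se {se_b:.4f})",
                f"  adj R2 = {self.r2_adj:.4f}   F = {self.f_stat:.2f}   "
                f"n = {self.n_obs}",
                f"  log-scale start: a = {self.loglinear_params[0]:.4f}, "
                f"b = {self.loglinear_params[1]:.4f}",
            ]
        )


def fit_growth(
    points: Sequence[tuple[float, float]], response: Response = "fw"
) -> ExponentialGrowthResults:
    """Fit Y = a * exp(b * LTF) to (ltf, y) pairs."""
    ltf, y = zip(*points)
    return ExponentialGrowth(np.array(ltf), np.array(y), response).fit()


# ---------------------------------------------------------------------------
# quadratic response of the rate parameter to N application


@dataclass(frozen=True)
class BQuadratic:
    """Quadratic response b(F) = c0 + c1*F + c2*F^2 of the growth rate to
    the N application rate F (g N per kg substrate)."""

    c0: float
    c1: float
    c2: float
    r2: float = float("nan")

    def __call__(self, n_rate):
        return b_response(n_rate, self)


#: Published quadratic coefficient sets for the three responses.
FW_QUADRATIC = BQuadratic(0.0665, 0.4749, -1.0323, r2=0.9649)
DW_QUADRATIC = BQuadratic(0.0729, 0.2052, -0.3986, r2=0.9026)
N_UPTAKE_QUADRATIC = BQuadratic(0.0599, 0.4114, -0.8141, r2=0.8588)


def b_response(n_rate, quad: BQuadratic):
    """Growth-rate parameter b at N application rate ``n_rate`` (g N/kg)."""
    arr = np.asarray(n_rate, dtype=float)
    if np.any(arr < 0):
        raise ValueError("n_rate must be non-negative")
    out = quad.c0 + quad.c1 * arr + quad.c2 * arr**2
    return float(out) if np.isscalar(n_rate) else out


def optimal_n_rate(
    quad: BQuadratic, interval: tuple[float, float] | None = None
) -> tuple[float, float]:
    """Vertex of the quadratic: the N rate maximising b and the maximum b.

    Returns the unconstrained vertex ``(f_star, b_max)``.  If
    ``interval`` is given, the maximiser over that closed interval is
    returned instead (the vertex if interior, else the better endpoint).
    """
    if quad.c2 >= 0:
        raise ValueError("no interior maximum: c2 must be negative")
    f_star = -quad.c1 / (2.0 * quad.c2)
    b_max = quad.c0 - quad.c1**2 / (4.0 * quad.c2)
    if interval is not None:
        lo, hi = interval
        candidates = [lo, hi] + ([f_star] if lo <= f_star <= hi else [])
        f_star = max(candidates, key=lambda f: quad.c0 + quad.c1 * f + quad.c2 * f**2)
        b_max = quad.c0 + quad.c1 * f_star + quad.c2 * f_star**2
    return float(f_star), float(b_max)


def fit_b_quadratic(points: Sequence[tuple[float, float]]) -> BQuadratic:
    """OLS degree-2 polynomial fit of (n_rate, b) pairs.

    Requires at least 4 points spanning at least 3 distinct rates.
    """
    if len(points) < 4:
        raise FitError(f"need at least 4 points, got {len(points)}")
    f, b = map(np.asarray, zip(*points))
    if len(np.unique(f)) < 3:
        raise FitError("need at least 3 distinct N rates for a quadratic fit")
    c2, c1, c0 = np.polyfit(f, b, 2)
    pred = c0 + c1 * f + c2 * f**2
    ss_tot = float(np.sum((b - b.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum((b - pred) ** 2)) / ss_tot
    return BQuadratic(float(c0), float(c1), float(c2), r2=r2)


# ---------------------------------------------------------------------------
# biomass unit conversions


@dataclass(frozen=True)
class ConversionParams:
    """Biomass unit conversions.

    ``fw_dw_ratio`` is the fresh-to-dry weight ratio (FW = ratio * DW;
    25.64 for pakchoi).  ``plant_density`` (plants/ha) converts per-plant
    masses to areal t/ha; it has no default because the source
    experiments never state one — any areal computation must set it.
    """

    fw_dw_ratio: float = 25.64
    plant_density: float | None = None

    def __post_init__(self) -> None:
        if self.fw_dw_ratio <= 0:
            raise ValueError("fw_dw_ratio must be positive")
        if self.plant_density is not None and self.plant_density <= 0:
            raise ValueError("plant_density must be positive")


def dw_to_fw(dw, conv: ConversionParams = ConversionParams()):
    """Fresh weight from dry weight (same units, e.g. g/plant)."""
    arr = np.asarray(dw, dtype=float)
    if np.any(arr < 0):
        raise ValueError("biomass must be non-negative")
    out = arr * conv.fw_dw_ratio
    return float(out) if np.isscalar(dw) else out


def fw_to_dw(fw, conv: ConversionParams = ConversionParams()):
    """Dry weight from fresh weight (inverse of :func:`dw_to_fw`)."""
    arr = np.asarray(fw, dtype=float)
    if np.any(arr < 0):
        raise ValueError("biomass must be non-negative")
    out = arr / conv.fw_dw_ratio
    return float(out) if np.isscalar(fw) else out


def _require_density(conv: ConversionParams) -> float:
    if conv.plant_density is None:
        raise ConfigError(
            "plant_density is not set; areal conversions (g/plant <-> t/ha) "
            "require an explicit planting density"
        )
    return conv.plant_density


def per_plant_to_area(y, conv: ConversionParams):
    """Convert g/plant to t/ha using the configured planting density."""
    density = _require_density(conv)
    out = np.asarray(y, dtype=float) * density * 1e-6
    return float(out) if np.isscalar(y) else out


def area_to_per_plant(y, conv: ConversionParams):
    """Convert t/ha to g/plant (inverse of :func:`per_plant_to_area`)."""
    density = _require_density(conv)
    out = np.asarray(y, dtype=float) * 1e6 / density
    return float(out) if np.isscalar(y) else out
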