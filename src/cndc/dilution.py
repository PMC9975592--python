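"""Critical nitrogen dilution curve, N envelope curves and the NNI.

As a crop accumulates biomass, the whole-plant nitrogen concentration
that just sustains maximum growth declines ("dilution").  For pakchoi
the critical N content Nc (% of dry weight) is a plateau at low biomass
joined to an allometric power law:

    Nc(DW) = 4.78 %                  for DW <= 1.5 t/ha
    Nc(DW) = 4.78 * DW^-0.33         for DW  > 1.5 t/ha

with the plateau equal to 0.7 * Nmax (Nmax = 6.83 %, the mean measured
N content at full cotyledon expansion).  Maximum and minimum envelopes
use the same exponent with plateaus Nmax and 0.4 * Nmax and power-law
coefficients chosen so the branches join at DW = 2 and 0.5 t/ha
respectively (the CropSyst-style recipe a_max = Nmax * 2^b,
a_c = 0.7 Nmax * 1.5^b, a_min = 0.4 Nmax * 0.5^b).

The published critical curve uses the plateau value itself (4.78) as
the power-law coefficient, which makes Nc drop discontinuously at the
breakpoint; the recipe coefficient a_c instead gives a continuous
curve.  Both are available through ``DilutionParams.mode``
(``"as_printed"``, the default, vs ``"continuous"``).

The nitrogen nutrition index NNI = Na / Nc diagnoses crop N status:
1 is optimal, below 1 deficient, above 1 luxury uptake.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import statsmodels.api as sm

from ._exceptions import FitError

__all__ = [
    "DilutionParams",
    "NStatus",
    "critical_n",
    "n_max_curve",
    "n_min_curve",
    "nni",
    "classify_status",
    "DilutionCurveModel",
    "DilutionCurveResults",
    "fit_dilution",
]

Mode = Literal["as_printed", "continuous"]


@dataclass(frozen=True)
class DilutionParams:
    """Parameters of the N dilution envelope for one crop.

    Attributes
    ----------
    n_max_pct : float
        Maximum whole-plant N content Nmax, % of dry weight. Default
        6.83 (pakchoi, mean of the four day-11 treatment means).
    plateau_fraction_c : float
        Critical plateau as a fraction of Nmax (0.7).
    plateau_fraction_min : float
        Minimum plateau as a fraction of Nmax (0.4).
    exponent_b : float
        Dilution exponent b of the power law DW^-b. Default 0.33.
    dw_break : float
        Dry-biomass breakpoint (t/ha) where the critical curve leaves
        its plateau. Default 1.5.
    mode : {"as_printed", "continuous"}
        ``as_printed`` uses the plateau value as power-law coefficient
        (discontinuous at the breakpoint); ``continuous`` uses the
        recipe coefficient a_c = plateau * dw_break^b.
    """

    n_max_pct: float = 6.83
    plateau_fraction_c: float = 0.7
    plateau_fraction_min: float = 0.4
    exponent_b: float = 0.33
    dw_break: float = 1.5
    mode: Mode = "as_printed"

    def __post_init__(self) -> None:
        if not (0 < self.plateau_fraction_min < self.plateau_fraction_c < 1):
            raise ValueError("need 0 < plateau_fraction_min < plateau_fraction_c < 1")
        if self.exponent_b <= 0 or self.dw_break <= 0 or self.n_max_pct <= 0:
            raise ValueError("exponent_b, dw_break and n_max_pct must be positive")
        if self.mode not in ("as_printed", "continuous"):
            raise ValueError(f"unknown mode {self.mode!r}")

    # derived coefficients -------------------------------------------------
    @property
    def plateau_c(self) -> float:
        """Critical plateau value, % of DW (0.7 * Nmax = 4.78 for defaults)."""
        return self.plateau_fraction_c * self.n_max_pct

    @property
    def a_c(self) -> float:
        """Continuous-mode power-law coefficient of the critical curve."""
        return self.plateau_c * self.dw_break**self.exponent_b

    @property
    def a_max(self) -> float:
        """Power-law coefficient of the Nmax curve (joins the plateau at DW=2)."""
        return self.n_max_pct * 2.0**self.exponent_b

    @property
    def a_min(self) -> float:
        """Power-law coefficient of the Nmin curve (joins the plateau at DW=0.5)."""
        return self.plateau_fraction_min * self.n_max_pct * 0.5**self.exponent_b

    def fw_break(self, fw_dw_ratio: float = 25.64) -> float:
        """Fresh-biomass equivalent of the DW breakpoint (t/ha)."""
        return fw_dw_ratio * self.dw_break


def _check_dw(dw) -> np.ndarray:
    arr = np.asarray(dw, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("dry biomass must be positive (t/ha)")
    return arr


def critical_n(dw, params: DilutionParams = DilutionParams()):
    """Critical N content Nc (% of DW) at aboveground dry biomass ``dw`` (t/ha).

    Vectorised over ``dw``. The breakpoint itself belongs to the plateau.
    """
    arr = _check_dw(dw)
    if params.mode == "as_printed":
        out = np.where(
            arr <= params.dw_break,
            params.plateau_c,
            params.plateau_c * arr ** (-params.exponent_b),
        )
    else:
        out = np.minimum(params.plateau_c, params.a_c * arr ** (-params.exponent_b))
    return float(out) if np.isscalar(dw) else out


def n_max_curve(dw, params: DilutionParams = DilutionParams()):
    """Maximum (luxury) N content envelope, % of DW."""
    arr = _check_dw(dw)
    out = np.minimum(params.n_max_pct, params.a_max * arr ** (-params.exponent_b))
    return float(out) if np.isscalar(dw) else out


def n_min_curve(dw, params: DilutionParams = DilutionParams()):
    """Minimum (structural) N content envelope, % of DW."""
    arr = _check_dw(dw)
    out = np.minimum(
        params.plateau_fraction_min * params.n_max_pct,
        params.a_min * arr ** (-params.exponent_b),
    )
    return float(out) if np.isscalar(dw) else out


def nni(na_pct: float, nc_pct: float) -> float:
    """Nitrogen nutrition index, the ratio of actual to critical N content."""
    if nc_pct <= 0:
        raise ValueError(f"critical N content must be positive, got {nc_pct}")
    if na_pct < 0:
        raise ValueError(f"actual N content must be non-negative, got {na_pct}")
    return na_pct / nc_pct


@dataclass(frozen=True)
class NStatus:
    """Diagnosed N nutrition status of one plant state."""

    nni: float
    label: Literal["deficient", "optimal", "excess"]
    tolerance: float


def classify_status(nni_value: float, tolerance: float = 0.05) -> NStatus:
    """Classify an NNI into deficient / optimal / excess.

    ``optimal`` means |NNI - 1| <= tolerance; the tolerance exists because
    a strict NNI == 1 is unattainable in floating-point pipelines.
    """
    if nni_value < 0 or tolerance < 0:
        raise ValueError("nni_value and tolerance must be non-negative")
    if nni_value < 1.0 - tolerance:
        label = "deficient"
    elif nni_value > 1.0 + tolerance:
        label = "excess"
    else:
        label = "optimal"
    return NStatus(nni=nni_value, label=label, tolerance=tolerance)


class DilutionCurveModel:
    """Log-log regression model for the dilution power law Nc = a * DW^-b.

    Only samples with ``dw > dw_break`` enter the fit: plateau points do
    not carry information about the power law.  Fitting is ordinary
    least squares of ln(N%) on ln(DW); ``a = exp(intercept)`` and
    ``b = -slope``.

    Parameters
    ----------
    dw : array-like
        Aboveground dry biomass, t/ha.
    n_pct : array-like
        Measured N content, % of DW.
    dw_break : float
        Plateau breakpoint; points at or below it are excluded.

    Examples
    --------
    >>> import numpy as np
    >>> dw = np.array([2.0, 3.0, 4.0, 5.0])
    >>> res = DilutionCurveModel(dw, 4.78 * dw ** -0.33).fit()
    >>> round(res.a, 2), round(res.b, 2)
    (4.78, 0.33)
    """

    def __init__(self, dw, n_pct, dw_break: float = 1.5):
        dw = np.asarray(dw, dtype=float)
        n_pct = np.asarray(n_pct, dtype=float)
        if dw.shape != n_pct.shape:
            raise ValueError("dw and n_pct must have the same length")
        mask = dw > dw_break
        self.dw_break = dw_break
        self.n_excluded = int((~mask).sum())
        self.dw = dw[mask]
        self.n_pct = n_pct[mask]
        if len(self.dw) < 3:
            raise FitError(
                f"need at least 3 samples with dw > {dw_break} t/ha for the "
                f"power-law fit, got {len(self.dw)}"
            )
        if np.any(self.n_pct <= 0):
            raise FitError("N contents must be positive for the log-log fit")

    def fit(self) -> "DilutionCurveResults":
        X = sm.add_constant(np.log(self.dw))
        ols = sm.OLS(np.log(self.n_pct), X).fit()
        return DilutionCurveResults(self, ols)


class DilutionCurveResults:
    """Fitted dilution power law with OLS diagnostics."""

    def __init__(self, model: DilutionCurveModel, ols_results):
        self.model = model
        self._ols = ols_results
        self.a = float(np.exp(ols_results.params[0]))
        self.b = float(-ols_results.params[1])
        self.rsquared = float(ols_results.rsquared)
        self.nobs = int(ols_results.nobs)

    @property
    def bse(self) -> tuple[float, float]:
        """Standard errors of (ln a, b) from the log-scale regression."""
        se = self._ols.bse
        return float(se[0]), float(se[1])

    def predict(self, dw):
        """Nc predicted by the fitted power law (no plateau applied)."""
        return self.a * np.asarray(dw, dtype=float) ** (-self.b)

    def to_dict(self) -> dict:
        return {"a": self.a, "b": self.b, "r2": self.rsquared, "n_points": self.nobs}

    def summary(self) -> str:
        lines = [
            "Dilution curve fit  Nc = a * DW^-b  (log-log OLS)",
            f"  n points (dw > {self.model.dw_break}): {self.nobs}"
            f"  (excluded plateau points: {self.model.n_excluded})",
            f"  a = {self.a:.4f} %   b = {self.b:.4f}   R2 = {self.rsquared:.4f}",
        ]
        return "\n".join(lines)


def fit_dilution(
    samples: Sequence[tuple[float, float]], dw_break: float = 1.5
) -> tuple[float, float, float]:
    """Fit the power law to (dw, n_pct) pairs; returns ``(a, b, r2)``."""
    dw, n_pct = zip(*samples)
    res = DilutionCurveModel(np.array(dw), np.array(n_pct), dw_break).fit()
    return res.a, res.b, res.rsquared
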