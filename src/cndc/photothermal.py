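"""Photothermal effect accumulation from hourly greenhouse weather.

Crop growth in a greenhouse is driven jointly by temperature and light.
This module turns an hourly weather series (air temperature in deg C and
photosynthetically active radiation, PAR, in mol m^-2 h^-1) into a daily
dimensionless photothermal index and its running sum over the growth
period, the cumulative photothermal effect (LTF):

    LTF = sum_j fT(j) * fI(j)

where, on day j, ``fT`` is a piecewise-linear suitability of temperature
between the cardinal temperatures (base Tb, optimum T0, maximum Tm) and
``fI = 1 - exp(-alpha * I)`` is a saturating response to the daily PAR
integral I (mmol m^-2 d^-1).  LTF replaces calendar time as the
independent variable of the growth models in :mod:`cndc.growth`.

Aggregation convention: fT is evaluated on each hourly temperature and
averaged over the 24 h of a calendar day; hourly PAR is integrated over
the day (mol -> mmol) before fI is applied.  Days with missing hours are
not padded: interior gaps raise :class:`~cndc._exceptions.WeatherDataError`
while partial first/last days are dropped from the series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from ._exceptions import WeatherDataError

__all__ = [
    "WeatherRecord",
    "ThermalLightParams",
    "DailyEffect",
    "temperature_effect",
    "light_effect",
    "daily_effects",
    "cumulative_ltf",
]

#: mol -> mmol conversion for the daily PAR integral.
MOL_TO_MMOL = 1000.0


class WeatherRecord(NamedTuple):
    """One hourly weather observation."""

    timestamp: pd.Timestamp  #: calendar date + hour
    temp_c: float            #: hourly mean air temperature, deg C
    par_mol_m2: float        #: PAR received during that hour, mol m^-2


@dataclass(frozen=True)
class ThermalLightParams:
    """Cardinal temperatures and light-response curvature.

    Parameters
    ----------
    t_base : float
        Base temperature Tb (deg C) below which growth stops. Default 7.
    t_opt : float
        Optimum temperature T0 (deg C) where the thermal effect is 1.
        Default 24.
    t_max : float
        Maximum temperature Tm (deg C) above which growth stops.
        Default 35.
    alpha : float
        Curvature of the light response, per mmol m^-2 d^-1.
        Default 0.001, which saturates fI near 1 at typical greenhouse
        daily PAR integrals of 5-10 mol m^-2.
    """

    t_base: float = 7.0
    t_opt: float = 24.0
    t_max: float = 35.0
    alpha: float = 0.001

    def __post_init__(self) -> None:
        if not (self.t_base < self.t_opt < self.t_max):
            raise ValueError(
                "cardinal temperatures must satisfy t_base < t_opt < t_max, "
                f"got {self.t_base}, {self.t_opt}, {self.t_max}"
            )
        if not self.alpha > 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")


class DailyEffect(NamedTuple):
    """Daily photothermal factors for one calendar day."""

    day_index: int        #: days since the start of the series (0-based)
    f_t: float            #: mean hourly thermal effect, in [0, 1]
    f_i: float            #: light effect of the daily PAR integral, in [0, 1)
    daily_par: float      #: daily PAR integral, mmol m^-2 d^-1


def temperature_effect(t: float, params: ThermalLightParams = ThermalLightParams()) -> float:
    """Piecewise-linear thermal suitability of an hourly temperature.

    Rises linearly from 0 at ``t_base`` to 1 at ``t_opt``, then falls
    linearly back to 0 at ``t_max``; 0 outside the (t_base, t_max) window.

    Examples
    --------
    >>> temperature_effect(24.0)
    1.0
    >>> temperature_effect(7.0), temperature_effect(35.0)
    (0.0, 0.0)
    """
    if t <= params.t_base or t >= params.t_max:
        return 0.0
    if t < params.t_opt:
        return (t - params.t_base) / (params.t_opt - params.t_base)
    if t > params.t_opt:
        return (params.t_max - t) / (params.t_max - params.t_opt)
    return 1.0


def light_effect(daily_par: float, params: ThermalLightParams = ThermalLightParams()) -> float:
    """Saturating light response ``1 - exp(-alpha * I)``.

    Parameters
    ----------
    daily_par : float
        Daily PAR integral I in mmol m^-2 d^-1 (multiply a value reported
        in mol m^-2 by 1000).

    Returns
    -------
    float in [0, 1), strictly increasing in ``daily_par``.
    """
    if daily_par < 0:
        raise ValueError(f"daily_par must be non-negative, got {daily_par}")
    return 1.0 - math.exp(-params.alpha * daily_par)


def _to_frame(weather: Iterable[WeatherRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(weather, pd.DataFrame):
        df = weather.copy()
        if "timestamp" not in df.columns:
            if {"date", "hour"}.issubset(df.columns):
                df["timestamp"] = pd.to_datetime(df["date"]) + pd.to_timedelta(
                    df["hour"], unit="h"
                )
            else:
                raise WeatherDataError(
                    "weather frame needs a 'timestamp' column or 'date'+'hour' columns"
                )
        df = df.rename(columns={"par_mol_m2": "par_mol_m2", "temp_c": "temp_c"})
    else:
        df = pd.DataFrame(list(weather), columns=["timestamp", "temp_c", "par_mol_m2"])
        df["timestamp"] = pd.to_datetime(df["timestamp"])
    if df.empty:
        raise WeatherDataError("weather series is empty")
    if not df["timestamp"].is_monotonic_increasing or df["timestamp"].duplicated().any():
        raise WeatherDataError("timestamps must be strictly increasing")
    if (df["par_mol_m2"] < 0).any():
        raise WeatherDataError("PAR values must be non-negative")
    if not np.isfinite(df["temp_c"]).all():
        raise WeatherDataError("temperatures must be finite")
    return df


def daily_effects(
    weather: Iterable[WeatherRecord] | pd.DataFrame,
    params: ThermalLightParams = ThermalLightParams(),
) -> list[DailyEffect]:
    """Aggregate an hourly weather series into daily photothermal factors.

    Each complete calendar day yields one :class:`DailyEffect` with
    ``f_t`` = mean of the 24 hourly :func:`temperature_effect` values and
    ``f_i`` = :func:`light_effect` of the daily PAR sum (converted mol ->
    mmol).  Partial first/last days are dropped; a day that is neither
    first nor last but has missing hours raises
    :class:`~cndc._exceptions.WeatherDataError`.
    """
    df = _to_frame(weather)
    df["date"] = df["timestamp"].dt.normalize()
    counts = df.groupby("date", sort=True).size()
    dates = counts.index
    complete = counts == 24
    # partial days allowed only at the series boundaries
    interior_bad = complete.iloc[1:-1][~complete.iloc[1:-1]] if len(counts) > 2 else complete.iloc[0:0]
    if len(interior_bad):
        day = interior_bad.index[0].date()
        raise WeatherDataError(
            f"day {day} has {counts.loc[interior_bad.index[0]]} hourly records; "
            "gaps of more than 1 hour within a day are not allowed"
        )
    keep = dates[complete]
    if len(keep) == 0:
        raise WeatherDataError("weather series contains no complete calendar day")
    df = df[df["date"].isin(keep)]
    out: list[DailyEffect] = []
    for j, (date, grp) in enumerate(df.groupby("date", sort=True)):
        hours = grp["timestamp"].dt.hour.to_numpy()
        if len(np.unique(hours)) != 24:
            raise WeatherDataError(f"day {date.date()} does not cover all 24 hours")
        f_t = float(np.mean([temperature_effect(t, params) for t in grp["temp_c"]]))
        daily_par = float(grp["par_mol_m2"].sum()) * MOL_TO_MMOL
        out.append(DailyEffect(j, f_t, light_effect(daily_par, params), daily_par))
    return out


def cumulative_ltf(
    effects: Sequence[DailyEffect], start_day: int = 0, end_day: int | None = None
) -> float:
    """Cumulative photothermal effect over [start_day, end_day] inclusive.

    An empty range (``start_day > end_day``) returns 0 by convention.
    """
    if end_day is None:
        end_day = len(effects) - 1
    if start_day > end_day:
        return 0.0
    indices = {e.day_index for e in effects}
    for d in (start_day, end_day):
        if d not in indices:
            raise IndexError(f"day {d} is outside the weather series (have days {min(indices)}..{max(indices)})")
    return float(
        sum(e.f_t * e.f_i for e in effects if start_day <= e.day_index <= end_day)
    )


def ltf_series(effects: Sequence[DailyEffect]) -> pd.Series:
    """Running LTF indexed by day: value at day j is LTF over days 0..j."""
    eff = sorted(effects, key=lambda e: e.day_index)
    vals = np.cumsum([e.f_t * e.f_i for e in eff])
    return pd.Series(vals, index=[e.day_index for e in eff], name="ltf")
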