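"""Nitrogen demand and supply from plant state and the critical curve.

Crop N demand is the fertiliser N needed to close the gap between the
critical and the actual N concentration of the standing biomass:

    N_demand = 0.39 * FW * (Nc - Na) / 100        [g/plant]
    N_supply = N_demand / use_efficiency          [g/plant]

with FW the aboveground fresh weight (g/plant), Nc and Na in % of dry
weight and 0.39 an empirically calibrated crop coefficient.  The N
contents enter as fractions (hence /100): that is the only reading of
the published equation under which demands land in the tens of
milligrams per plant, the scale of the reported verification error.

Use efficiency is the fraction of supplied N the crop actually
captures: 0.38 for substrate culture and 0.17 for soil culture.

A negative gap (Na > Nc, luxury uptake) is reported as zero demand
plus a ``surplus`` quantity — a fertiliser recommendation cannot be
negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from . import dilution as _dil
from ._exceptions import ConfigError

__all__ = [
    "USE_EFFICIENCY",
    "DemandParams",
    "DemandResult",
    "n_demand",
    "n_supply",
    "demand_report",
]

#: Measured apparent N use efficiency by cultivation system.
USE_EFFICIENCY: dict[str, float] = {"substrate": 0.38, "soil": 0.17}

System = Literal["substrate", "soil"]


@dataclass(frozen=True)
class DemandParams:
    """Crop coefficient and N use efficiency for demand/supply budgeting."""

    crop_coefficient: float = 0.39
    use_efficiency: float = USE_EFFICIENCY["substrate"]
    system: System = "substrate"

    def __post_init__(self) -> None:
        if self.crop_coefficient <= 0:
            raise ValueError("crop_coefficient must be positive")
        if not (0 < self.use_efficiency <= 1):
            raise ConfigError(
                f"use_efficiency must be in (0, 1], got {self.use_efficiency}"
            )

    @classmethod
    def for_system(cls, system: System, crop_coefficient: float = 0.39) -> "DemandParams":
        """Parameters with the measured efficiency of a cultivation system."""
        if system not in USE_EFFICIENCY:
            raise ConfigError(
                f"unknown system {system!r}; choose from {sorted(USE_EFFICIENCY)}"
            )
        return cls(
            crop_coefficient=crop_coefficient,
            use_efficiency=USE_EFFICIENCY[system],
            system=system,
        )


@dataclass(frozen=True)
class DemandResult:
    """Full N diagnosis for one plant state."""

    nc_pct: float
    na_pct: float
    nni: float
    status: _dil.NStatus
    n_demand: float        #: g/plant, >= 0
    n_supply: float        #: g/plant, >= 0
    surplus: float = 0.0   #: g/plant of N above the critical level, >= 0


def n_demand(fw: float, nc_pct: float, na_pct: float,
             params: DemandParams = DemandParams()) -> float:
    """Signed N demand (g/plant); negative means luxury uptake.

    Percentages enter as fractions: demand = k * FW * (Nc - Na)/100.

    >>> round(n_demand(30.0, 4.78, 3.78), 4)
    0.117
    """
    if fw < 0 or nc_pct < 0 or na_pct < 0:
        raise ValueError("fw and N percentages must be non-negative")
    return params.crop_coefficient * fw * (nc_pct - na_pct) / 100.0


def n_supply(demand: float, params: DemandParams = DemandParams()) -> float:
    """N to apply so the crop captures ``demand`` grams, given use efficiency."""
    if demand < 0:
        raise ValueError("demand must be non-negative; clip surplus first")
    return demand / params.use_efficiency


def demand_report(
    fw: float,
    dw_area: float,
    na_pct: float,
    dil: _dil.DilutionParams = _dil.DilutionParams(),
    params: DemandParams = DemandParams(),
    tolerance: float = 0.05,
) -> DemandResult:
    """Diagnose one plant state and budget its N demand and supply.

    Parameters
    ----------
    fw : float
        Aboveground fresh weight, g/plant.
    dw_area : float
        Aboveground dry biomass on an areal basis, t/ha (the domain of
        the dilution curve).
    na_pct : float
        Measured actual N content, % of DW.
    """
    nc = _dil.critical_n(dw_area, dil)
    index = _dil.nni(na_pct, nc)
    status = _dil.classify_status(index, tolerance)
    gap = n_demand(fw, nc, na_pct, params)
    demand = max(gap, 0.0)
    surplus = max(-gap, 0.0)
    return DemandResult(
        nc_pct=nc,
        na_pct=na_pct,
        nni=index,
        status=status,
        n_demand=demand,
        n_supply=n_supply(demand, params),
        surplus=surplus,
    )
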