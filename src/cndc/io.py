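"""CSV dialects, JSON reports and the pipeline configuration file.

Three small CSV dialects are used throughout (comma-separated, UTF-8,
header required, locale-independent decimal points):

========================  =============================================
dialect                   required columns
========================  =============================================
weather                   ``date`` (ISO-8601), ``hour`` (0-23),
                          ``temp_c``, ``par_mol_m2``
dilution samples          ``dw_t_ha``, ``n_pct``
growth points             ``ltf``, ``y``, ``response``, ``treatment``
plant state               ``fw_g``, ``dw_t_ha``, ``na_pct``
========================  =============================================

Extra columns are preserved and ignored.  Schema violations raise
:class:`~cndc._exceptions.SchemaError` naming the offending column and
data line.  The config file is YAML with units spelled out in the key
names and round-trips losslessly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._exceptions import SchemaError
from .demand import DemandParams
from .dilution import DilutionParams
from .growth import ConversionParams
from .photothermal import ThermalLightParams

__all__ = [
    "PipelineConfig",
    "load_config",
    "save_config",
    "read_weather_csv",
    "read_samples_csv",
    "read_growth_csv",
    "read_plant_state_csv",
    "write_json_report",
]


def _read_csv(path, required: dict[str, bool], what: str) -> pd.DataFrame:
    """required maps column -> must-be-numeric."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file, expected a {what} CSV with header")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {missing} for a {what} CSV "
            f"(found {list(df.columns)})"
        )
    if df.empty:
        raise SchemaError(f"{path}: header only, no data rows")
    for col, numeric in required.items():
        if not numeric:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            # +2: one for the header line, one for 0-based indexing
            lines = [int(i) + 2 for i in bad[:5]]
            raise SchemaError(
                f"{path}: non-numeric values in column {col!r} at line(s) {lines}"
            )
        if coerced.isna().any():
            lines = [int(i) + 2 for i in df.index[coerced.isna()][:5]]
            raise SchemaError(f"{path}: missing values in column {col!r} at line(s) {lines}")
        df[col] = coerced
    return df


def read_weather_csv(path) -> pd.DataFrame:
    """Read and schema-check an hourly weather CSV."""
    df = _read_csv(
        path, {"date": False, "hour": True, "temp_c": True, "par_mol_m2": True},
        "weather",
    )
    if not df["hour"].between(0, 23).all():
        bad = int(df.index[~df["hour"].between(0, 23)][0]) + 2
        raise SchemaError(f"{path}: hour outside 0-23 at line {bad}")
    if (df["par_mol_m2"] < 0).any():
        bad = int(df.index[df["par_mol_m2"] < 0][0]) + 2
        raise SchemaError(f"{path}: negative PAR at line {bad}")
    return df


def read_samples_csv(path) -> pd.DataFrame:
    """Read a dilution-samples CSV (``dw_t_ha``, ``n_pct``)."""
    df = _read_csv(path, {"dw_t_ha": True, "n_pct": True}, "dilution samples")
    if (df["dw_t_ha"] <= 0).any() or (df["n_pct"] <= 0).any():
        raise SchemaError(f"{path}: dw_t_ha and n_pct must be positive")
    return df


def read_growth_csv(path) -> pd.DataFrame:
    """Read a growth-points CSV (``ltf``, ``y``, ``response``, ``treatment``)."""
    df = _read_csv(
        path, {"ltf": True, "y": True, "response": False, "treatment": False},
        "growth points",
    )
    if (df["y"] <= 0).any():
        raise SchemaError(f"{path}: growth responses y must be positive")
    return df


def read_plant_state_csv(path) -> pd.DataFrame:
    """Read a plant-state CSV (``fw_g``, ``dw_t_ha``, ``na_pct``)."""
    df = _read_csv(
        path, {"fw_g": True, "dw_t_ha": True, "na_pct": True}, "plant state"
    )
    if (df["dw_t_ha"] <= 0).any():
        raise SchemaError(f"{path}: dw_t_ha must be positive")
    return df


def write_json_report(obj, path) -> None:
    """Write a JSON report with stable key order and full float precision."""
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=default))


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """All model parameters for one pipeline run, plus the seed."""

    thermal_light: ThermalLightParams = field(default_factory=ThermalLightParams)
    dilution: DilutionParams = field(default_factory=DilutionParams)
    conversion: ConversionParams = field(default_factory=ConversionParams)
    demand: DemandParams = field(default_factory=DemandParams)
    seed: int = 0

    def to_dict(self) -> dict:
        tl, dl, cv, dm = self.thermal_light, self.dilution, self.conversion, self.demand
        return {
            "thermal_light": {
                "t_base_c": tl.t_base, "t_opt_c": tl.t_opt, "t_max_c": tl.t_max,
                "alpha_per_mmol_m2_d": tl.alpha,
            },
            "dilution": {
                "n_max_pct_dw": dl.n_max_pct,
                "plateau_fraction_c": dl.plateau_fraction_c,
                "plateau_fraction_min": dl.plateau_fraction_min,
                "exponent_b": dl.exponent_b,
                "dw_break_t_ha": dl.dw_break,
                "mode": dl.mode,
            },
            "conversion": {
                "fw_dw_ratio": cv.fw_dw_ratio,
                "plant_density_per_ha": cv.plant_density,
            },
            "demand": {
                "crop_coefficient": dm.crop_coefficient,
                "use_efficiency": dm.use_efficiency,
                "system": dm.system,
            },
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        tl = d.get("thermal_light", {})
        dl = d.get("dilution", {})
        cv = d.get("conversion", {})
        dm = d.get("demand", {})
        return cls(
            thermal_light=ThermalLightParams(
                t_base=tl.get("t_base_c", 7.0),
                t_opt=tl.get("t_opt_c", 24.0),
                t_max=tl.get("t_max_c", 35.0),
                alpha=tl.get("alpha_per_mmol_m2_d", 0.001),
            ),
            dilution=DilutionParams(
                n_max_pct=dl.get("n_max_pct_dw", 6.83),
                plateau_fraction_c=dl.get("plateau_fraction_c", 0.7),
                plateau_fraction_min=dl.get("plateau_fraction_min", 0.4),
                exponent_b=dl.get("exponent_b", 0.33),
                dw_break=dl.get("dw_break_t_ha", 1.5),
                mode=dl.get("mode", "as_printed"),
            ),
            conversion=ConversionParams(
                fw_dw_ratio=cv.get("fw_dw_ratio", 25.64),
                plant_density=cv.get("plant_density_per_ha"),
            ),
            demand=DemandParams(
                crop_coefficient=dm.get("crop_coefficient", 0.39),
                use_efficiency=dm.get("use_efficiency", 0.38),
                system=dm.get("system", "substrate"),
            ),
            seed=int(d.get("seed", 0)),
        )


def load_config(path) -> PipelineConfig:
    """Load a YAML config file; missing keys take the pakchoi defaults."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: config must be a YAML mapping")
    return PipelineConfig.from_dict(raw)


def save_config(config: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
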