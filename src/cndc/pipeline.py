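"""End-to-end pipeline: weather -> LTF -> fits -> per-sample N diagnosis."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import demand as _dm
from . import dilution as _dil
from . import growth as _gr
from . import io as _io
from . import photothermal as _pt
from ._exceptions import FitError, SchemaError

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    """Everything one pipeline run produced."""

    ltf: pd.Series                      #: running LTF indexed by day (0-based)
    growth_fits: list[dict]             #: one record per (treatment, response)
    dilution_fit: dict | None           #: power-law fit, None if too few points
    demand_table: pd.DataFrame          #: per-sample N diagnosis

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "ltf": outdir / "ltf.csv",
            "growth_fits": outdir / "growth_fits.json",
            "dilution_fit": outdir / "dilution_fit.json",
            "demand": outdir / "demand.csv",
        }
        self.ltf.rename_axis("day").to_csv(paths["ltf"])
        _io.write_json_report(self.growth_fits, paths["growth_fits"])
        _io.write_json_report(self.dilution_fit, paths["dilution_fit"])
        self.demand_table.to_csv(paths["demand"], index=False, float_format="%.6g")
        return paths


def run_pipeline(
    config: _io.PipelineConfig,
    weather_csv: str | Path,
    samples_csv: str | Path,
) -> PipelineResult:
    """Run the full analysis on a weather series and a trial-sample table.

    The samples CSV must carry ``day``, ``n_rate``, ``fw``, ``dw`` (both
    g/plant) and ``n_pct`` — the dialect the synthetic generator writes.
    LTF at a sample's day is recomputed from the weather (day d uses
    days 1..d of the series); any ``ltf`` column in the file is ignored.
    """
    weather = _io.read_weather_csv(weather_csv)
    samples = pd.read_csv(samples_csv)
    required = {"day", "n_rate", "fw", "dw", "n_pct"}
    missing = required - set(samples.columns)
    if missing:
        raise SchemaError(f"{samples_csv}: missing column(s) {sorted(missing)}")

    effects = _pt.daily_effects(weather, config.thermal_light)
    ltf = _pt.ltf_series(effects)
    max_day = len(ltf)
    if samples["day"].max() > max_day:
        raise SchemaError(
            f"samples reach day {int(samples['day'].max())} but the weather "
            f"series covers only {max_day} complete day(s)"
        )
    samples = samples.assign(ltf=ltf.to_numpy()[samples["day"].astype(int) - 1])

    growth_fits: list[dict] = []
    for rate, sub in samples.groupby("n_rate"):
        uptake = 10.0 * sub["dw"] * sub["n_pct"]  # mg/plant
        for response, y in (("fw", sub["fw"]), ("dw", sub["dw"]), ("n_uptake", uptake)):
            try:
                res = _gr.ExponentialGrowth(
                    sub["ltf"].to_numpy(), y.to_numpy(), response
                ).fit()
            except FitError as exc:
                growth_fits.append(
                    {"treatment": float(rate), "response": response, "error": str(exc)}
                )
                continue
            growth_fits.append({"treatment": float(rate)} | res.to_dict())

    dw_area = _gr.per_plant_to_area(samples["dw"].to_numpy(), config.conversion)
    try:
        dil_res = _dil.DilutionCurveModel(
            dw_area, samples["n_pct"].to_numpy(), config.dilution.dw_break
        ).fit()
        dilution_fit = dil_res.to_dict()
    except FitError as exc:
        dilution_fit = None

    rows = []
    for (_, s), dwa in zip(samples.iterrows(), dw_area):
        rep = _dm.demand_report(
            fw=float(s["fw"]), dw_area=float(dwa), na_pct=float(s["n_pct"]),
            dil=config.dilution, params=config.demand,
        )
        rows.append(
            {
                "day": int(s["day"]),
                "n_rate": float(s["n_rate"]),
                "fw_g": float(s["fw"]),
                "dw_t_ha": float(dwa),
                "na_pct": rep.na_pct,
                "nc_pct": rep.nc_pct,
                "nni": rep.nni,
                "status": rep.status.label,
                "n_demand_mg": 1000.0 * rep.n_demand,
                "n_supply_mg": 1000.0 * rep.n_supply,
                "n_surplus_mg": 1000.0 * rep.surplus,
            }
        )
    return PipelineResult(
        ltf=ltf,
        growth_fits=growth_fits,
        dilution_fit=dilution_fit,
        demand_table=pd.DataFrame(rows),
    )
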