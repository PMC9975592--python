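"""Synthetic greenhouse weather and virtual destructive-sampling trials.

The source experiments' raw data are not deposited, so every stage of
the pipeline is exercised on simulated inputs that reproduce the
*structure* of those experiments — greenhouse regimes, N-rate
treatments, 5-7 day destructive sampling over a 42-45 day cycle — while
the trajectories themselves come from the package's own forward model:
rate parameters drawn from the published b(F) quadratics, exponential
growth in cumulative photothermal effect (LTF), and N content bounded
by the dilution envelope.

Two weather presets mirror the reported regimes: ``exp13``
(autumn/winter, daily mean 19 degC, range 13-23, mean daily PAR
5.3 mol m^-2) and ``exp2`` (warm winter greenhouse, mean 26.3 degC,
range 19-31, PAR 9.5 mol m^-2).

Everything is deterministic given a seed; noiseless trajectories do not
depend on the seed at all once the weather is fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import dilution as _dil
from . import growth as _gr
from . import photothermal as _pt

__all__ = [
    "WeatherRegime",
    "TrialDesign",
    "EXP13_REGIME",
    "EXP2_REGIME",
    "exp1_design",
    "exp2_design",
    "generate_weather",
    "trial_trajectories",
    "generate_trial",
    "make_fixture",
    "FIXTURES",
]

#: Default planting density (plants/ha) used when mapping per-plant dry
#: weight onto the areal axis of the dilution curve; chosen so a mature
#: ~2.6 g/plant crop sits at the 1.5 t/ha breakpoint.
DEFAULT_PLANT_DENSITY = 577_000.0

#: Fresh weight of the crop at the start of LTF accumulation, g/plant.
FW_INTERCEPT = 0.2816


@dataclass(frozen=True)
class WeatherRegime:
    """Statistical description of one greenhouse season.

    ``t_amplitude`` is the half-range of the diurnal temperature cycle;
    ``par_daily_mean``/``par_daily_sd`` describe the day-to-day
    distribution of the daily PAR integral (mol m^-2 d^-1), spread over
    ``daylight_hours`` as a half-sine centred on noon.
    """

    name: str
    t_mean: float
    t_amplitude: float
    par_daily_mean: float
    par_daily_sd: float
    daylight_hours: float = 11.0

    def __post_init__(self) -> None:
        if self.t_amplitude < 0 or self.par_daily_sd < 0:
            raise ValueError("amplitude and sd must be non-negative")
        if not (0 < self.daylight_hours <= 24):
            raise ValueError("daylight_hours must be in (0, 24]")


EXP13_REGIME = WeatherRegime(
    "exp13", t_mean=19.0, t_amplitude=5.0,
    par_daily_mean=5.3, par_daily_sd=1.5, daylight_hours=11.0,
)
EXP2_REGIME = WeatherRegime(
    "exp2", t_mean=26.3, t_amplitude=6.0,
    par_daily_mean=9.5, par_daily_sd=2.5, daylight_hours=10.0,
)


@dataclass(frozen=True)
class TrialDesign:
    """Layout of one virtual pot trial."""

    n_rates: tuple[float, ...] = (0.0, 0.05, 0.1, 0.2)  #: g N per kg substrate
    duration_days: int = 45
    sampling_days: tuple[int, ...] = (11, 18, 31, 38, 45)
    plants_per_sample: int = 9
    noise_cv: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if any(d < 1 or d > self.duration_days for d in self.sampling_days):
            raise ValueError("sampling_days must lie within the trial duration")
        if any(r < 0 for r in self.n_rates):
            raise ValueError("N rates must be non-negative")


def exp1_design(**overrides) -> TrialDesign:
    """Soil-culture layout: 4 rates, 45 days, sampling on days 11-45."""
    return replace(TrialDesign(), **overrides)


def exp2_design(**overrides) -> TrialDesign:
    """Substrate-culture layout: 42 days, weekly sampling, 12 plants."""
    base = TrialDesign(
        n_rates=(0.0, 0.089, 0.109, 0.127),
        duration_days=42,
        sampling_days=(7, 14, 21, 28, 35, 42),
        plants_per_sample=12,
    )
    return replace(base, **overrides)


def generate_weather(
    regime: WeatherRegime,
    days: int,
    seed: int = 0,
    start: str = "2017-01-01",
) -> pd.DataFrame:
    """Hourly synthetic weather for ``days`` complete calendar days.

    Temperature is a sinusoid with its minimum pre-dawn (~03:00) and
    maximum mid-afternoon (~15:00) plus small AR(1) noise; PAR is a
    half-sine over the daylight window scaled so the daily integral is
    a Normal(par_daily_mean, par_daily_sd) draw truncated at zero.

    Returns a frame with columns ``date``, ``hour``, ``temp_c``,
    ``par_mol_m2`` (the weather-CSV dialect).
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    rng = np.random.default_rng(seed)
    n = days * 24
    hours = np.tile(np.arange(24), days)
    dates = np.repeat(pd.date_range(start, periods=days, freq="D"), 24)

    diurnal = regime.t_mean + regime.t_amplitude * np.sin(2 * np.pi * (hours - 9) / 24)
    # AR(1) hour-to-hour wander, sd 0.5 degC, phi 0.7
    eps = rng.normal(0.0, 0.5, size=n)
    noise = np.empty(n)
    noise[0] = eps[0]
    for i in range(1, n):
        noise[i] = 0.7 * noise[i - 1] + eps[i]
    temp = diurnal + noise

    daily_total = rng.normal(regime.par_daily_mean, regime.par_daily_sd, size=days)
    daily_total = np.clip(daily_total, 0.0, None)
    half = regime.daylight_hours / 2.0
    # weight of each hour within the daylight half-sine, normalised to sum 1
    centred = hours - 12.0
    w = np.where(
        np.abs(centred) < half,
        np.cos(np.pi * centred / (2 * half)),
        0.0,
    )
    w = w.reshape(days, 24)
    w = w / w.sum(axis=1, keepdims=True)
    par = (w * daily_total[:, None]).reshape(n)

    return pd.DataFrame(
        {
            "date": pd.Series(dates).dt.strftime("%Y-%m-%d"),
            "hour": hours,
            "temp_c": temp,
            "par_mol_m2": par,
        }
    )


def _intercepts(dil: _dil.DilutionParams, conv: _gr.ConversionParams):
    """Trajectory intercepts derived from the FW intercept.

    Only the fresh-weight intercept is published; the dry-weight
    intercept follows from the FW/DW ratio and the N-uptake intercept
    (mg/plant) from the Nmax plateau that young plants sit on.
    """
    a_fw = FW_INTERCEPT
    a_dw = a_fw / conv.fw_dw_ratio
    a_n_mg = a_dw * dil.n_max_pct * 10.0  # g * (%/100) * 1000 mg/g
    return a_fw, a_dw, a_n_mg


def trial_trajectories(
    design: TrialDesign,
    regime: WeatherRegime = EXP13_REGIME,
    dil: _dil.DilutionParams = _dil.DilutionParams(),
    conv: _gr.ConversionParams | None = None,
    weather: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Noiseless daily model trajectories per N rate.

    Columns: ``n_rate``, ``day`` (1-based), ``ltf``, ``fw``, ``dw``
    (g/plant), ``n_uptake_mg``, ``n_pct`` (% of DW, clipped into the
    dilution envelope), ``rate_b_fw``/``_dw``/``_n`` (injected truth).
    """
    if conv is None:
        conv = _gr.ConversionParams(plant_density=DEFAULT_PLANT_DENSITY)
    if weather is None:
        weather = generate_weather(regime, design.duration_days, seed=design.seed)
    effects = _pt.daily_effects(weather)
    ltf = _pt.ltf_series(effects).to_numpy()  # ltf[d-1] = LTF through day d
    days = np.arange(1, design.duration_days + 1)
    a_fw, a_dw, a_n = _intercepts(dil, conv)

    frames = []
    for rate in design.n_rates:
        b_fw = _gr.b_response(rate, _gr.FW_QUADRATIC)
        b_dw = _gr.b_response(rate, _gr.DW_QUADRATIC)
        b_n = _gr.b_response(rate, _gr.N_UPTAKE_QUADRATIC)
        L = ltf[days - 1]
        fw = a_fw * np.exp(b_fw * L)
        dw = a_dw * np.exp(b_dw * L)
        uptake = a_n * np.exp(b_n * L)
        n_pct = uptake / (10.0 * dw)  # mg/plant over g/plant -> % of DW
        dw_area = _gr.per_plant_to_area(dw, conv)
        n_pct = np.clip(
            n_pct, _dil.n_min_curve(dw_area, dil), _dil.n_max_curve(dw_area, dil)
        )
        uptake = 10.0 * dw * n_pct  # keep uptake consistent after clipping
        frames.append(
            pd.DataFrame(
                {
                    "n_rate": rate,
                    "day": days,
                    "ltf": L,
                    "fw": fw,
                    "dw": dw,
                    "n_uptake_mg": uptake,
                    "n_pct": n_pct,
                    "rate_b_fw": b_fw,
                    "rate_b_dw": b_dw,
                    "rate_b_n": b_n,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def generate_trial(
    design: TrialDesign,
    regime: WeatherRegime = EXP13_REGIME,
    dil: _dil.DilutionParams = _dil.DilutionParams(),
    conv: _gr.ConversionParams | None = None,
    weather: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Simulate destructive samples from a virtual trial.

    At each sampling day and N rate, ``plants_per_sample`` distinct
    plants are drawn from the noiseless trajectory with independent
    multiplicative lognormal errors of coefficient of variation
    ``design.noise_cv`` on fresh weight, dry weight and N content
    (mean-one noise, so expectations stay on the model).

    Returns a frame with columns ``day``, ``n_rate``, ``plant``,
    ``ltf``, ``fw``, ``dw``, ``n_pct``.
    """
    traj = trial_trajectories(design, regime, dil, conv, weather)
    rng = np.random.default_rng(design.seed)
    cv = design.noise_cv
    sigma = float(np.sqrt(np.log1p(cv**2)))
    rows = []
    for rate in design.n_rates:
        sub = traj[traj["n_rate"] == rate].set_index("day")
        for day in design.sampling_days:
            base = sub.loc[day]
            for plant in range(design.plants_per_sample):
                if cv > 0:
                    f = np.exp(rng.normal(-sigma**2 / 2.0, sigma, size=3))
                else:
                    f = np.ones(3)
                rows.append(
                    {
                        "day": day,
                        "n_rate": rate,
                        "plant": plant,
                        "ltf": base["ltf"],
                        "fw": base["fw"] * f[0],
                        "dw": base["dw"] * f[1],
                        "n_pct": base["n_pct"] * f[2],
                    }
                )
    return pd.DataFrame(rows)


def _fixture_minimal(outdir: Path) -> list[Path]:
    design = TrialDesign(
        n_rates=(0.0, 0.1), duration_days=3, sampling_days=(2, 3),
        plants_per_sample=1, noise_cv=0.0, seed=1,
    )
    weather = generate_weather(EXP13_REGIME, 3, seed=1)
    samples = generate_trial(design, EXP13_REGIME, weather=weather)
    wpath, spath = outdir / "minimal_weather.csv", outdir / "minimal_samples.csv"
    weather.to_csv(wpath, index=False)
    samples.to_csv(spath, index=False)
    return [wpath, spath]


def _fixture_exp2_like(outdir: Path) -> list[Path]:
    design = exp2_design(seed=7)
    weather = generate_weather(EXP2_REGIME, design.duration_days, seed=7)
    samples = generate_trial(design, EXP2_REGIME, weather=weather)
    wpath, spath = outdir / "exp2_like_weather.csv", outdir / "exp2_like_samples.csv"
    weather.to_csv(wpath, index=False)
    samples.to_csv(spath, index=False)
    return [wpath, spath]


FIXTURES = {"minimal": _fixture_minimal, "exp2_like": _fixture_exp2_like}


def make_fixture(name: str, outdir: str | Path = ".") -> list[Path]:
    """Write the deterministic CSV fixture bundle ``name`` into ``outdir``."""
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(FIXTURES)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    return FIXTURES[name](outdir)
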