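import numpy as np
import pandas as pd
import pytest

from cndc.photothermal import ThermalLightParams


@pytest.fixture
def default_params() -> ThermalLightParams:
    return ThermalLightParams()


def constant_weather(days: int, temp_c: float, par_per_hour: float) -> pd.DataFrame:
    """Hourly weather frame with constant temperature and PAR."""
    hours = np.tile(np.arange(24), days)
    dates = np.repeat(pd.date_range("2020-03-01", periods=days, freq="D"), 24)
    return pd.DataFrame(
        {
            "date": pd.Series(dates).dt.strftime("%Y-%m-%d"),
            "hour": hours,
            "temp_c": temp_c,
            "par_mol_m2": par_per_hour,
        }
    )


@pytest.fixture
def constant_day():
    return constant_weather
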