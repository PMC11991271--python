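import numpy as np
import pandas as pd
import pytest

import brutia_flux as bf


@pytest.fixture(scope="session")
def all_plots():
    return bf.load_plots()


@pytest.fixture(scope="session")
def elevation_plots():
    return bf.load_plots(group="elevation")


@pytest.fixture(scope="session")
def postfire_plots():
    return bf.load_plots(group="postfire")


@pytest.fixture(scope="session")
def forcing_3y():
    """Three synthetic years (2001-2003, no leap year complications)."""
    return bf.synth_weather(bf.WeatherGenParams(seed=7), 3, start_year=2001)


@pytest.fixture(scope="session")
def forcing_12y():
    """Twelve synthetic years (1994-2005) for annual-scale checks."""
    return bf.synth_weather(bf.WeatherGenParams(seed=3), 12, start_year=1994)


def make_constant_forcing(
    n_days=730,
    start="2001-01-01",
    tmean=15.0,
    rh=60.0,
    precip=2.0,
    rad=15.0,
    co2=368.0,
):
    """A constant-weather forcing series for limit-case tests."""
    dates = pd.date_range(start, periods=n_days, freq="D")
    n = len(dates)
    return bf.ForcingSeries(
        pd.DataFrame(
            {
                "date": dates,
                "tmean": np.full(n, tmean),
                "tmin": np.full(n, tmean - 4.0),
                "tmax": np.full(n, tmean + 4.0),
                "rh": np.full(n, rh),
                "precip": np.full(n, precip),
                "rad": np.full(n, rad),
                "co2": np.full(n, co2),
            }
        )
    )
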