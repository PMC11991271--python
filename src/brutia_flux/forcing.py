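"""Daily meteorological and CO2 forcing.

Reads and validates daily weather series, applies the local elevation
lapse-rate correction, computes FAO-56 extraterrestrial radiation, provides
CO2 concentration trajectories for present-climate and RCP scenarios, and
synthesizes stochastic Mediterranean weather calibrated to the island
climate normals of the study region (mean annual temperature ~18.0 degC,
~645 mm annual precipitation concentrated in winter, summer drought).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "ForcingFormatError",
    "ForcingGapError",
    "ForcingSeries",
    "WeatherGenParams",
    "read_met_csv",
    "lapse_correct",
    "extraterrestrial_radiation",
    "synth_weather",
    "co2_trajectory",
]

#: Local lapse rate, degC per 100 m of elevation, fitted for the study area.
DEFAULT_LAPSE = 0.638

#: Solar constant, MJ m-2 min-1 (FAO-56).
SOLAR_CONSTANT = 0.0820

MET_COLUMNS = ("tmean", "tmin", "tmax", "rh", "precip", "rad", "co2")


class ForcingFormatError(ValueError):
    """A forcing file is missing a mandatory column or has malformed rows."""


class ForcingGapError(ValueError):
    """A forcing series has missing calendar days."""


class ForcingSeries:
    """A validated, contiguous daily weather + CO2 record.

    Wraps a :class:`pandas.DataFrame` with columns ``date`` (datetime64),
    ``tmean``, ``tmin``, ``tmax`` (degC), ``rh`` (%), ``precip`` (mm day-1),
    ``rad`` (shortwave, MJ m-2 day-1) and ``co2`` (ppm). Rows are sorted by
    date on construction; dates must then be strictly consecutive calendar
    days and every row must satisfy the physical invariants
    (tmin <= tmean <= tmax, 0 <= rh <= 100, precip >= 0, rad >= 0, co2 > 0).
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        missing = [c for c in ("date", *MET_COLUMNS) if c not in frame.columns]
        if missing:
            raise ForcingFormatError(f"missing mandatory column(s): {', '.join(missing)}")
        frame["date"] = pd.to_datetime(frame["date"])
        frame = frame.sort_values("date").reset_index(drop=True)
        deltas = frame["date"].diff().dt.days.iloc[1:]
        if (deltas == 0).any():
            dup = frame["date"].iloc[int(np.argmax(deltas.to_numpy() == 0)) + 1]
            raise ForcingFormatError(f"duplicate date {dup.date()}")
        if (deltas != 1).any():
            i = int(np.argmax(deltas.to_numpy() != 1))
            raise ForcingGapError(
                "non-contiguous dates: first gap after "
                f"{frame['date'].iloc[i].date()} (next row {frame['date'].iloc[i + 1].date()})"
            )
        self._validate_rows(frame)
        self.frame = frame

    @staticmethod
    def _validate_rows(frame: pd.DataFrame) -> None:
        bad = ~(
            (frame["tmin"] <= frame["tmean"])
            & (frame["tmean"] <= frame["tmax"])
            & frame["rh"].between(0.0, 100.0)
            & (frame["precip"] >= 0.0)
            & (frame["rad"] >= 0.0)
            & (frame["co2"] > 0.0)
        )
        if bad.any():
            first = frame.loc[bad, "date"].iloc[0]
            raise ForcingFormatError(f"physically invalid forcing row on {first.date()}")

    def __len__(self) -> int:
        return len(self.frame)

    def __getattr__(self, name: str) -> np.ndarray:
        if name in MET_COLUMNS:
            return self.frame[name].to_numpy(dtype=float)
        raise AttributeError(name)

    @property
    def date(self) -> pd.Series:
        return self.frame["date"]

    @property
    def doy(self) -> np.ndarray:
        return self.frame["date"].dt.dayofyear.to_numpy()

    @property
    def year(self) -> np.ndarray:
        return self.frame["date"].dt.year.to_numpy()

    def slice_years(self, start_year: int, end_year: int) -> "ForcingSeries":
        """Return the sub-series covering calendar years [start, end]."""
        mask = (self.year >= start_year) & (self.year <= end_year)
        if not mask.any():
            raise ValueError(f"series does not cover {start_year}-{end_year}")
        return ForcingSeries(self.frame.loc[mask])

    def perturb(
        self,
        dt: float = 0.0,
        precip_factor: float = 1.0,
        co2_delta: float = 0.0,
    ) -> "ForcingSeries":
        """A uniformly shifted copy: +dt degC on all temperatures, precip
        scaled by ``precip_factor``, CO2 shifted by ``co2_delta`` ppm.

        Convenience for building synthetic climate-change sensitivity
        forcings from a baseline series.
        """
        if precip_factor < 0:
            raise ValueError("precip_factor must be >= 0")
        out = self.frame.copy()
        for col in ("tmean", "tmin", "tmax"):
            out[col] += dt
        out["precip"] *= precip_factor
        out["co2"] += co2_delta
        return ForcingSeries(out)

    def with_co2_scenario(self, scenario: str) -> "ForcingSeries":
        """Replace the CO2 column with the named scenario trajectory."""
        out = self.frame.copy()
        out["co2"] = co2_trajectory(scenario, self.year)
        return ForcingSeries(out)

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out["date"] = out["date"].dt.strftime("%Y-%m-%d")
        out.to_csv(path, index=False)


def read_met_csv(path, dialect: dict[str, str] | None = None) -> ForcingSeries:
    """Read a daily forcing CSV into a validated :class:`ForcingSeries`.

    Parameters
    ----------
    path:
        CSV with a header and one row per day. Canonical columns are
        ``date,tmean,tmin,tmax,rh,precip,rad,co2`` (ISO-8601 dates).
    dialect:
        Optional mapping from canonical column names to the names used in
        the file, e.g. ``{"tmean": "TAVG"}``.

    Rows out of order are tolerated (the series is date-sorted before the
    contiguity check); missing days raise :class:`ForcingGapError`.
    """
    frame = pd.read_csv(path, comment="#")
    if dialect:
        rename = {src: canon for canon, src in dialect.items()}
        frame = frame.rename(columns=rename)
    return ForcingSeries(frame)


def lapse_correct(t_source, z_offset, lapse: float = DEFAULT_LAPSE):
    """Correct temperature for an elevation offset with the local lapse rate.

    ``t_source - lapse * z_offset / 100`` where ``z_offset`` (m) is the
    target-site elevation minus the elevation of the forcing source. The
    default coefficient is the locally fitted 0.638 degC per 100 m.
    """
    return np.asarray(t_source, dtype=float) - lapse * np.asarray(z_offset, dtype=float) / 100.0


def extraterrestrial_radiation(latitude: float, doy) -> np.ndarray | float:
    """Daily extraterrestrial radiation R_ex (MJ m-2 day-1), FAO-56 eq. 21.

    Uses the solar constant 0.0820 MJ m-2 min-1, inverse relative
    Earth-Sun distance, solar declination and sunset hour angle. Valid for
    non-polar latitudes (|lat| < 66 degrees).
    """
    if not -66.0 < latitude < 66.0:
        raise ValueError(f"latitude {latitude} outside the non-polar domain (-66, 66)")
    doy_arr = np.asarray(doy, dtype=float)
    if np.any((doy_arr < 1) | (doy_arr > 366)):
        raise ValueError("day of year must be in [1, 366]")
    phi = np.deg2rad(latitude)
    dr = 1.0 + 0.033 * np.cos(2.0 * np.pi * doy_arr / 365.0)
    delta = 0.409 * np.sin(2.0 * np.pi * doy_arr / 365.0 - 1.39)
    ws = np.arccos(np.clip(-np.tan(phi) * np.tan(delta), -1.0, 1.0))
    ra = (
        24.0 * 60.0 / np.pi
        * SOLAR_CONSTANT
        * dr
        * (ws * np.sin(phi) * np.sin(delta) + np.cos(phi) * np.cos(delta) * np.sin(ws))
    )
    ra = np.maximum(ra, 0.0)
    return float(ra) if np.isscalar(doy) else ra


@lru_cache(maxsize=1)
def _co2_table() -> pd.DataFrame:
    with resources.files("brutia_flux.data").joinpath("co2_scenarios.csv").open() as fh:
        return pd.read_csv(fh, comment="#")


def co2_trajectory(scenario: str, year) -> np.ndarray | float:
    """CO2 concentration (ppm) for a scenario and calendar year(s).

    Scenarios: ``baseline`` (fixed late-1990s concentration), ``rcp45``,
    ``rcp85``. Values are linearly interpolated between the decadal entries
    of the shipped concentration table (1970-2100).
    """
    table = _co2_table()
    key = scenario.lower()
    if key not in table.columns[1:]:
        valid = ", ".join(table.columns[1:])
        raise ValueError(f"unknown scenario {scenario!r}; valid scenarios: {valid}")
    years = np.asarray(year, dtype=float)
    if np.any((years < 1970) | (years > 2100)):
        raise ValueError("year must be within 1970-2100")
    out = np.interp(years, table["year"], table[key])
    return float(out) if np.isscalar(year) else out


# ---------------------------------------------------------------------------
# Stochastic weather generator
# ---------------------------------------------------------------------------

_DAYS_IN_MONTH = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])


@dataclass
class WeatherGenParams:
    """Parameters of the stochastic Mediterranean weather generator.

    Defaults are calibrated to the long-term normals of the study island:
    mean annual temperature 18.0 degC (January coolest, peak in mid-July),
    645 mm annual precipitation falling mostly from November to March, and
    a pronounced April-October drought. Temperature is an annual sinusoid
    plus AR(1) daily noise; precipitation occurrence follows a monthly
    two-state Markov chain with gamma-distributed wet-day amounts;
    radiation is extraterrestrial radiation scaled by a stochastic
    transmissivity that is lower on wet days.
    """

    mean_annual_t: float = 18.0
    seasonal_amplitude: float = 8.2
    peak_doy: int = 197
    ar1_rho: float = 0.7
    ar1_sd: float = 1.5
    diurnal_range: float = 9.5
    latitude: float = 39.09
    monthly_precip_mm: tuple = (120, 98, 72, 43, 22, 6, 2, 3, 12, 40, 92, 135)
    monthly_wet_days: tuple = (12, 10, 9, 7, 4, 1.5, 0.5, 0.7, 2, 5, 9, 13)
    wet_persistence: float = 0.3
    gamma_shape: float = 0.75
    monthly_rh: tuple = (75, 73, 70, 65, 60, 52, 48, 50, 57, 66, 72, 76)
    rh_sd: float = 8.0
    tau_clear: float = 0.68
    tau_wet: float = 0.35
    tau_sd: float = 0.08
    co2: float = 368.0
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.monthly_precip_mm) <= 0:
            raise ValueError("annual precipitation must be positive")
        pi = np.asarray(self.monthly_wet_days) / _DAYS_IN_MONTH
        if np.any((pi < 0) | (pi > 1)):
            raise ValueError("monthly wet-day counts imply probabilities outside [0, 1]")
        if not 0.0 <= self.wet_persistence < 1.0:
            raise ValueError("wet_persistence must be in [0, 1)")

    @property
    def wet_prob(self) -> np.ndarray:
        """Stationary monthly wet-day probability."""
        return np.asarray(self.monthly_wet_days, dtype=float) / _DAYS_IN_MONTH


def synth_weather(
    params: WeatherGenParams | None = None,
    n_years: int = 1,
    start_year: int = 2000,
) -> ForcingSeries:
    """Generate ``n_years`` calendar years of synthetic daily forcing.

    Reproducible for a fixed ``params.seed``; long-run annual means of
    temperature and precipitation converge to the generator normals.
    """
    params = params or WeatherGenParams()
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    rng = np.random.default_rng(params.seed)
    dates = pd.date_range(
        f"{start_year}-01-01", f"{start_year + n_years - 1}-12-31", freq="D"
    )
    n = len(dates)
    doy = dates.dayofyear.to_numpy()
    month = dates.month.to_numpy() - 1

    # temperature: sinusoid peaking at peak_doy + stationary AR(1) noise
    seasonal = params.mean_annual_t + params.seasonal_amplitude * np.cos(
        2.0 * np.pi * (doy - params.peak_doy) / 365.25
    )
    eps = np.empty(n)
    innov = rng.standard_normal(n) * params.ar1_sd * np.sqrt(1.0 - params.ar1_rho**2)
    eps[0] = rng.standard_normal() * params.ar1_sd
    for i in range(1, n):
        eps[i] = params.ar1_rho * eps[i - 1] + innov[i]
    tmean = seasonal + eps
    half_range = 0.5 * params.diurnal_range
    tmin = tmean - half_range
    tmax = tmean + half_range

    # precipitation: monthly two-state Markov occurrence + gamma amounts
    pi = params.wet_prob
    r = params.wet_persistence
    p_wet_after_wet = pi + r * (1.0 - pi)
    p_wet_after_dry = pi * (1.0 - r)
    u = rng.random(n)
    wet = np.empty(n, dtype=bool)
    wet[0] = u[0] < pi[month[0]]
    for i in range(1, n):
        p = p_wet_after_wet[month[i]] if wet[i - 1] else p_wet_after_dry[month[i]]
        wet[i] = u[i] < p
    mean_amount = np.where(
        pi > 0,
        np.asarray(params.monthly_precip_mm, dtype=float)
        / np.maximum(pi * _DAYS_IN_MONTH, 1e-12),
        0.0,
    )
    scale = mean_amount[month] / params.gamma_shape
    amounts = rng.gamma(params.gamma_shape, 1.0, size=n) * scale
    precip = np.where(wet, amounts, 0.0)

    # relative humidity: monthly normals + noise, moister on wet days
    rh = np.asarray(params.monthly_rh, dtype=float)[month] + rng.normal(0, params.rh_sd, n)
    rh = np.clip(rh + np.where(wet, 10.0, 0.0), 15.0, 100.0)

    # shortwave radiation: extraterrestrial x stochastic transmissivity
    rex = extraterrestrial_radiation(params.latitude, doy)
    tau = np.where(wet, params.tau_wet, params.tau_clear) + rng.normal(0, params.tau_sd, n)
    rad = rex * np.clip(tau, 0.10, 0.78)

    return ForcingSeries(
        pd.DataFrame(
            {
                "date": dates,
                "tmean": tmean,
                "tmin": tmin,
                "tmax": tmax,
                "rh": rh,
                "precip": precip,
                "rad": rad,
                "co2": np.full(n, params.co2),
            }
        )
    )
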