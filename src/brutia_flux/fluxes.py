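"""Daily stand-level carbon fluxes.

GPP follows the optimality-based light-use-efficiency model (P-model v1.0
lineage): a temperature-dependent intrinsic quantum yield, Beer-Lambert
canopy light absorption, a soil-moisture multiplier (relative extractable
water), and a CO2 limitation factor built from the least-cost optimal
ci:ca ratio with a Jmax-limitation correction. NPP is a fixed affine
allocation of GPP; soil heterotrophic respiration is an empirical
log-linear function of soil temperature, soil moisture and leaf area
index; NEP is their difference. ``simulate_plot`` orchestrates the daily
loop for one stand over a forcing series, including the soil-water bucket
and elevation lapse-rate correction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from . import forcing as fc
from . import soilwater as sw

__all__ = [
    "PhotosynParams",
    "PlotSpec",
    "RHET_COEFFS",
    "phi0",
    "i_abs",
    "m_prime",
    "gpp_daily",
    "npp_from_gpp",
    "soil_t_from_air",
    "fit_ts_model",
    "default_ts_model",
    "rhet_umol",
    "rhet_daily",
    "nep_daily",
    "vpd_from_t_rh",
    "load_plots",
    "simulate_plot",
]

# -- physical constants -----------------------------------------------------
R_GAS = 8.3145          # J mol-1 K-1
KPO = 101325.0          # standard pressure, Pa
KTO = 25.0              # reference temperature, degC
GS25 = 4.332            # photorespiratory compensation point at 25 degC, Pa
DHA_GS = 37830.0        # activation energy for gammastar, J mol-1
KC25, DHA_KC = 39.97, 79430.0    # Michaelis constant for CO2 at 25 degC (Pa)
KO25, DHA_KO = 27480.0, 36380.0  # Michaelis constant for O2 at 25 degC (Pa)
O2_FRAC = 0.209476      # mole fraction of O2 in dry air
MC = 12.011             # molar mass of carbon, g mol-1

#: micromol CO2 m-2 s-1 -> g C m-2 day-1
UMOL_S_TO_GC_DAY = 86400.0 * MC * 1e-6

#: Fitted coefficients of the empirical heterotrophic respiration equation
#: (natural-log micromol CO2 m-2 s-1 scale): intercept, soil temperature and
#: its square, volumetric moisture and its square, log leaf area index.
RHET_COEFFS = {
    "intercept": -4.31,
    "ts": 0.25,
    "ts2": -0.004,
    "theta": 5.36,
    "theta2": -6.37,
    "loglai": 0.69,
}

#: NPP allocation: NPP = 0.53 GPP + 66.05/365 (g C m-2 day-1); the slope is
#: one minus the autotrophic-respiration fraction of GPP, the constant is an
#: annual term expressed per day.
NPP_SLOPE = 0.53
NPP_INTERCEPT_ANNUAL = 66.05


@dataclass(frozen=True)
class PhotosynParams:
    """Tunables of the light-use-efficiency GPP model.

    ``phi0_ref`` scales the quantum-yield temperature polynomial
    ``phi0_poly`` (the standard quadratic peaking near 32 degC);
    ``k_ext`` is the Beer-Lambert canopy extinction coefficient;
    ``beta`` the unit-cost ratio of carboxylation to transpiration
    capacity in the optimal-chi criterion; ``c_star`` the Jmax-limitation
    constant; ``par_fraction`` the PAR share of shortwave radiation and
    ``photons_per_mj`` the photon conversion (mol MJ_PAR-1).
    """

    phi0_ref: float = 0.081785
    phi0_poly: tuple = (0.352, 0.022, -3.4e-4)
    k_ext: float = 0.5
    beta: float = 146.0
    c_star: float = 0.41
    par_fraction: float = 0.50
    photons_per_mj: float = 4.57
    mc: float = MC

    def __post_init__(self) -> None:
        if not 0.0 < self.par_fraction < 1.0:
            raise ValueError("par_fraction must be in (0, 1)")
        for name in ("phi0_ref", "k_ext", "beta", "c_star", "photons_per_mj", "mc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


DEFAULT_PHOTOSYN = PhotosynParams()


# -- P-model internals ------------------------------------------------------

def patm_from_elevation(z) -> np.ndarray | float:
    """Atmospheric pressure (Pa) from elevation via the barometric formula."""
    out = KPO * (1.0 - 0.0065 * np.asarray(z, dtype=float) / 288.15) ** 5.2553
    return float(out) if out.ndim == 0 else out


def _arrhenius(k25: float, dha: float, t_c) -> np.ndarray:
    tk = np.asarray(t_c, dtype=float) + 273.15
    return k25 * np.exp(dha / R_GAS * (1.0 / 298.15 - 1.0 / tk))


def gammastar(t_c, patm) -> np.ndarray:
    """Photorespiratory CO2 compensation point (Pa)."""
    return _arrhenius(GS25, DHA_GS, t_c) * np.asarray(patm) / KPO


def kmm(t_c, patm) -> np.ndarray:
    """Effective Michaelis-Menten coefficient for Rubisco (Pa)."""
    kc = _arrhenius(KC25, DHA_KC, t_c)
    ko = _arrhenius(KO25, DHA_KO, t_c)
    return kc * (1.0 + O2_FRAC * np.asarray(patm) / ko)


def viscosity_ratio(t_c) -> np.ndarray:
    """Viscosity of water at t_c relative to 25 degC (Korson et al. 1969
    temperature dependence; the pressure dependence is negligible here)."""
    t = np.asarray(t_c, dtype=float)

    def log10_rel20(temp):
        d = 20.0 - temp
        return d / (temp + 96.0) * (1.2364 - 1.37e-3 * d + 5.7e-6 * d * d)

    return 10.0 ** (log10_rel20(t) - log10_rel20(np.asarray(25.0)))


def phi0(t_mean, params: PhotosynParams = DEFAULT_PHOTOSYN):
    """Temperature-dependent intrinsic quantum yield (mol CO2 / mol photons):
    the reference yield times a quadratic in temperature, clamped at zero
    outside the quadratic's roots."""
    c0, c1, c2 = params.phi0_poly
    t = np.asarray(t_mean, dtype=float)
    out = params.phi0_ref * np.maximum(c0 + c1 * t + c2 * t * t, 0.0)
    return float(out) if out.ndim == 0 else out


def i_abs(sw_rad, lai, params: PhotosynParams = DEFAULT_PHOTOSYN):
    """Canopy-absorbed photosynthetic photon flux (mol photons m-2 day-1):
    shortwave x PAR fraction x photon conversion x (1 - exp(-k LAI))."""
    sw_rad = np.asarray(sw_rad, dtype=float)
    lai = np.asarray(lai, dtype=float)
    if np.any(sw_rad < 0) or np.any(lai < 0):
        raise ValueError("sw_rad and lai must be >= 0")
    ppfd = sw_rad * params.par_fraction * params.photons_per_mj
    out = ppfd * (1.0 - np.exp(-params.k_ext * lai))
    return float(out) if out.ndim == 0 else out


def optimal_chi(t_c, co2_ppm, vpd_kpa, elevation=0.0,
                params: PhotosynParams = DEFAULT_PHOTOSYN):
    """Least-cost optimal ci:ca ratio chi.

    chi = gammastar/ca + (1 - gammastar/ca) * xi / (xi + sqrt(D)) with
    xi = sqrt(beta (K + gammastar) / (1.6 eta*)); D is the vapour pressure
    deficit in Pa. This is the closed-form minimiser of the combined
    transpiration + carboxylation maintenance cost per unit assimilation.
    """
    co2_ppm = np.asarray(co2_ppm, dtype=float)
    vpd = np.asarray(vpd_kpa, dtype=float) * 1000.0
    if np.any(co2_ppm <= 0):
        raise ValueError("co2 must be positive (ppm)")
    if np.any(vpd < 0):
        raise ValueError("vpd must be >= 0")
    patm = patm_from_elevation(elevation)
    ca = co2_ppm * 1e-6 * patm
    gs = gammastar(t_c, patm)
    k = kmm(t_c, patm)
    ns = viscosity_ratio(t_c)
    xi = np.sqrt(params.beta * (k + gs) / (1.6 * ns))
    chi = gs / ca + (1.0 - gs / ca) * xi / (xi + np.sqrt(np.maximum(vpd, 1e-12)))
    return chi, ca, gs


def m_prime(t_mean, co2, vpd, elevation=0.0,
            params: PhotosynParams = DEFAULT_PHOTOSYN):
    """CO2 limitation factor for light-limited assimilation, in (0, 1].

    m = (ci - gammastar) / (ci + 2 gammastar) at the optimal ci, then the
    Jmax-limitation correction m' = m sqrt(1 - (c*/m)^(2/3)), clamped at 0
    when m <= c*.
    """
    chi, ca, gs = optimal_chi(t_mean, co2, vpd, elevation, params)
    ci = chi * ca
    m = (ci - gs) / (ci + 2.0 * gs)
    ratio = np.clip(params.c_star / np.maximum(m, 1e-12), 0.0, None)
    inner = 1.0 - ratio ** (2.0 / 3.0)
    out = np.where(inner > 0.0, m * np.sqrt(np.maximum(inner, 0.0)), 0.0)
    return float(out) if out.ndim == 0 else out


def vpd_from_t_rh(t_mean, rh_mean):
    """Vapour pressure deficit (kPa) from mean temperature and relative
    humidity via the Magnus saturation-vapour-pressure formula."""
    t = np.asarray(t_mean, dtype=float)
    rh = np.asarray(rh_mean, dtype=float)
    es = 0.6108 * np.exp(17.27 * t / (t + 237.3))
    out = np.maximum(es * (1.0 - rh / 100.0), 0.0)
    return float(out) if out.ndim == 0 else out


# -- daily fluxes -----------------------------------------------------------

def gpp_daily(phi0_v, iabs_v, rew_v, mprime_v, params: PhotosynParams = DEFAULT_PHOTOSYN):
    """Daily GPP (g C m-2 day-1): phi0 . I_abs . REW . m' . Mc."""
    out = (
        np.asarray(phi0_v, dtype=float)
        * np.asarray(iabs_v, dtype=float)
        * np.asarray(rew_v, dtype=float)
        * np.asarray(mprime_v, dtype=float)
        * params.mc
    )
    return float(out) if out.ndim == 0 else out


def npp_from_gpp(gpp):
    """Daily NPP (g C m-2 day-1) as a fixed allocation of GPP:
    0.53 GPP + 66.05/365."""
    out = NPP_SLOPE * np.asarray(gpp, dtype=float) + NPP_INTERCEPT_ANNUAL / 365.0
    return float(out) if out.ndim == 0 else out


def soil_t_from_air(t_mean, ts_model: tuple[float, float]):
    """Soil temperature (degC) from air temperature via a linear model
    (intercept, slope)."""
    intercept, slope = ts_model
    out = intercept + slope * np.asarray(t_mean, dtype=float)
    return float(out) if out.ndim == 0 else out


def fit_ts_model(t_air, t_soil) -> tuple[float, float]:
    """Least-squares (intercept, slope) of soil on air temperature."""
    t_air = np.asarray(t_air, dtype=float)
    t_soil = np.asarray(t_soil, dtype=float)
    slope, intercept = np.polyfit(t_air, t_soil, 1)
    return float(intercept), float(slope)


@lru_cache(maxsize=1)
def default_ts_model() -> tuple[float, float]:
    """Air-to-soil temperature model fitted on the annual-mean (air, soil)
    temperature pairs of the monitored plots that carried soil sensors."""
    raw = _plots_yaml()
    pairs = [(p["t_a"], p["ts_a"]) for p in raw["plots"] if "ts_a" in p]
    t_air, t_soil = zip(*pairs)
    return fit_ts_model(t_air, t_soil)


def rhet_umol(ts, theta, lai, coeffs: dict | None = None):
    """Heterotrophic soil respiration (micromol CO2 m-2 s-1):
    exp(b0 + b1 Ts + b2 Ts^2 + b3 theta + b4 theta^2 + b5 ln LAI)."""
    c = coeffs or RHET_COEFFS
    ts = np.asarray(ts, dtype=float)
    theta = np.asarray(theta, dtype=float)
    lai = np.asarray(lai, dtype=float)
    if np.any(lai <= 0):
        raise ValueError("lai must be positive")
    if np.any(theta < 0):
        raise ValueError("theta must be >= 0")
    expo = (
        c["intercept"]
        + c["ts"] * ts
        + c["ts2"] * ts * ts
        + c["theta"] * theta
        + c["theta2"] * theta * theta
        + c["loglai"] * np.log(lai)
    )
    out = np.exp(expo)
    return float(out) if out.ndim == 0 else out


def rhet_daily(ts, theta, lai, coeffs: dict | None = None):
    """Daily heterotrophic respiration (g C m-2 day-1): the instantaneous
    micromol flux scaled by 86400 s day-1 and the molar mass of carbon."""
    out = np.asarray(rhet_umol(ts, theta, lai, coeffs)) * UMOL_S_TO_GC_DAY
    return float(out) if out.ndim == 0 else out


def nep_daily(npp, rhet):
    """Daily NEP (g C m-2 day-1): NPP - Rhet (negative = carbon source)."""
    out = np.asarray(npp, dtype=float) - np.asarray(rhet, dtype=float)
    return float(out) if out.ndim == 0 else out


# -- plots and orchestration ------------------------------------------------

@dataclass(frozen=True)
class PlotSpec:
    """Static descriptor of one stand: location, structure (constant LAI),
    soil column, and the air-to-soil temperature model."""

    plot_id: str
    latitude: float
    elevation: float
    lai: float
    stand_age: float
    soil: sw.SoilColumn
    ts_model: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.lai <= 0:
            raise ValueError("lai must be positive")
        if not 0.0 < self.elevation < 3000.0:
            raise ValueError("elevation must be in (0, 3000) m")

    @property
    def ts_coeffs(self) -> tuple[float, float]:
        return self.ts_model if self.ts_model is not None else default_ts_model()

    def with_lai(self, lai: float) -> "PlotSpec":
        return replace(self, lai=lai)

    def with_elevation(self, elevation: float) -> "PlotSpec":
        return replace(self, elevation=elevation)


@lru_cache(maxsize=4)
def _plots_yaml(path: str | None = None) -> dict:
    if path is None:
        with resources.files("brutia_flux.data").joinpath("plots_lesvos.yaml").open() as fh:
            return yaml.safe_load(fh)
    with open(path) as fh:
        return yaml.safe_load(fh)


def load_plots(
    path: str | None = None,
    group: str | None = None,
    hydraulics: sw.SpeciesHydraulics | None = None,
) -> list[PlotSpec]:
    """Load plot specifications from a YAML fixture (the shipped nine
    monitoring plots by default). ``group`` filters on the fixture's
    ``group`` field (``postfire`` or ``elevation``)."""
    raw = _plots_yaml(path)
    plots = []
    for entry in raw["plots"]:
        if group is not None and entry.get("group") != group:
            continue
        soil_cfg = entry["soil"]
        texture = sw.texture_params(soil_cfg["texture"])
        if "rho_soil" in soil_cfg:
            texture = sw.SoilTextureParams(
                **{**texture.__dict__, "rho_soil": soil_cfg["rho_soil"]}
            )
        column = sw.SoilColumn.from_texture(soil_cfg["depth_mm"], texture, hydraulics)
        plots.append(
            PlotSpec(
                plot_id=entry["id"],
                latitude=entry["latitude"],
                elevation=entry["elevation"],
                lai=entry["lai"],
                stand_age=entry["stand_age"],
                soil=column,
            )
        )
    if not plots:
        raise ValueError("no plots matched the requested group")
    return plots


def simulate_plot(
    plot: PlotSpec,
    forcing: fc.ForcingSeries,
    params: PhotosynParams = DEFAULT_PHOTOSYN,
    hydraulics: sw.SpeciesHydraulics | None = None,
    spin_up_days: int = 365,
    forcing_elevation: float = 0.0,
    lapse: float = fc.DEFAULT_LAPSE,
) -> pd.DataFrame:
    """Simulate daily carbon fluxes for one stand over a forcing series.

    Per day: lapse-correct the forcing temperatures to the plot elevation,
    compute PET and step the soil-water bucket (previous-day REW-limited
    PET draw), then GPP from quantum yield, absorbed light, same-day REW
    and the CO2 limitation factor; NPP by fixed allocation; soil
    temperature from air; heterotrophic respiration from (Ts, theta, LAI);
    NEP = NPP - Rhet. The first ``spin_up_days`` days initialise the
    bucket and are discarded. LAI is constant throughout (no demography).

    Returns a DataFrame with columns
    ``date, gpp, npp, rhet, nep, pet, theta, rew, ts``.
    """
    n = len(forcing)
    if n < spin_up_days + 365:
        raise ValueError(
            f"forcing has {n} days; need at least spin-up ({spin_up_days}) + one year"
        )
    z_offset = plot.elevation - forcing_elevation
    t_mean = fc.lapse_correct(forcing.tmean, z_offset, lapse)

    rex = fc.extraterrestrial_radiation(plot.latitude, forcing.doy)
    pet = sw.pet_daily(rex, t_mean)
    bucket = sw.run_bucket(plot.soil, forcing.precip, pet)
    theta = bucket["theta"].to_numpy()
    rew_v = bucket["rew"].to_numpy()

    vpd = vpd_from_t_rh(t_mean, forcing.rh)
    gpp = gpp_daily(
        phi0(t_mean, params),
        i_abs(forcing.rad, plot.lai, params),
        rew_v,
        m_prime(t_mean, forcing.co2, vpd, plot.elevation, params),
        params,
    )
    npp = npp_from_gpp(gpp)
    ts = soil_t_from_air(t_mean, plot.ts_coeffs)
    rhet = rhet_daily(ts, theta, plot.lai)
    nep = nep_daily(npp, rhet)

    out = pd.DataFrame(
        {
            "date": forcing.date,
            "gpp": gpp,
            "npp": npp,
            "rhet": rhet,
            "nep": nep,
            "pet": pet,
            "theta": theta,
            "rew": rew_v,
            "ts": ts,
        }
    )
    return out.iloc[spin_up_days:].reset_index(drop=True)
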