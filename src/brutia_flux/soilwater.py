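"""Daily soil-water bucket.

A single-layer store of plant-available water per unit ground area,
bounded between a residual amount and field capacity. Moisture is
interconverted with volumetric water content through the soil column
geometry, with soil water potential through the Campbell power-law
retention curve, and normalised to relative extractable water (REW)
between field capacity and the soil moisture at the species' minimum
water potential. Atmospheric demand is an empirical radiation-temperature
potential-evapotranspiration equation fitted for Greece, and the daily
draw on the bucket is REW-limited PET.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "SoilTextureParams",
    "SoilColumn",
    "SoilState",
    "SpeciesHydraulics",
    "texture_params",
    "texture_classes",
    "pet_daily",
    "aw_from_theta",
    "theta_from_aw",
    "psi_from_theta",
    "theta_from_psi",
    "theta_sp_min",
    "rew",
    "step_water_balance",
    "initial_state",
    "run_bucket",
]

#: Density of water, g cm-3.
RHO_W = 1.0

#: Cap on mean temperature in the PET equation, degC. The empirical PET
#: formula has a pole near 42.7 degC; capping keeps it finite under extreme
#: synthetic forcing without touching any realistic regime in the study area.
PET_T_CAP = 40.0


@dataclass(frozen=True)
class SoilTextureParams:
    """Campbell retention and bucket parameters for one texture class.

    theta_* are volumetric water contents (m3 m-3): saturation, residual
    and field capacity. ``psi_e`` is the air-entry potential magnitude
    (MPa), ``b`` the dimensionless Campbell exponent, ``rho_soil`` the bulk
    density (g cm-3).
    """

    theta_s: float
    theta_r: float
    theta_fc: float
    psi_e: float
    b: float
    rho_soil: float

    def __post_init__(self) -> None:
        if not 0.0 < self.theta_r < self.theta_fc < self.theta_s < 1.0:
            raise ValueError("require 0 < theta_r < theta_fc < theta_s < 1")
        if self.psi_e <= 0 or self.b <= 0 or self.rho_soil <= 0:
            raise ValueError("psi_e, b and rho_soil must be positive")


@dataclass(frozen=True)
class SpeciesHydraulics:
    """Species water-extraction limit: minimum water potential magnitude
    (MPa, positive; negated internally). Default 3.3 MPa for the study pine."""

    psi_min: float = 3.3

    def __post_init__(self) -> None:
        if self.psi_min <= 0:
            raise ValueError("psi_min must be a positive magnitude")


@dataclass(frozen=True)
class SoilColumn:
    """A plot's soil column: depth (mm), texture, and the derived bucket
    bounds AW_r / AW_fc (mm) and theta_sp_min (m3 m-3), kept mutually
    consistent with the moisture conversions."""

    depth: float
    texture: SoilTextureParams
    aw_r: float
    aw_fc: float
    theta_sp_min: float

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive (mm)")
        if not 0.0 <= self.aw_r < self.aw_fc:
            raise ValueError("require 0 <= aw_r < aw_fc")
        if not self.texture.theta_r <= self.theta_sp_min < self.texture.theta_fc:
            raise ValueError("require theta_r <= theta_sp_min < theta_fc")

    @classmethod
    def from_texture(
        cls,
        depth_mm: float,
        texture: SoilTextureParams,
        hydraulics: SpeciesHydraulics | None = None,
    ) -> "SoilColumn":
        """Build a column whose bucket bounds are the residual and
        field-capacity moistures converted over the column depth."""
        hyd = hydraulics or SpeciesHydraulics()
        t_spmin = theta_sp_min(texture, hyd)
        return cls(
            depth=depth_mm,
            texture=texture,
            aw_r=texture.theta_r * texture.rho_soil * depth_mm / RHO_W,
            aw_fc=texture.theta_fc * texture.rho_soil * depth_mm / RHO_W,
            theta_sp_min=t_spmin,
        )


@dataclass(frozen=True)
class SoilState:
    """One day's bucket state: available water AW (mm), volumetric content
    theta (m3 m-3), relative extractable water REW in [0, 1], and water
    potential psi (MPa, <= 0)."""

    aw: float
    theta: float
    rew: float
    psi: float


@lru_cache(maxsize=1)
def _texture_table() -> pd.DataFrame:
    with resources.files("brutia_flux.data").joinpath("texture_classes.csv").open() as fh:
        return pd.read_csv(fh, comment="#")


def texture_classes() -> list[str]:
    """Names of the shipped European texture classes."""
    return list(_texture_table()["class"])


def texture_params(class_name: str) -> SoilTextureParams:
    """Look up the shipped Campbell parameters for a European texture class
    (Coarse, Medium, Medium Fine, Fine, Very Fine; case-insensitive)."""
    table = _texture_table()
    key = " ".join(class_name.split()).lower()
    match = table[table["class"].str.lower() == key]
    if match.empty:
        raise ValueError(
            f"unknown texture class {class_name!r}; valid classes: "
            + ", ".join(texture_classes())
        )
    row = match.iloc[0]
    return SoilTextureParams(
        theta_s=row["theta_s"],
        theta_r=row["theta_r"],
        theta_fc=row["theta_fc"],
        psi_e=row["psi_e"],
        b=row["b"],
        rho_soil=row["rho_soil"],
    )


def pet_daily(r_ex, t_mean):
    """Potential evapotranspiration (mm day-1), empirical equation for
    Greece: 0.06257 * R_ex / (1 - 0.0234 * T_mean), with T_mean capped at
    40 degC to stay clear of the formula's pole."""
    r_ex = np.asarray(r_ex, dtype=float)
    if np.any(r_ex < 0):
        raise ValueError("extraterrestrial radiation must be >= 0")
    t = np.minimum(np.asarray(t_mean, dtype=float), PET_T_CAP)
    out = 0.06257 * r_ex / (1.0 - 0.0234 * t)
    return float(out) if out.ndim == 0 else out


def aw_from_theta(theta, column: SoilColumn):
    """Available water (mm) from volumetric content over the column depth."""
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < 0):
        raise ValueError("theta must be >= 0")
    out = theta * column.texture.rho_soil * column.depth / RHO_W
    return float(out) if out.ndim == 0 else out


def theta_from_aw(aw, column: SoilColumn):
    """Volumetric content (m3 m-3) from available water:
    theta = AW * rho_w / (rho_soil * depth)."""
    aw = np.asarray(aw, dtype=float)
    if np.any(aw < 0):
        raise ValueError("aw must be >= 0")
    out = aw * RHO_W / (column.texture.rho_soil * column.depth)
    return float(out) if out.ndim == 0 else out


def psi_from_theta(theta, texture: SoilTextureParams):
    """Campbell retention: psi = -psi_e * (theta/theta_s)^(-b), MPa (<= 0)."""
    theta = np.asarray(theta, dtype=float)
    if np.any(theta <= 0):
        raise ValueError("theta must be > 0 for the retention curve")
    out = -texture.psi_e * (theta / texture.theta_s) ** (-texture.b)
    return float(out) if out.ndim == 0 else out


def theta_from_psi(psi, texture: SoilTextureParams):
    """Inverse Campbell retention: theta = theta_s * (-psi/psi_e)^(-1/b)
    for psi <= -psi_e (drier than air entry)."""
    psi = np.asarray(psi, dtype=float)
    if np.any(psi >= 0):
        raise ValueError("psi must be negative (MPa)")
    out = texture.theta_s * (-psi / texture.psi_e) ** (-1.0 / texture.b)
    return float(out) if out.ndim == 0 else out


def theta_sp_min(texture: SoilTextureParams, hydraulics: SpeciesHydraulics) -> float:
    """Soil moisture at the species minimum water potential, clamped below
    at the residual content."""
    if hydraulics.psi_min <= texture.psi_e:
        raise ValueError(
            "psi_min must exceed the air-entry potential "
            f"({hydraulics.psi_min} <= {texture.psi_e} MPa)"
        )
    value = theta_from_psi(-hydraulics.psi_min, texture)
    return max(value, texture.theta_r)


def rew(theta, column: SoilColumn):
    """Relative extractable water: (theta - theta_sp_min) /
    (theta_fc - theta_sp_min), clamped to [0, 1]."""
    denom = column.texture.theta_fc - column.theta_sp_min
    if denom <= 0:
        raise ValueError("degenerate column: theta_fc <= theta_sp_min")
    out = np.clip((np.asarray(theta, dtype=float) - column.theta_sp_min) / denom, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def _state_from_aw(aw: float, column: SoilColumn) -> SoilState:
    theta = theta_from_aw(aw, column)
    return SoilState(
        aw=aw,
        theta=theta,
        rew=rew(theta, column),
        psi=psi_from_theta(theta, column.texture),
    )


def initial_state(column: SoilColumn) -> SoilState:
    """Bucket at field capacity — the mid-winter Mediterranean start used
    on the first simulation day (before spin-up)."""
    return _state_from_aw(column.aw_fc, column)


def step_water_balance(
    state: SoilState,
    precip_today: float,
    pet_prev: float,
    rew_prev: float,
    column: SoilColumn,
) -> SoilState:
    """One daily bucket update.

    AW_new = min(max(AW + P - REW* . PET*, AW_r), AW_fc), where the starred
    quantities are previous-day REW and PET; theta, REW and psi are derived
    from the clamped store.
    """
    if precip_today < 0:
        raise ValueError("precipitation must be >= 0")
    aw_new = min(max(state.aw + precip_today - rew_prev * pet_prev, column.aw_r), column.aw_fc)
    return _state_from_aw(aw_new, column)


def run_bucket(
    column: SoilColumn,
    precip: np.ndarray,
    pet: np.ndarray,
    state0: SoilState | None = None,
) -> pd.DataFrame:
    """Run the bucket over aligned daily precipitation and PET arrays.

    Day d consumes P(d) together with the previous day's REW and PET (a
    zero draw on the first day, which starts from ``state0`` or field
    capacity). Returns a DataFrame with columns ``aw, theta, rew, psi``.
    """
    precip = np.asarray(precip, dtype=float)
    pet = np.asarray(pet, dtype=float)
    if precip.shape != pet.shape:
        raise ValueError("precip and pet must have equal length")
    n = len(precip)
    state = state0 or initial_state(column)
    aw = np.empty(n)
    theta = np.empty(n)
    rew_arr = np.empty(n)
    psi = np.empty(n)
    pet_prev = 0.0
    rew_prev = state.rew
    for i in range(n):
        state = step_water_balance(state, precip[i], pet_prev, rew_prev, column)
        aw[i] = state.aw
        theta[i] = state.theta
        rew_arr[i] = state.rew
        psi[i] = state.psi
        pet_prev = pet[i]
        rew_prev = state.rew
    return pd.DataFrame({"aw": aw, "theta": theta, "rew": rew_arr, "psi": psi})
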