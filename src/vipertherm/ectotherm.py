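"""Steady-state operative temperature (Te) of a cylindrical ectotherm.

Operative temperature is the equilibrium body temperature of a
non-thermoregulating animal — the environmental temperature "available" to
it. The animal is modelled as a horizontal cylinder exchanging heat by
absorbed shortwave on its silhouette, longwave with sky (upper half) and
substrate (lower half), thermal emission from its lateral surface, and
forced convection with the air. No behaviour, no metabolic heat, no
evaporation, no thermal inertia: each hour's Te is the root of a
steady-state energy balance.

The balance f(Te) = Q_abs - Q_loss(Te) is strictly decreasing in Te
(a quartic emission term plus a linear convective term, both with positive
coefficients), so the root is unique and bracketed bisection always
converges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .microclimate import EnvironmentHour, HourlyEnvironment, HOURS_PER_YEAR

STEFAN_BOLTZMANN = 5.67e-8  # W m^-2 K^-4
AIR_KINEMATIC_VISCOSITY = 1.5e-5  # m^2 s^-1
AIR_CONDUCTIVITY = 0.026  # W m^-1 K^-1
FREE_CONVECTION_FLOOR = 5.0  # W m^-2 K^-1
KELVIN = 273.15

BRACKET_BELOW = 50.0  # bisection bracket: [Ta - 50, Ta + 100] degC
BRACKET_ABOVE = 100.0
RESIDUAL_TOL_W = 1e-6


class BracketError(RuntimeError):
    """The energy balance has no sign change on the bisection bracket."""


@dataclass(frozen=True)
class TaxonTraits:
    """Morphological and physiological traits of one taxon.

    vtmax is the voluntary thermal maximum: the body temperature above which
    the animal ceases surface activity. The diurnal flag does not enter the
    Te computation (Te is behaviour-free) but is carried for trait-table
    fidelity.
    """

    name: str
    vtmax: float
    mass: float  # g
    density: float = 1000.0  # kg m^-3
    length_to_diameter: float = 10.0
    absorptance: float = 0.9
    emissivity: float = 0.95
    diurnal: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.vtmax < 60):
            raise ValueError(f"implausible threshold: vtmax={self.vtmax} degC")
        if self.mass <= 0:
            raise ValueError("mass must be positive")
        if self.density <= 0:
            raise ValueError("density must be positive")
        if not 0 < self.absorptance <= 1:
            raise ValueError("absorptance must be in (0, 1]")
        if not 0 < self.emissivity <= 1:
            raise ValueError("emissivity must be in (0, 1]")
        if self.length_to_diameter <= 0:
            raise ValueError("length_to_diameter must be positive")


@dataclass(frozen=True)
class CylinderGeometry:
    radius: float  # m
    length: float  # m
    area_lateral: float  # m^2
    area_total: float  # m^2
    area_silhouette: float  # m^2, diameter x length (sun normal to axis)


@dataclass
class OperativeSeries:
    """8760 hourly Te values for one site x scenario x taxon."""

    te: np.ndarray
    site_id: str
    scenario: str
    taxon: str

    def __post_init__(self) -> None:
        te = np.asarray(self.te, dtype=float)
        if te.shape != (HOURS_PER_YEAR,):
            raise ValueError(f"Te series must have {HOURS_PER_YEAR} hours, got {te.shape}")
        if not np.isfinite(te).all():
            raise ValueError("non-finite Te")
        self.te = te


def cylinder_geometry(traits: TaxonTraits) -> CylinderGeometry:
    """Cylinder dimensions from mass: V = m/rho, L = k * 2r => r = (V/(2 k pi))^(1/3)."""
    volume = (traits.mass / 1000.0) / traits.density  # m^3
    k = traits.length_to_diameter
    radius = (volume / (2.0 * k * np.pi)) ** (1.0 / 3.0)
    length = 2.0 * k * radius
    area_lateral = 2.0 * np.pi * radius * length
    area_total = area_lateral + 2.0 * np.pi * radius ** 2
    return CylinderGeometry(
        radius=radius,
        length=length,
        area_lateral=area_lateral,
        area_total=area_total,
        area_silhouette=2.0 * radius * length,
    )


def convective_coefficient(wind, diameter: float):
    """Forced-convection coefficient for a cylinder in crossflow, W m^-2 K^-1.

    Nu = 0.615 Re^0.466 (Hilpert-type correlation for the relevant Reynolds
    range), floored at a free-convection value for still air.
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    wind = np.asarray(wind, dtype=float)
    if (wind < 0).any():
        raise ValueError("wind must be non-negative")
    reynolds = wind * diameter / AIR_KINEMATIC_VISCOSITY
    with np.errstate(divide="ignore"):
        nusselt = 0.615 * reynolds ** 0.466
    h = np.maximum(nusselt * AIR_CONDUCTIVITY / diameter, FREE_CONVECTION_FLOOR)
    return float(h) if h.ndim == 0 else h


def energy_residual(te, air_temp, solar, sky_temp, substrate_temp, wind, geom: CylinderGeometry, traits: TaxonTraits):
    """f(Te) = Q_abs - Q_loss(Te), W; array-capable.

    Q_abs: shortwave on the silhouette plus longwave from sky (upper half of
    the lateral area) and substrate (lower half). Q_loss: longwave emission
    from the full lateral area plus convection.
    """
    te_k = np.asarray(te, dtype=float) + KELVIN
    sky_k = np.asarray(sky_temp, dtype=float) + KELVIN
    sub_k = np.asarray(substrate_temp, dtype=float) + KELVIN
    h = convective_coefficient(wind, 2.0 * geom.radius)
    q_abs = (
        traits.absorptance * np.asarray(solar, dtype=float) * geom.area_silhouette
        + traits.emissivity * STEFAN_BOLTZMANN * (geom.area_lateral / 2.0) * (sky_k ** 4 + sub_k ** 4)
    )
    q_loss = (
        traits.emissivity * STEFAN_BOLTZMANN * geom.area_lateral * te_k ** 4
        + h * geom.area_lateral * (np.asarray(te, dtype=float) - np.asarray(air_temp, dtype=float))
    )
    return q_abs - q_loss


def solve_operative(
    air_temp,
    solar,
    sky_temp,
    substrate_temp,
    wind,
    geom: CylinderGeometry,
    traits: TaxonTraits,
    tol: float = RESIDUAL_TOL_W,
    max_iter: int = 200,
):
    """Vectorized bisection for Te on [Ta - 50, Ta + 100] to |f| < tol W."""
    ta = np.atleast_1d(np.asarray(air_temp, dtype=float))
    solar = np.broadcast_to(np.asarray(solar, dtype=float), ta.shape)
    sky = np.broadcast_to(np.asarray(sky_temp, dtype=float), ta.shape)
    sub = np.broadcast_to(np.asarray(substrate_temp, dtype=float), ta.shape)
    wind = np.broadcast_to(np.asarray(wind, dtype=float), ta.shape)

    lo = ta - BRACKET_BELOW
    hi = ta + BRACKET_ABOVE
    f_lo = energy_residual(lo, ta, solar, sky, sub, wind, geom, traits)
    f_hi = energy_residual(hi, ta, solar, sky, sub, wind, geom, traits)
    bad = (f_lo <= 0) | (f_hi >= 0)
    if bad.any():
        i = int(np.argmax(bad))
        raise BracketError(
            "bracket failure: no sign change for "
            f"Ta={ta[i]:.2f}, solar={solar[i]:.1f}, sky={sky[i]:.2f}, "
            f"substrate={sub[i]:.2f}, wind={wind[i]:.2f}"
        )

    mid = (lo + hi) / 2.0
    for _ in range(max_iter):
        f_mid = energy_residual(mid, ta, solar, sky, sub, wind, geom, traits)
        if np.abs(f_mid).max() < tol:
            break
        go_up = f_mid > 0  # f decreasing: positive residual means root is above
        lo = np.where(go_up, mid, lo)
        hi = np.where(go_up, hi, mid)
        mid = (lo + hi) / 2.0
    else:
        raise RuntimeError("bisection failed to reach residual tolerance")
    return mid


def operative_temperature(env_hour: EnvironmentHour, geom: CylinderGeometry, traits: TaxonTraits) -> float:
    """Te (degC) for a single hour's environment."""
    te = solve_operative(
        env_hour.air_temp,
        env_hour.solar,
        env_hour.sky_temp,
        env_hour.substrate_temp,
        env_hour.wind,
        geom,
        traits,
    )
    return float(te[0])


def annual_operative_series(
    env: HourlyEnvironment,
    traits: TaxonTraits,
    site_id: str = "",
    scenario: str = "",
) -> OperativeSeries:
    """Hourly Te for a full year; a behaviour-free ('dead-model') animal."""
    geom = cylinder_geometry(traits)
    try:
        te = solve_operative(
            env.air_temp, env.solar, env.sky_temp, env.substrate_temp, env.wind, geom, traits
        )
    except BracketError as exc:
        raise BracketError(f"{exc} (annual series for site {site_id!r})") from exc
    return OperativeSeries(te=te, site_id=site_id, scenario=scenario, taxon=traits.name)
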