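"""Aerodynamic and boundary-layer resistances under Monin-Obukhov
similarity.

The network has four resistances: R_A from the canopy air space to the
measurement height (MOST with Dyer-Businger stability corrections),
R_sub above the substrate (cover crop + soil) layer, R_x in the bulk
understory canopy boundary layer, and R_s just above the soil surface.
R_x and R_s use the Norman/Kustas convective forms with the default
coefficient set C' = 90 s^1/2 m^-1, s = 0.01 m, b = 0.012, c = 0.0025.
In-canopy wind follows a Goudriaan-type exponential attenuation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ResistanceConfig
from .thermo import GRAVITY, KARMAN

#: sentinel Obukhov length for neutral conditions (m)
L_NEUTRAL = 1.0e6


@dataclass
class StabilityState:
    """Friction velocity, Obukhov length and roughness parameters."""

    l_mo: np.ndarray
    u_star: np.ndarray
    d: np.ndarray
    z0m: np.ndarray
    z0h: np.ndarray
    converged: np.ndarray = None


def roughness(h_c, config: ResistanceConfig, z_ref: float = None):
    """Displacement height and roughness lengths from canopy height."""
    h_c = np.asarray(h_c, dtype=float)
    if np.any(h_c <= 0):
        raise ValueError("canopy height must be positive")
    if z_ref is not None and np.any(h_c >= z_ref):
        raise ValueError("canopy height reaches the measurement height")
    d = config.d_ratio * h_c
    z0m = config.z0m_ratio * h_c
    z0h = z0m / np.exp(config.kb_inv)
    return d, z0m, z0h


def psi_m(zeta):
    """Dyer-Businger integrated stability function for momentum.

    Exactly zero in the neutral band |zeta| < 1e-4 so that the neutral
    sentinel Obukhov length recovers the pure log law.
    """
    zeta = np.asarray(zeta, dtype=float)
    zeta = np.where(np.abs(zeta) < 1e-4, 0.0, zeta)
    unstable = zeta < 0
    x = (1.0 - 16.0 * np.where(unstable, zeta, 0.0)) ** 0.25
    psi_u = (
        2.0 * np.log((1.0 + x) / 2.0)
        + np.log((1.0 + x ** 2) / 2.0)
        - 2.0 * np.arctan(x)
        + np.pi / 2.0
    )
    psi_s = -5.0 * np.clip(zeta, 0.0, 5.0)
    return np.where(unstable, psi_u, psi_s)


def psi_h(zeta):
    """Dyer-Businger integrated stability function for heat."""
    zeta = np.asarray(zeta, dtype=float)
    zeta = np.where(np.abs(zeta) < 1e-4, 0.0, zeta)
    unstable = zeta < 0
    x = (1.0 - 16.0 * np.where(unstable, zeta, 0.0)) ** 0.25
    psi_u = 2.0 * np.log((1.0 + x ** 2) / 2.0)
    psi_s = -5.0 * np.clip(zeta, 0.0, 5.0)
    return np.where(unstable, psi_u, psi_s)


def friction_velocity(u, z_u, d, z0m, l_mo, config: ResistanceConfig):
    """u* from the stability-corrected log wind profile."""
    u = np.maximum(np.asarray(u, dtype=float), config.u_floor)
    z = np.asarray(z_u, dtype=float) - d
    denom = np.log(z / z0m) - psi_m(z / l_mo) + psi_m(z0m / l_mo)
    denom = np.maximum(denom, 0.1)
    return KARMAN * u / denom


def aerodynamic_resistance(u, z_u, z_t, stability: StabilityState,
                           config: ResistanceConfig):
    """R_A (s m-1) between the canopy air space and measurement height.

    R_A = [ln((z_T - d)/z0h) - Psi_h] / (k u*); in the neutral limit
    this reduces to the familiar product-of-logs form over k^2 u.
    """
    z = np.asarray(z_t, dtype=float) - stability.d
    num = (
        np.log(z / stability.z0h)
        - psi_h(z / stability.l_mo)
        + psi_h(stability.z0h / stability.l_mo)
    )
    num = np.maximum(num, 0.1)
    r_a = num / (KARMAN * np.maximum(stability.u_star, 1e-4))
    return np.clip(r_a, 1.0, 5000.0)


def wind_at_height(z, h_c, stability: StabilityState, config: ResistanceConfig):
    """Above-canopy MOST wind speed at height z (>= canopy top)."""
    zz = np.maximum(np.asarray(z, dtype=float) - stability.d, stability.z0m * 1.5)
    term = (
        np.log(zz / stability.z0m)
        - psi_m(zz / stability.l_mo)
        + psi_m(stability.z0m / stability.l_mo)
    )
    return np.maximum(stability.u_star / KARMAN * term, 0.05)


def goudriaan_attenuation(lai, h_c, leaf_width):
    """Wind extinction coefficient of a canopy layer (Goudriaan)."""
    lai = np.maximum(np.asarray(lai, dtype=float), 1e-6)
    return 0.28 * lai ** (2.0 / 3.0) * np.asarray(h_c, dtype=float) ** (1.0 / 3.0) * (
        np.asarray(leaf_width, dtype=float) ** (-1.0 / 3.0)
    )


def in_canopy_wind(u_top, h_c, z, attenuation):
    """Exponentially attenuated wind inside the canopy at height z."""
    z = np.asarray(z, dtype=float)
    u = np.asarray(u_top, dtype=float) * np.exp(
        -attenuation * (1.0 - z / np.asarray(h_c, dtype=float))
    )
    return np.maximum(u, 0.01)


def boundary_resistances(
    stability: StabilityState,
    h_c_ov,
    lai_ov,
    leaf_width_ov,
    h_c_un,
    lai_un,
    leaf_width_un,
    dt_sub,
    dt_soil,
    config: ResistanceConfig,
):
    """R_x, R_s and R_sub of the substrate network (s m-1).

    Parameters
    ----------
    dt_sub : T_sub - T_A (K), drives free convection above the substrate.
    dt_soil : T_soil - T_AC (K), drives free convection above the soil.

    The wind profile is attenuated through the overstory down to the
    understory top, then through the understory down to the soil.
    """
    h_c_ov = np.asarray(h_c_ov, dtype=float)
    h_c_un = np.asarray(h_c_un, dtype=float)
    u_hc = wind_at_height(h_c_ov, h_c_ov, stability, config)
    a_ov = goudriaan_attenuation(lai_ov, h_c_ov, leaf_width_ov)
    a_un = goudriaan_attenuation(lai_un, h_c_un, leaf_width_un)

    # wind at the substrate (understory canopy top) level
    u_sub = in_canopy_wind(u_hc, h_c_ov, h_c_un, a_ov)
    # wind at the understory source height and just above the soil
    u_mid_un = u_sub * np.exp(-a_un * (1.0 - 0.5))
    u_soil = u_sub * np.exp(-a_un * (1.0 - np.minimum(0.05 / h_c_un, 1.0)))
    u_mid_un = np.maximum(u_mid_un, 0.01)
    u_soil = np.maximum(u_soil, 0.01)

    lai_un_safe = np.maximum(np.asarray(lai_un, dtype=float), 1e-3)
    r_x = config.c_prime / lai_un_safe * np.sqrt(
        config.leaf_size / u_mid_un
    )
    # cap keeps the H_un * R_x temperature offset bounded as LAI_cc -> 0
    # (H_un -> 0 in that limit, so the cap never changes a resolved flux)
    r_x = np.clip(r_x, 1.0, 2.0e3)

    free_s = config.c_coeff * np.maximum(np.asarray(dt_soil, dtype=float), 0.0) ** (
        1.0 / 3.0
    )
    r_s = 1.0 / np.maximum(free_s + config.b_coeff * u_soil, 1.0e-4)
    r_s = np.clip(r_s, 1.0, 1.0e4)

    free_sub = config.c_coeff * np.maximum(np.asarray(dt_sub, dtype=float), 0.0) ** (
        1.0 / 3.0
    )
    r_sub = 1.0 / np.maximum(free_sub + config.b_coeff * u_sub, 1.0e-4)
    r_sub = np.clip(r_sub, 1.0, 1.0e4)
    return r_x, r_s, r_sub


def obukhov_length(u_star, t_a, rho_cp_air, h_total, config: ResistanceConfig):
    """Obukhov length L = -rho cp u*^3 T_A / (k g H) with clipping."""
    u_star = np.asarray(u_star, dtype=float)
    h = np.asarray(h_total, dtype=float)
    l_mo = np.where(
        np.abs(h) > 1e-6,
        -np.asarray(rho_cp_air, dtype=float)
        * u_star ** 3
        * np.asarray(t_a, dtype=float)
        / (KARMAN * GRAVITY * np.where(np.abs(h) > 1e-6, h, 1.0)),
        L_NEUTRAL,
    )
    sign = np.where(l_mo >= 0, 1.0, -1.0)
    return sign * np.clip(np.abs(l_mo), config.l_min, L_NEUTRAL)


def stability_iteration(
    h_total,
    u,
    t_a,
    rho_cp_air,
    z_u,
    d,
    z0m,
    z0h,
    config: ResistanceConfig,
    max_iter: int = 50,
    rel_tol: float = 1.0e-3,
) -> StabilityState:
    """Fixed-point iteration of (u*, L) for a given total sensible heat.

    Returns a :class:`StabilityState`; records that fail to converge
    fall back to neutral and are flagged in ``converged``.
    """
    h_total = np.asarray(h_total, dtype=float)
    shape = np.broadcast_shapes(
        h_total.shape, np.shape(u), np.shape(t_a), np.shape(d)
    )
    l_mo = np.full(shape, L_NEUTRAL)
    converged = np.zeros(shape, dtype=bool)
    u_star = friction_velocity(u, z_u, d, z0m, l_mo, config)
    for _ in range(max_iter):
        l_new = obukhov_length(u_star, t_a, rho_cp_air, h_total, config)
        delta = np.abs(l_new - l_mo) / np.maximum(np.abs(l_new), 1.0)
        converged = delta < rel_tol
        l_mo = l_new
        u_star = friction_velocity(u, z_u, d, z0m, l_mo, config)
        if np.all(converged):
            break
    l_mo = np.where(converged, l_mo, L_NEUTRAL)
    u_star = friction_velocity(u, z_u, d, z0m, l_mo, config)
    return StabilityState(
        l_mo=l_mo,
        u_star=u_star,
        d=np.broadcast_to(np.asarray(d, dtype=float), shape).copy(),
        z0m=np.broadcast_to(np.asarray(z0m, dtype=float), shape).copy(),
        z0h=np.broadcast_to(np.asarray(z0h, dtype=float), shape).copy(),
        converged=converged,
    )
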