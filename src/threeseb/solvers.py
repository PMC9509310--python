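"""Nested three-source and two-source energy balance solvers.

The surface is first split into a parallel overstory-substrate system:
the vine sensible heat follows directly from its aerodynamic coupling
to the air above (H_ov = rho cp (T_ov - T_A) / R_A) and the substrate
temperature is obtained by radiometric decomposition of T_rad.  The
substrate is then split in series into understory and soil: the
canopy-air-space temperature T_AC follows from the substrate sensible
heat, the understory temperature from its Priestley-Taylor flux
through R_x, and the soil temperature by a second radiometric
decomposition, closing the soil balance with LE as the residual.

Both vegetation layers are initialized with the Priestley-Taylor
coefficient at its default 1.26 and alpha is reduced layer-by-layer in
0.1 steps whenever the residual soil latent heat turns negative, until
no daytime condensation remains.  The two-source solver is the exact
specialization of the same network with a single bulk canopy layer and
the understory zeroed, so the models agree identically when the cover
crop is absent.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields

import numpy as np
import pandas as pd

from . import thermo
from .canopy import beam_extinction_kb, clumping_index, fraction_viewed, structural_params
from .config import SiteConfig
from .forcing_io import daytime_mask
from .radiation import net_radiation_three_source, soil_heat_flux
from .resistances import (
    L_NEUTRAL,
    StabilityState,
    aerodynamic_resistance,
    boundary_resistances,
    friction_velocity,
    obukhov_length,
    roughness,
)
from .solar import sun_zenith

#: diagnostics reason codes
REASON_OK = 0
REASON_SOIL_PINNED = 1
REASON_MAX_ITER = 2
REASON_BAD_RADICAND = 3

#: under-relaxation weight of the canopy-temperature updates
RELAX = 0.6


@dataclass
class FluxPartition:
    """Solved per-source energy balance components (arrays, W m-2 / K)."""

    rn_ov: np.ndarray
    rn_un: np.ndarray
    rn_soil: np.ndarray
    h_ov: np.ndarray
    h_un: np.ndarray
    h_soil: np.ndarray
    le_ov: np.ndarray
    le_un: np.ndarray
    le_soil: np.ndarray
    g: np.ndarray
    t_ov: np.ndarray
    t_un: np.ndarray
    t_soil: np.ndarray
    t_sub: np.ndarray
    t_ac: np.ndarray
    alpha_ov: np.ndarray
    alpha_un: np.ndarray
    converged: np.ndarray
    n_iter: np.ndarray

    def to_frame(self, index=None) -> pd.DataFrame:
        data = {f.name: getattr(self, f.name) for f in dc_fields(self)}
        return pd.DataFrame(data, index=index)


@dataclass
class SolverDiagnostics:
    """Per-timestamp convergence bookkeeping."""

    reason: np.ndarray          # REASON_* codes
    l_mo: np.ndarray
    u_star: np.ndarray
    r_a: np.ndarray
    r_x: np.ndarray
    r_s: np.ndarray
    r_sub: np.ndarray


def pt_canopy_flux(rn_c, fg_c, alpha_c, delta, gamma):
    """Priestley-Taylor canopy fluxes.

    LE_c = alpha f_g Delta/(Delta+gamma) max(Rn_c, 0) and
    H_c = Rn_c - LE_c.  A layer with non-positive net radiation
    transpires nothing rather than condensing.
    """
    rn_c = np.asarray(rn_c, dtype=float)
    ratio = np.asarray(delta, dtype=float) / (
        np.asarray(delta, dtype=float) + np.asarray(gamma, dtype=float)
    )
    le = np.asarray(alpha_c, dtype=float) * np.asarray(fg_c, dtype=float) * ratio * np.maximum(rn_c, 0.0)
    return le, rn_c - le


def compose_trad(f_theta, t_layer, t_below):
    """Fourth-power composite temperature [f T_layer^4 + (1-f) T_below^4]^1/4."""
    f = np.asarray(f_theta, dtype=float)
    return (
        f * np.asarray(t_layer, dtype=float) ** 4
        + (1.0 - f) * np.asarray(t_below, dtype=float) ** 4
    ) ** 0.25


def decompose_trad(t_composite, f_theta, t_layer, clip: bool = False):
    """Invert the radiometric composition for the lower component.

    Returns T_below = [(T_comp^4 - f T_layer^4) / (1 - f)]^(1/4).  A
    negative radicand means the assumed layer temperature is physically
    inconsistent with the composite; by default this raises, while
    ``clip=True`` substitutes the composite temperature and returns a
    boolean mask of the affected entries (the solver uses this to
    trigger its alpha-reduction bookkeeping).
    """
    t_comp = np.asarray(t_composite, dtype=float)
    f = np.asarray(f_theta, dtype=float)
    if np.any(f >= 1.0) or np.any(f < 0.0):
        raise ValueError("f_theta must lie in [0, 1)")
    radicand = (t_comp ** 4 - f * np.asarray(t_layer, dtype=float) ** 4) / (1.0 - f)
    bad = radicand <= 0.0
    if np.any(bad):
        if not clip:
            raise ValueError(
                "negative radicand: component temperature inconsistent with composite"
            )
        radicand = np.where(bad, t_comp ** 4, radicand)
    t_below = radicand ** 0.25
    if clip:
        return t_below, bad
    return t_below


def _solve_network(forcing: dict, ov: dict, un: dict, config: SiteConfig,
                   g_mode: str = "ratio", g_obs=None):
    """Vectorized nested solver over daytime records.

    ``forcing`` and the two layer dicts hold equal-length arrays; see
    :func:`solve_3seb` for the public entry point.
    """
    sc = config.solver
    rc = config.resistance
    n = len(forcing["t_a"])

    t_a = forcing["t_a"]
    t_rad = forcing["t_rad"]
    p = forcing["p"]
    e_a = forcing["e_a"]
    u = forcing["u"]
    theta = forcing["theta"]
    doy = forcing["doy"]

    rho_cp = thermo.rho_cp(t_a, p, e_a)
    delta = thermo.delta_svp(t_a)
    gamma = thermo.psychrometric_gamma(p, t_a)

    # sensor view fractions (nadir-viewing radiometer)
    kb0_ov = beam_extinction_kb(0.0, float(np.atleast_1d(ov["x_lad"])[0]))
    kb0_un = beam_extinction_kb(0.0, float(np.atleast_1d(un["x_lad"])[0]))
    f_ov = np.clip(fraction_viewed(ov["lai"], ov["omega"], kb0_ov), 0.0, 0.99)
    f_un = np.clip(fraction_viewed(un["lai"], un["omega"], kb0_un), 0.0, 0.99)

    alpha_ov = np.full(n, sc.alpha_pt_max)
    alpha_un = np.full(n, sc.alpha_pt_max)
    t_ov = t_rad.copy()
    t_un = t_rad.copy()
    t_soil = t_rad.copy()
    t_sub = t_rad.copy()
    t_ac = t_a.copy()
    l_mo = np.full(n, L_NEUTRAL)

    active = np.ones(n, dtype=bool)
    reason = np.full(n, REASON_OK, dtype=int)
    pinned = np.zeros(n, dtype=bool)
    n_iter = np.zeros(n, dtype=int)

    d, z0m, z0h = roughness(ov["h_c"], rc, z_ref=None)

    state = {}
    for round_idx in range(sc.max_alpha_rounds):
        for _ in range(sc.max_inner_iter):
            u_star = friction_velocity(u, config.z_u, d, z0m, l_mo, rc)
            stab = StabilityState(l_mo=l_mo, u_star=u_star, d=d, z0m=z0m, z0h=z0h)
            r_a = aerodynamic_resistance(u, config.z_u, config.z_t, stab, rc)
            r_x, r_s, r_sub = boundary_resistances(
                stab,
                ov["h_c"], ov["lai"], ov["leaf_width"],
                un["h_c"], un["lai"], un["leaf_width"],
                t_sub - t_a, t_soil - t_ac, rc,
            )
            budget = net_radiation_three_source(
                forcing["sw_in"], forcing["l_in"], theta, doy,
                ov["lai"], ov["omega"], float(np.atleast_1d(ov["x_lad"])[0]),
                un["lai"], un["omega"], float(np.atleast_1d(un["x_lad"])[0]),
                t_ov, t_un, t_soil, config.optics,
            )
            g = soil_heat_flux(budget.rn_soil, g_mode, g_obs, sc.g_ratio)

            le_ov, h_ov = pt_canopy_flux(budget.rn_ov, ov["fg"], alpha_ov, delta, gamma)
            # under-relaxed, excursion-limited canopy temperatures keep the
            # fixed point identical while damping low-wind oscillations; the
            # radiometric inversions below them stay exact at every iterate
            t_ov_new = np.clip(t_a + h_ov * r_a / rho_cp, t_a - 60.0, t_a + 80.0)
            t_ov_new = RELAX * t_ov_new + (1.0 - RELAX) * t_ov
            t_sub_new, bad_sub = decompose_trad(t_rad, f_ov, t_ov_new, clip=True)
            h_sub = rho_cp * (t_sub_new - t_a) / (r_a + r_sub)
            t_ac_new = t_a + h_sub * r_a / rho_cp

            le_un, h_un = pt_canopy_flux(budget.rn_un, un["fg"], alpha_un, delta, gamma)
            t_un_new = np.clip(
                t_ac_new + h_un * r_x / rho_cp, t_a - 60.0, t_a + 80.0
            )
            t_un_new = RELAX * t_un_new + (1.0 - RELAX) * t_un
            t_soil_new, bad_soil = decompose_trad(t_sub_new, f_un, t_un_new, clip=True)
            h_soil = rho_cp * (t_soil_new - t_ac_new) / r_s
            le_soil = budget.rn_soil - h_soil - g

            h_total = h_ov + h_un + h_soil
            l_new = obukhov_length(u_star, t_a, rho_cp, h_total, rc)

            dt_max = np.max(
                np.stack(
                    [
                        np.abs(t_ov_new - t_ov),
                        np.abs(t_un_new - t_un),
                        np.abs(t_soil_new - t_soil),
                    ]
                ),
                axis=0,
            )
            dl_rel = np.abs(l_new - l_mo) / np.maximum(np.abs(l_new), 1.0)
            t_ov, t_un, t_soil = t_ov_new, t_un_new, t_soil_new
            t_sub, t_ac = t_sub_new, t_ac_new
            l_mo = l_new
            n_iter += active.astype(int)
            settled = (dt_max < sc.t_tol) & (dl_rel < sc.l_rel_tol)
            if np.all(settled[active]):
                break

        state = dict(
            budget=budget, g=g, le_ov=le_ov, h_ov=h_ov, le_un=le_un, h_un=h_un,
            h_soil=h_soil, le_soil=le_soil, r_a=r_a, r_x=r_x, r_s=r_s,
            r_sub=r_sub, u_star=u_star, bad_sub=bad_sub, bad_soil=bad_soil,
        )

        viol = active & (le_soil < -1e-6)
        if not np.any(viol):
            active &= viol  # all remaining rows are done
            break

        # layer whose alpha reduction can still change the solution
        can_un = (alpha_un > 1e-9) & (un["fg"] > 0) & (budget.rn_un > 0)
        can_ov = (alpha_ov > 1e-9) & (ov["fg"] > 0) & (budget.rn_ov > 0)
        red_un = viol & can_un
        red_ov = viol & ~can_un & can_ov
        stuck = viol & ~can_un & ~can_ov

        alpha_un = np.where(red_un, np.maximum(alpha_un - sc.alpha_step, 0.0), alpha_un)
        alpha_ov = np.where(red_ov, np.maximum(alpha_ov - sc.alpha_step, 0.0), alpha_ov)
        pinned |= stuck
        reason[stuck] = REASON_SOIL_PINNED
        active &= ~stuck
    else:
        # loop exhausted with violations outstanding
        leftover = active & (state["le_soil"] < -1e-6)
        reason[leftover] = REASON_MAX_ITER

    le_soil = state["le_soil"]
    h_soil = state["h_soil"]
    g = state["g"]
    budget = state["budget"]

    # pinned records: no daytime condensation, soil balance rebalanced
    le_soil = np.where(pinned, 0.0, le_soil)
    h_soil = np.where(pinned, budget.rn_soil - g, h_soil)

    bad = state["bad_sub"] | state["bad_soil"]
    reason = np.where(bad & (reason == REASON_OK), REASON_BAD_RADICAND, reason)
    converged = reason == REASON_OK

    partition = FluxPartition(
        rn_ov=budget.rn_ov,
        rn_un=budget.rn_un,
        rn_soil=budget.rn_soil,
        h_ov=state["h_ov"],
        h_un=state["h_un"],
        h_soil=h_soil,
        le_ov=state["le_ov"],
        le_un=state["le_un"],
        le_soil=le_soil,
        g=g,
        t_ov=t_ov,
        t_un=t_un,
        t_soil=t_soil,
        t_sub=t_sub,
        t_ac=t_ac,
        alpha_ov=alpha_ov,
        alpha_un=alpha_un,
        converged=converged,
        n_iter=n_iter,
    )
    diags = SolverDiagnostics(
        reason=reason,
        l_mo=l_mo,
        u_star=state["u_star"],
        r_a=state["r_a"],
        r_x=state["r_x"],
        r_s=state["r_s"],
        r_sub=state["r_sub"],
    )
    return partition, diags


def _forcing_arrays(met: pd.DataFrame, t_rad, config: SiteConfig, mask):
    times = pd.DatetimeIndex(met["timestamp"])
    theta = sun_zenith(times, config.latitude, config.longitude)
    return {
        "sw_in": met["sw_in"].to_numpy(dtype=float)[mask],
        "l_in": met["l_in"].to_numpy(dtype=float)[mask],
        "t_a": met["t_a"].to_numpy(dtype=float)[mask],
        "e_a": met["e_a"].to_numpy(dtype=float)[mask],
        "u": met["u"].to_numpy(dtype=float)[mask],
        "p": met["p"].to_numpy(dtype=float)[mask],
        "t_rad": np.asarray(t_rad, dtype=float)[mask],
        "theta": np.minimum(theta[mask], np.pi / 2 - 1e-6),
        "doy": times.dayofyear.to_numpy(dtype=float)[mask],
    }


def _layer_arrays(canopy: pd.DataFrame, layer: str, config: SiteConfig, mask):
    st = config.structure
    if layer == "vine":
        return {
            "lai": canopy["lai_vine"].to_numpy(dtype=float)[mask],
            "fg": canopy["fg_vine"].to_numpy(dtype=float)[mask],
            "omega": canopy["omega_vine"].to_numpy(dtype=float)[mask],
            "h_c": canopy["h_c_vine"].to_numpy(dtype=float)[mask],
            "leaf_width": st.leaf_width_vine,
            "x_lad": st.x_lad_vine,
        }
    return {
        "lai": canopy["lai_cc"].to_numpy(dtype=float)[mask],
        "fg": canopy["fg_cc"].to_numpy(dtype=float)[mask],
        "omega": canopy["omega_cc"].to_numpy(dtype=float)[mask],
        "h_c": canopy["h_c_cc"].to_numpy(dtype=float)[mask],
        "leaf_width": st.leaf_width_cc,
        "x_lad": st.x_lad_cc,
    }


def _expand(partition: FluxPartition, diags: SolverDiagnostics, mask, index):
    """Scatter daytime solutions back onto the full time axis."""
    n = len(mask)
    frame = pd.DataFrame(index=index)
    for f in dc_fields(FluxPartition):
        full = np.full(n, np.nan)
        full[mask] = getattr(partition, f.name)
        frame[f.name] = full
    frame["converged"] = frame["converged"] == 1.0
    reason = np.full(n, -1, dtype=int)
    reason[mask] = diags.reason
    frame["reason"] = reason
    for name in ("l_mo", "u_star", "r_a", "r_x", "r_s", "r_sub"):
        full = np.full(n, np.nan)
        full[mask] = getattr(diags, name)
        frame[name] = full
    frame["daytime"] = mask
    return frame


def solve_3seb(met: pd.DataFrame, t_rad, canopy: pd.DataFrame,
               config: SiteConfig, g_mode: str = "ratio") -> pd.DataFrame:
    """Run the three-source energy balance over a tower time series.

    Parameters
    ----------
    met : canonical met frame (see :mod:`threeseb.forcing_io`).
    t_rad : radiometric surface temperature (K), aligned with ``met``.
    canopy : per-timestamp canopy table (daily values joined onto the
        met timestamps; see :func:`threeseb.pipeline.align_canopy`).
    config : full site configuration.
    g_mode : ``"ratio"`` (G = 0.35 Rn_soil) or ``"observed"``.

    Returns
    -------
    DataFrame indexed like ``met`` with the solved per-source fluxes,
    component temperatures, final alpha values, resistances and
    convergence diagnostics; night-time rows are NaN.
    """
    mask = daytime_mask(met["sw_in"].to_numpy(dtype=float))
    mask &= np.isfinite(np.asarray(t_rad, dtype=float))
    forcing = _forcing_arrays(met, t_rad, config, mask)
    ov = _layer_arrays(canopy, "vine", config, mask)
    un = _layer_arrays(canopy, "cc", config, mask)
    g_obs = None
    if g_mode == "observed":
        g_obs = met["g_obs"].to_numpy(dtype=float)[mask]
    partition, diags = _solve_network(forcing, ov, un, config, g_mode, g_obs)
    return _expand(partition, diags, mask, met.index)


def solve_tseb(met: pd.DataFrame, t_rad, canopy: pd.DataFrame,
               config: SiteConfig, g_mode: str = "ratio") -> pd.DataFrame:
    """Two-source baseline: one bulk canopy layer over the soil.

    The bulk layer carries LAI_vine + LAI_cc with an LAI-weighted green
    fraction and structure rescaled through the same empirical maps;
    the network is otherwise identical to the three-source solver with
    the understory removed, so both models coincide exactly when the
    cover crop is absent.  Output columns mirror :func:`solve_3seb`
    (``*_ov`` is the bulk canopy; ``*_un`` entries are zero).
    """
    mask = daytime_mask(met["sw_in"].to_numpy(dtype=float))
    mask &= np.isfinite(np.asarray(t_rad, dtype=float))
    forcing = _forcing_arrays(met, t_rad, config, mask)

    st = config.structure
    lai_v = canopy["lai_vine"].to_numpy(dtype=float)[mask]
    lai_c = canopy["lai_cc"].to_numpy(dtype=float)[mask]
    fg_v = canopy["fg_vine"].to_numpy(dtype=float)[mask]
    fg_c = canopy["fg_cc"].to_numpy(dtype=float)[mask]
    lai_bulk = lai_v + lai_c
    fg_bulk = np.where(lai_bulk > 0, (fg_v * lai_v + fg_c * lai_c) / np.maximum(lai_bulk, 1e-9), 0.0)
    h_c, w_c = structural_params(lai_bulk, st, config.phenology.lai_vine_floor)
    kb0 = float(beam_extinction_kb(0.0, st.x_lad_vine))
    omega = clumping_index(lai_bulk, w_c, kb0)

    ov = {
        "lai": lai_bulk,
        "fg": fg_bulk,
        "omega": omega,
        "h_c": h_c,
        "leaf_width": st.leaf_width_vine,
        "x_lad": st.x_lad_vine,
    }
    zeros = np.zeros_like(lai_bulk)
    un = {
        "lai": zeros,
        "fg": zeros,
        "omega": np.ones_like(lai_bulk),
        "h_c": np.full_like(lai_bulk, st.hc_cc),
        "leaf_width": st.leaf_width_cc,
        "x_lad": st.x_lad_cc,
    }
    g_obs = None
    if g_mode == "observed":
        g_obs = met["g_obs"].to_numpy(dtype=float)[mask]
    partition, diags = _solve_network(forcing, ov, un, config, g_mode, g_obs)
    return _expand(partition, diags, mask, met.index)
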