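"""Net radiation partitioning among overstory, understory and soil.

A two-band (PAR/NIR) shortwave scheme with Beer's-law beam extinction,
quadrature-based diffuse extinction and single-scatter redistribution,
plus a broadband longwave exchange between sky, the two vegetation
layers and the soil.  Every intercepted watt is assigned exactly once
to a layer absorption or to the outgoing streams, so the per-layer
budget closes to machine precision by construction:

    Rn_ov + Rn_un + Rn_soil = SW_in - SW_out + L_in - L_out.

The overstory shades the understory: the understory receives only the
beam and diffuse radiation transmitted through the vine layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .canopy import beam_extinction_kb, diffuse_transmittance
from .config import OpticsConfig
from .thermo import SIGMA

#: beam is switched off when the sun is lower than this (cos zenith)
MIN_COS_ZENITH = 0.017  # ~89 degrees


@dataclass
class RadiationBudget:
    """Per-layer net radiation and the stream bookkeeping (W m-2)."""

    rn_ov: np.ndarray
    rn_un: np.ndarray
    rn_soil: np.ndarray
    s_dir: np.ndarray
    s_dif: np.ndarray
    sw_out: np.ndarray
    lw_out: np.ndarray

    @property
    def rn_total(self):
        return self.rn_ov + self.rn_un + self.rn_soil


def split_direct_diffuse(sw_in, theta, doy):
    """Partition global shortwave into direct-beam and diffuse parts.

    Diffuse fraction from the Erbs et al. clearness-index correlation;
    the beam is zeroed at night and for grazing sun angles.
    """
    sw = np.asarray(sw_in, dtype=float)
    theta = np.asarray(theta, dtype=float)
    doy = np.asarray(doy, dtype=float)
    cos_z = np.cos(theta)

    toa = 1367.0 * (1.0 + 0.033 * np.cos(2.0 * np.pi * doy / 365.0)) * np.maximum(
        cos_z, 1e-6
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        kt = np.clip(sw / toa, 0.0, 1.0)

    fd = np.where(
        kt <= 0.22,
        1.0,  # overcast: all-diffuse limit
        np.where(
            kt <= 0.80,
            0.9511 - 0.1604 * kt + 4.388 * kt ** 2 - 16.638 * kt ** 3 + 12.336 * kt ** 4,
            0.165,
        ),
    )
    fd = np.clip(fd, 0.0, 1.0)
    sun_up = (cos_z > MIN_COS_ZENITH) & (sw > 0)
    s_dif = np.where(sun_up, fd * sw, sw)
    s_dir = np.where(sun_up, sw - s_dif, 0.0)
    return s_dir, s_dif


def _layer_interceptance(lai, omega, x_lad, theta):
    """Beam and diffuse interception fractions of one layer."""
    lai_eff = np.asarray(omega, dtype=float) * np.asarray(lai, dtype=float)
    theta_b = np.minimum(np.asarray(theta, dtype=float), np.pi / 2 - 1e-6)
    kb = beam_extinction_kb(theta_b, x_lad)
    i_beam = 1.0 - np.exp(-kb * lai_eff)
    i_dif = 1.0 - diffuse_transmittance(lai_eff, x_lad)
    return i_beam, i_dif


def net_radiation_three_source(
    sw_in,
    l_in,
    theta,
    doy,
    lai_ov,
    omega_ov,
    x_lad_ov,
    lai_un,
    omega_un,
    x_lad_un,
    t_ov,
    t_un,
    t_soil,
    optics: OpticsConfig,
) -> RadiationBudget:
    """Solve the layered radiation budget for every timestamp.

    All array arguments broadcast to a common length n.  Component
    temperatures are in kelvin; the longwave exchange uses the layer
    emissivities from ``optics`` (the blackbody assumption applies only
    to the radiometric temperature retrieval, not to the exchange).
    """
    sw_in = np.asarray(sw_in, dtype=float)
    l_in = np.asarray(l_in, dtype=float)
    s_dir, s_dif = split_direct_diffuse(sw_in, theta, doy)

    ib_ov, id_ov = _layer_interceptance(lai_ov, omega_ov, x_lad_ov, theta)
    ib_un, id_un = _layer_interceptance(lai_un, omega_un, x_lad_un, theta)

    abs_ov = np.zeros_like(sw_in)
    abs_un = np.zeros_like(sw_in)
    abs_soil = np.zeros_like(sw_in)
    sw_out = np.zeros_like(sw_in)

    bands = (
        (optics.par_fraction, optics.leaf_abs_par),
        (1.0 - optics.par_fraction, optics.leaf_abs_nir),
    )
    for frac, a_leaf in bands:
        beam = frac * s_dir
        dif = frac * s_dif

        # --- overstory ---
        int_b = ib_ov * beam
        int_d = id_ov * dif
        abs_ov += a_leaf * (int_b + int_d)
        scat = (1.0 - a_leaf) * (int_b + int_d)
        sw_out += 0.5 * scat                      # upward single scatter exits
        beam_below = beam - int_b
        dif_below = (dif - int_d) + 0.5 * scat    # downward scatter joins diffuse

        # --- understory ---
        int_b = ib_un * beam_below
        int_d = id_un * dif_below
        abs_un += a_leaf * (int_b + int_d)
        scat = (1.0 - a_leaf) * (int_b + int_d)
        up = 0.5 * scat
        # upward scatter re-intercepted by the overstory
        abs_ov += a_leaf * id_ov * up
        sw_out += up * (1.0 - a_leaf * id_ov)
        beam_soil = beam_below - int_b
        dif_soil = (dif_below - int_d) + 0.5 * scat

        # --- soil ---
        incident = beam_soil + dif_soil
        abs_soil += (1.0 - optics.soil_albedo) * incident
        up = optics.soil_albedo * incident
        abs_un += a_leaf * id_un * up
        up *= 1.0 - a_leaf * id_un
        abs_ov += a_leaf * id_ov * up
        sw_out += up * (1.0 - a_leaf * id_ov)

    # ---------------- longwave ----------------
    ev, es = optics.emiss_veg, optics.emiss_soil
    t_ov4 = SIGMA * np.asarray(t_ov, dtype=float) ** 4
    t_un4 = SIGMA * np.asarray(t_un, dtype=float) ** 4
    t_s4 = SIGMA * np.asarray(t_soil, dtype=float) ** 4
    e_ov = ev * id_ov * t_ov4          # per-side emission of the overstory
    e_un = ev * id_un * t_un4
    e_soil = es * t_s4

    lw_ov = np.zeros_like(sw_in)
    lw_un = np.zeros_like(sw_in)
    lw_soil = np.zeros_like(sw_in)
    lw_out = np.zeros_like(sw_in)

    def up_from_soil(stream):
        nonlocal lw_un, lw_ov, lw_out
        lw_un = lw_un + ev * id_un * stream
        stream = stream * (1.0 - ev * id_un)
        lw_ov = lw_ov + ev * id_ov * stream
        lw_out = lw_out + stream * (1.0 - ev * id_ov)

    def up_from_understory(stream):
        nonlocal lw_ov, lw_out
        lw_ov = lw_ov + ev * id_ov * stream
        lw_out = lw_out + stream * (1.0 - ev * id_ov)

    # downward pass
    lw_ov += ev * id_ov * l_in
    lw_out += (1.0 - ev) * id_ov * l_in           # top-layer reflection exits
    below_ov = (1.0 - id_ov) * l_in + e_ov

    lw_un += ev * id_un * below_ov
    up_from_understory((1.0 - ev) * id_un * below_ov)
    at_soil = (1.0 - id_un) * below_ov + e_un

    lw_soil += es * at_soil
    up_from_soil((1.0 - es) * at_soil)

    # upward emissions
    up_from_soil(e_soil)
    up_from_understory(e_un)
    lw_out += e_ov

    rn_ov = abs_ov + lw_ov - 2.0 * e_ov
    rn_un = abs_un + lw_un - 2.0 * e_un
    rn_soil = abs_soil + lw_soil - e_soil
    return RadiationBudget(
        rn_ov=rn_ov,
        rn_un=rn_un,
        rn_soil=rn_soil,
        s_dir=s_dir,
        s_dif=s_dif,
        sw_out=sw_out,
        lw_out=lw_out,
    )


def soil_heat_flux(rn_soil, mode: str = "ratio", g_obs=None, ratio: float = 0.35):
    """Ground heat flux as a fixed fraction of soil net radiation, or
    pass-through of the measured series."""
    if mode == "ratio":
        return ratio * np.asarray(rn_soil, dtype=float)
    if mode == "observed":
        if g_obs is None:
            raise ValueError("observed mode requires g_obs")
        g = np.asarray(g_obs, dtype=float)
        if np.any(~np.isfinite(g)):
            raise ValueError("observed mode requires g_obs at every timestamp")
        return g
    raise ValueError(f"unknown soil heat flux mode '{mode}'")
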