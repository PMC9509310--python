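"""Canopy structure: LAI decomposition, phenology, extinction and view
fractions.

The ecosystem leaf area index of a vineyard with an interrow cover crop
mixes two layers with opposite seasonal cycles.  ``partition_lai``
splits a daily ecosystem LAI series into vine (overstory) and cover
crop (understory) components using phenology-driven exponential
transitions; the remaining functions provide the radiative-geometry
primitives (beam extinction, clumping, fraction of vegetation seen by
a nadir radiometer) and the LAI-scaled structural parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PhenologyConfig, StructureConfig


@dataclass
class CanopyState:
    """Structure of both vegetation layers at one timestamp."""

    lai_eco: float
    lai_vine: float
    lai_cc: float
    fg_vine: float
    fg_cc: float
    h_c_vine: float
    h_c_cc: float
    w_c_vine: float
    w_c_cc: float
    omega_vine: float
    omega_cc: float
    row_width: float

    def __post_init__(self):
        for name in ("lai_eco", "lai_vine", "lai_cc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("fg_vine", "fg_cc"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("omega_vine", "omega_cc"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name}={v} outside (0, 1]")


def partition_lai(lai_eco: pd.Series, pheno: PhenologyConfig) -> pd.DataFrame:
    """Split daily ecosystem LAI into vine and cover-crop components.

    Before vine bud-break the cover crop carries all of the ecosystem
    LAI; from bud-break it senesces exponentially (e-folding
    ``pheno.decay_efolding_days``) until the day of peak ecosystem LAI,
    holds its senesced value through summer, and after vine leaf-off
    regrows exponentially toward the ecosystem LAI.  The vine component
    is the remainder, floored at ``pheno.lai_vine_floor`` year-round to
    represent woody elements.

    Parameters
    ----------
    lai_eco : Series of daily LAI with a DatetimeIndex (full years).
    pheno : phenology configuration.

    Returns
    -------
    DataFrame with columns ``lai_eco``, ``lai_vine``, ``lai_cc``.
    """
    if not isinstance(lai_eco.index, pd.DatetimeIndex):
        raise TypeError("lai_eco must have a DatetimeIndex")
    values = lai_eco.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError("lai_eco contains negative values")

    out = pd.DataFrame({"lai_eco": values}, index=lai_eco.index)
    out["lai_cc"] = 0.0

    if pheno.cc_present:
        tau = pheno.decay_efolding_days
        for _, grp in out.groupby(out.index.year):
            doy = grp.index.dayofyear.to_numpy()
            eco = grp["lai_eco"].to_numpy()
            if doy.min() > pheno.budbreak_doy or doy.max() < pheno.leafoff_doy:
                raise ValueError(
                    "phenology dates fall outside the LAI series coverage "
                    f"(year spans DOY {doy.min()}-{doy.max()})"
                )
            cc = np.empty_like(eco)
            pre = doy < pheno.budbreak_doy
            cc[pre] = eco[pre]

            # value carried into the decay phase
            i_bb = int(np.argmin(np.abs(doy - pheno.budbreak_doy)))
            cc_at_bb = eco[i_bb]
            # "peak summer" = day of maximum ecosystem LAI within the
            # vine leaf-on window; ties resolve to the latest such day
            window = (doy >= pheno.budbreak_doy) & (doy <= pheno.leafoff_doy)
            w_doy, w_eco = doy[window], eco[window]
            peak_doy = int(w_doy[len(w_eco) - 1 - int(np.argmax(w_eco[::-1]))])
            peak_doy = max(peak_doy, pheno.budbreak_doy + 1)

            decay = (doy >= pheno.budbreak_doy) & (doy <= pheno.leafoff_doy)
            d = np.minimum(doy[decay], peak_doy) - pheno.budbreak_doy
            cc[decay] = cc_at_bb * np.exp(-d / tau)

            post = doy > pheno.leafoff_doy
            if np.any(post):
                i_off = int(np.argmin(np.abs(doy - pheno.leafoff_doy)))
                hold = cc_at_bb * np.exp(-(peak_doy - pheno.budbreak_doy) / tau)
                gap0 = max(eco[i_off] - hold, 0.0)
                cc[post] = eco[post] - gap0 * np.exp(
                    -(doy[post] - pheno.leafoff_doy) / tau
                )
            cc = np.clip(cc, 0.0, eco)
            out.loc[grp.index, "lai_cc"] = cc

    out["lai_vine"] = np.maximum(
        out["lai_eco"] - out["lai_cc"], pheno.lai_vine_floor
    )
    return out


def green_fraction(doy, pheno: PhenologyConfig, layer: str):
    """Green (photosynthetically active) fraction of a layer.

    Vine foliage is fully green during leaf-on and senesced during
    leaf-off, with exponential transitions on the same e-folding time
    as the LAI dynamics.  The cover crop is green in spring and autumn
    and decays exponentially toward zero during its summer senescence.
    """
    doy = np.asarray(doy, dtype=float)
    tau = pheno.decay_efolding_days
    if layer == "vine":
        rise = 1.0 - np.exp(-(doy - pheno.budbreak_doy) / tau)
        fall = np.exp(-(doy - pheno.leafoff_doy) / tau)
        carry = np.exp(-(doy + 365.0 - pheno.leafoff_doy) / tau)
        fg = np.where(
            doy < pheno.budbreak_doy,
            carry,
            np.where(doy <= pheno.leafoff_doy, rise, fall),
        )
    elif layer == "cc":
        if not pheno.cc_present:
            return np.zeros_like(doy)
        sen = np.exp(-(doy - pheno.cc_mow_doy) / tau)
        f_end = np.exp(-(pheno.cc_regrow_doy - pheno.cc_mow_doy) / tau)
        regrow = 1.0 - (1.0 - f_end) * np.exp(-(doy - pheno.cc_regrow_doy) / tau)
        fg = np.where(
            doy < pheno.cc_mow_doy,
            1.0,
            np.where(doy < pheno.cc_regrow_doy, sen, regrow),
        )
    else:
        raise ValueError(f"unknown layer '{layer}'")
    return np.clip(fg, 0.0, 1.0)


def beam_extinction_kb(theta, x_lad: float = 1.0):
    """Beam extinction coefficient of an ellipsoidal leaf-angle canopy.

    kb = sqrt(x^2 + tan^2 theta) / (x + 1.774 (x + 1.182)^-0.733),
    with x the ellipsoid axis ratio (1 = spherical distribution).
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < 0) or np.any(theta >= np.pi / 2):
        raise ValueError("theta must lie in [0, pi/2): gate night-time records")
    return np.sqrt(x_lad ** 2 + np.tan(theta) ** 2) / (
        x_lad + 1.774 * (x_lad + 1.182) ** -0.733
    )


def diffuse_transmittance(lai_eff, x_lad: float = 1.0, n_nodes: int = 10):
    """Hemispherical (diffuse) transmittance of a canopy layer.

    tau_d = 2 int_0^{pi/2} exp(-kb(theta) * L) cos(theta) sin(theta)
    d(theta), evaluated with Gauss-Legendre quadrature.  ``lai_eff`` is
    the clumping-corrected leaf area index Omega * LAI.
    """
    lai_eff = np.atleast_1d(np.asarray(lai_eff, dtype=float))
    nodes, weights = np.polynomial.legendre.leggauss(n_nodes)
    theta = 0.25 * np.pi * (nodes + 1.0)  # map [-1, 1] -> [0, pi/2)
    w = 0.25 * np.pi * weights
    kb = beam_extinction_kb(np.minimum(theta, np.pi / 2 - 1e-9), x_lad)
    integrand = np.exp(-kb[None, :] * lai_eff[:, None]) * np.cos(theta) * np.sin(theta)
    tau = 2.0 * integrand @ w
    return np.clip(tau, 0.0, 1.0)


def fraction_viewed(lai, omega, kb):
    """Fraction of a layer seen by the radiometer: 1 - exp(-kb Omega F)."""
    lai = np.asarray(lai, dtype=float)
    return 1.0 - np.exp(-np.asarray(kb, dtype=float) * np.asarray(omega, dtype=float) * lai)


def clumping_index(lai, f_cover, kb_nadir: float = 0.5):
    """Clumping index of a row canopy from its fractional ground cover.

    Matches the gap probability of a rectangular-hedgerow canopy whose
    foliage is concentrated over a fraction ``f_cover`` of the ground:
    exp(-kb Omega F) = f_cover exp(-kb F / f_cover) + (1 - f_cover).
    Homogeneous cover (f_cover = 1) returns Omega = 1.
    """
    lai = np.asarray(lai, dtype=float)
    f = np.clip(np.asarray(f_cover, dtype=float), 1e-6, 1.0)
    gap = f * np.exp(-kb_nadir * lai / f) + (1.0 - f)
    with np.errstate(divide="ignore", invalid="ignore"):
        omega = -np.log(gap) / (kb_nadir * lai)
    omega = np.where(lai > 1e-9, omega, 1.0)
    return np.clip(omega, 1e-3, 1.0)


def structural_params(lai_vine, structure: StructureConfig, lai_floor: float = 0.4):
    """Vine canopy height and width fraction from LAI.

    Piecewise-linear interpolation between the dormant (woody) and
    peak-season anchors, clipped to the configured bounds.
    """
    lai_vine = np.asarray(lai_vine, dtype=float)
    span = max(structure.lai_vine_max - lai_floor, 1e-9)
    frac = np.clip((lai_vine - lai_floor) / span, 0.0, 1.0)
    h_c = structure.hc_vine_min + (structure.hc_vine_max - structure.hc_vine_min) * frac
    w_c = structure.wc_vine_min + (structure.wc_vine_max - structure.wc_vine_min) * frac
    return h_c, w_c


def daily_canopy(lai_df: pd.DataFrame, pheno: PhenologyConfig,
                 structure: StructureConfig) -> pd.DataFrame:
    """Assemble the full daily canopy table from a LAI partition.

    Parameters
    ----------
    lai_df : output of :func:`partition_lai` (DatetimeIndex).
    pheno, structure : configuration blocks.

    Returns
    -------
    DataFrame with LAI, green fractions, structural parameters and
    clumping indices of both layers for every day.
    """
    doy = lai_df.index.dayofyear.to_numpy()
    out = lai_df.copy()
    out["fg_vine"] = green_fraction(doy, pheno, "vine")
    out["fg_cc"] = green_fraction(doy, pheno, "cc")
    h_c, w_c = structural_params(
        out["lai_vine"].to_numpy(), structure, pheno.lai_vine_floor
    )
    out["h_c_vine"] = h_c
    out["w_c_vine"] = w_c
    out["h_c_cc"] = structure.hc_cc
    out["w_c_cc"] = structure.wc_cc
    kb0 = beam_extinction_kb(0.0, structure.x_lad_vine)
    out["omega_vine"] = clumping_index(out["lai_vine"].to_numpy(), w_c, float(kb0))
    out["omega_cc"] = 1.0
    out["row_width"] = structure.row_width
    return out
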