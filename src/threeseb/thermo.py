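"""Moist-air thermodynamic helpers.

All functions are vectorized over numpy arrays.  Temperatures are in
kelvin, pressures and vapor pressures in kPa, energies in SI.
"""

from __future__ import annotations

import numpy as np

#: Stefan-Boltzmann constant (W m-2 K-4)
SIGMA = 5.670374419e-8
#: von Karman constant (-)
KARMAN = 0.41
#: gravitational acceleration (m s-2)
GRAVITY = 9.81
#: specific gas constant of dry air (J kg-1 K-1)
R_DRY = 287.04
#: specific heat of dry air at constant pressure (J kg-1 K-1)
CP_DRY = 1005.0
#: ratio of molecular weights water/dry air (-)
EPS_W = 0.622


def esat(t_k):
    """Saturation vapor pressure (kPa), Magnus form over water."""
    t_c = np.asarray(t_k, dtype=float) - 273.15
    return 0.61078 * np.exp(17.269 * t_c / (t_c + 237.3))


def delta_svp(t_k):
    """Slope of the saturation vapor pressure curve (kPa K-1)."""
    t_c = np.asarray(t_k, dtype=float) - 273.15
    return esat(t_k) * 17.269 * 237.3 / (t_c + 237.3) ** 2


def latent_heat(t_k):
    """Latent heat of vaporization of water (J kg-1), linear in T."""
    return 2.501e6 - 2361.0 * (np.asarray(t_k, dtype=float) - 273.15)


def psychrometric_gamma(p_kpa, t_k):
    """Psychrometric constant gamma = cp p / (eps lambda) (kPa K-1)."""
    return CP_DRY * np.asarray(p_kpa, dtype=float) / (EPS_W * latent_heat(t_k))


def air_density(t_k, p_kpa, e_kpa):
    """Moist-air density (kg m-3) from the ideal-gas law."""
    t_k = np.asarray(t_k, dtype=float)
    p = np.asarray(p_kpa, dtype=float) * 1000.0
    e = np.asarray(e_kpa, dtype=float) * 1000.0
    # partial pressures of dry air and vapor
    return (p - e) / (R_DRY * t_k) + e * EPS_W / (R_DRY * t_k)


def cp_moist(t_k, p_kpa, e_kpa):
    """Specific heat of moist air (J kg-1 K-1)."""
    q = EPS_W * np.asarray(e_kpa, dtype=float) / (
        np.asarray(p_kpa, dtype=float) - (1.0 - EPS_W) * np.asarray(e_kpa, dtype=float)
    )
    return CP_DRY * (1.0 + 0.84 * q)


def rho_cp(t_k, p_kpa, e_kpa):
    """Volumetric heat capacity of moist air rho*cp (J m-3 K-1)."""
    return air_density(t_k, p_kpa, e_kpa) * cp_moist(t_k, p_kpa, e_kpa)
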