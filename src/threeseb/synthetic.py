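"""Self-contained synthetic tower data.

Emulates the forcing of a semi-arid Central-Valley-style vineyard: a
clear-sky diurnal shortwave course, a lagged sinusoidal air
temperature with a seasonal cycle, near-constant humidity and wind
with instrument-scale noise, a two-season LAI climatology (spring
cover crop + summer vine), and - through :func:`forward_scene` - a
radiometric temperature and observed-flux record generated by the
model's own network equations for a prescribed flux partition, so that
the solvers can be tested by exact forward-inverse recovery.

What this generator does *not* emulate: cloud fields, synoptic
variability, advection from neighboring orchards, sensor drift or
energy-balance non-closure of real eddy-covariance towers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import thermo
from .canopy import (
    beam_extinction_kb,
    clumping_index,
    fraction_viewed,
    green_fraction,
    structural_params,
)
from .config import PhenologyConfig, SiteConfig
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
from .solar import sun_zenith, sunrise_sunset_hours
from .solvers import compose_trad, pt_canopy_flux
from .thermo import SIGMA


@dataclass
class SyntheticScenario:
    """Controls for one synthetic site-year."""

    seed: int = 0
    days: int = 365
    start: str = "2019-01-01"
    latitude: float = 36.85
    longitude: float = -120.2
    timezone: str = "Etc/GMT+8"
    sw_amplitude: float = 950.0       # W m-2, clear-sky solar-noon peak
    t_mean: float = 290.0             # K, annual mean air temperature
    t_seasonal_amp: float = 9.0       # K, seasonal half-range
    t_diurnal_amp: float = 7.0        # K, diurnal half-range
    e_a_mean: float = 1.0             # kPa
    u_mean: float = 2.5               # m s-1
    p_surface: float = 100.6          # kPa
    alpha_ov: float = 1.26            # prescribed PT coefficient, vine
    alpha_un: float = 1.26            # prescribed PT coefficient, cover crop
    soil_le_fraction: float = 0.3     # LE_soil / (Rn_soil - G)
    t_rad_noise_sd: float = 0.0       # K (0.5 is the nominal instrument scale)
    u_noise_sd: float = 0.3           # m s-1
    e_a_noise_sd: float = 0.05        # kPa
    lai_noise_sd: float = 0.10        # multiplicative, daily LAI
    lai_vine_peak: float = 2.0        # m2 m-2, truth vine LAI maximum
    lai_cc_peak: float = 0.8          # m2 m-2, truth CC LAI at bud-break
    lai_cc_winter: float = 0.6        # m2 m-2, truth CC winter plateau
    cc_present: bool = True
    phenology: PhenologyConfig = field(default_factory=PhenologyConfig)

    def __post_init__(self):
        if not 0.0 <= self.soil_le_fraction <= 1.0:
            raise ValueError("soil_le_fraction must lie in [0, 1]")
        if self.alpha_ov < 0 or self.alpha_un < 0:
            raise ValueError("prescribed alpha values must be >= 0")
        self.phenology = replace(self.phenology, cc_present=self.cc_present)

    def to_site_config(self) -> SiteConfig:
        cfg = SiteConfig(latitude=self.latitude, longitude=self.longitude)
        cfg.phenology = self.phenology
        return cfg


def _utc_hours(times: pd.DatetimeIndex):
    utc = times.tz_convert("UTC")
    hour = (
        utc.hour.to_numpy(dtype=float)
        + utc.minute.to_numpy(dtype=float) / 60.0
    )
    return utc.dayofyear.to_numpy(dtype=float), hour


def generate_met(scenario: SyntheticScenario) -> pd.DataFrame:
    """Hourly meteorological forcing for the scenario.

    Shortwave follows a half-sine between sunrise and sunset peaking at
    ``sw_amplitude`` at solar noon; air temperature combines a seasonal
    cosine with a diurnal cosine lagged two hours behind solar noon;
    humidity and wind are constant with Gaussian instrument noise; and
    incoming longwave uses the Brutsaert clear-sky emissivity.
    """
    rng = np.random.default_rng(scenario.seed)
    times = pd.date_range(
        scenario.start, periods=scenario.days * 24, freq="h", tz=scenario.timezone
    )
    doy_utc, hour_utc = _utc_hours(times)

    sw = np.zeros(len(times))
    for shift in (0.0, 1.0):  # sun windows can straddle the UTC midnight
        d = doy_utc - shift
        h = hour_utc + 24.0 * shift
        rise, sset, _ = sunrise_sunset_hours(d, scenario.latitude, scenario.longitude)
        inside = (h > rise) & (h < sset)
        phase = np.pi * (h - rise) / np.maximum(sset - rise, 1e-6)
        sw = np.maximum(sw, np.where(inside, scenario.sw_amplitude * np.sin(phase), 0.0))

    local_hour = (
        times.hour.to_numpy(dtype=float) + times.minute.to_numpy(dtype=float) / 60.0
    )
    doy_local = times.dayofyear.to_numpy(dtype=float)
    t_a = (
        scenario.t_mean
        - scenario.t_seasonal_amp * np.cos(2.0 * np.pi * (doy_local - 200.0) / 365.0)
        - scenario.t_diurnal_amp * np.cos(2.0 * np.pi * (local_hour - 14.0) / 24.0)
    )

    e_a = scenario.e_a_mean + rng.normal(0.0, scenario.e_a_noise_sd, len(times))
    e_a = np.clip(e_a, 0.2, 0.95 * thermo.esat(t_a))
    u = np.clip(
        scenario.u_mean + rng.normal(0.0, scenario.u_noise_sd, len(times)), 0.3, None
    )
    p = np.full(len(times), scenario.p_surface)

    # Brutsaert clear-sky emissivity (vapor pressure in hPa)
    eps_sky = 1.24 * (10.0 * e_a / t_a) ** (1.0 / 7.0)
    l_in = np.clip(eps_sky, None, 1.0) * SIGMA * t_a ** 4

    return pd.DataFrame(
        {
            "timestamp": times,
            "sw_in": sw,
            "t_a": t_a,
            "e_a": e_a,
            "u": u,
            "p": p,
            "l_in": l_in,
            "l_out": np.nan,
        }
    )


def generate_lai_season(scenario: SyntheticScenario) -> pd.DataFrame:
    """Daily ecosystem LAI with the vine/cover-crop ground truth.

    The vine rises logistically after bud-break and senesces shortly
    before leaf-off; the cover crop holds a winter plateau, peaks at
    bud-break, decays exponentially (the same e-folding time the
    partitioning assumes) and regrows after leaf-off.  The published
    ecosystem series is the noisy sum of the two truths.
    """
    rng = np.random.default_rng(scenario.seed + 101)
    ph = scenario.phenology
    dates = pd.date_range(scenario.start, periods=scenario.days, freq="1D")
    doy = dates.dayofyear.to_numpy(dtype=float)

    rise = 1.0 / (1.0 + np.exp(-(doy - (ph.budbreak_doy + 20.0)) / 7.0))
    fall = 1.0 / (1.0 + np.exp((doy - (ph.leafoff_doy - 15.0)) / 6.0))
    lai_vine = scenario.lai_vine_peak * rise * fall

    if scenario.cc_present:
        tau = ph.decay_efolding_days
        spring = scenario.lai_cc_winter + (
            scenario.lai_cc_peak - scenario.lai_cc_winter
        ) / (1.0 + np.exp(-(doy - (ph.budbreak_doy - 30.0)) / 10.0))
        decay = scenario.lai_cc_peak * np.exp(-(doy - ph.budbreak_doy) / tau)
        regrow = scenario.lai_cc_winter * (
            1.0 - np.exp(-(doy - ph.leafoff_doy) / tau)
        )
        lai_cc = np.where(
            doy < ph.budbreak_doy, spring, np.where(doy <= ph.leafoff_doy, decay, regrow)
        )
    else:
        lai_cc = np.zeros_like(doy)

    lai_eco = (lai_vine + lai_cc) * np.clip(
        1.0 + rng.normal(0.0, scenario.lai_noise_sd, len(doy)), 0.5, 1.5
    )
    return pd.DataFrame(
        {"lai_eco": lai_eco, "lai_vine": lai_vine, "lai_cc": lai_cc}, index=dates
    )


def truth_canopy(lai_truth: pd.DataFrame, config: SiteConfig) -> pd.DataFrame:
    """Daily canopy table built from the ground-truth LAI components."""
    ph, st = config.phenology, config.structure
    doy = lai_truth.index.dayofyear.to_numpy()
    out = lai_truth.copy()
    out["lai_vine"] = np.maximum(out["lai_vine"], ph.lai_vine_floor)
    out["fg_vine"] = green_fraction(doy, ph, "vine")
    out["fg_cc"] = green_fraction(doy, ph, "cc")
    h_c, w_c = structural_params(out["lai_vine"].to_numpy(), st, ph.lai_vine_floor)
    out["h_c_vine"] = h_c
    out["w_c_vine"] = w_c
    out["h_c_cc"] = st.hc_cc
    out["w_c_cc"] = st.wc_cc
    kb0 = float(beam_extinction_kb(0.0, st.x_lad_vine))
    out["omega_vine"] = clumping_index(out["lai_vine"].to_numpy(), w_c, kb0)
    out["omega_cc"] = 1.0
    out["row_width"] = st.row_width
    return out


def forward_scene(met: pd.DataFrame, canopy: pd.DataFrame,
                  scenario: SyntheticScenario, config: SiteConfig = None,
                  max_iter: int = 120, tol: float = 1.0e-7) -> pd.DataFrame:
    """Component temperatures and T_rad consistent with a prescribed
    flux partition.

    Runs the model's network equations forward: Priestley-Taylor
    canopy fluxes at the prescribed alpha values, a prescribed soil
    evaporative fraction, component temperatures from the resistance
    equations, and the radiometric composition of T_rad.  By
    construction the solvers recover the prescription on a noiseless
    scene.  Night-time rows are isothermal at air temperature with
    zero turbulent fluxes.

    Returns a frame aligned with ``met`` carrying ``t_rad`` (with
    optional Gaussian noise of SD ``scenario.t_rad_noise_sd``),
    ``l_out``, the observed-flux columns and the ``*_true`` component
    truth.
    """
    config = config or scenario.to_site_config()
    rc, sc = config.resistance, config.solver
    st = config.structure
    rng = np.random.default_rng(scenario.seed + 202)

    times = pd.DatetimeIndex(met["timestamp"])
    theta = np.minimum(
        sun_zenith(times, config.latitude, config.longitude), np.pi / 2 - 1e-6
    )
    sw = met["sw_in"].to_numpy(dtype=float)
    day = sw > 50.0  # generate scenes for all lit hours; solver gates at 100

    t_a = met["t_a"].to_numpy(dtype=float)
    e_a = met["e_a"].to_numpy(dtype=float)
    u = met["u"].to_numpy(dtype=float)
    p = met["p"].to_numpy(dtype=float)
    l_in = met["l_in"].to_numpy(dtype=float)
    doy = times.dayofyear.to_numpy(dtype=float)

    rho_cp = thermo.rho_cp(t_a, p, e_a)
    delta = thermo.delta_svp(t_a)
    gamma = thermo.psychrometric_gamma(p, t_a)

    lai_ov = canopy["lai_vine"].to_numpy(dtype=float)
    lai_un = canopy["lai_cc"].to_numpy(dtype=float)
    fg_ov = canopy["fg_vine"].to_numpy(dtype=float)
    fg_un = canopy["fg_cc"].to_numpy(dtype=float)
    om_ov = canopy["omega_vine"].to_numpy(dtype=float)
    om_un = canopy["omega_cc"].to_numpy(dtype=float)
    h_c_ov = canopy["h_c_vine"].to_numpy(dtype=float)
    h_c_un = canopy["h_c_cc"].to_numpy(dtype=float)

    kb0_ov = float(beam_extinction_kb(0.0, st.x_lad_vine))
    kb0_un = float(beam_extinction_kb(0.0, st.x_lad_cc))
    f_ov = np.clip(fraction_viewed(lai_ov, om_ov, kb0_ov), 0.0, 0.99)
    f_un = np.clip(fraction_viewed(lai_un, om_un, kb0_un), 0.0, 0.99)

    t_ov = t_a.copy()
    t_un = t_a.copy()
    t_soil = t_a.copy()
    t_sub = t_a.copy()
    t_ac = t_a.copy()
    l_mo = np.full(len(t_a), L_NEUTRAL)
    d, z0m, z0h = roughness(h_c_ov, rc)

    t_rad = t_a.copy()
    state = {}
    for _ in range(max_iter):
        budget = net_radiation_three_source(
            sw, l_in, theta, doy,
            lai_ov, om_ov, st.x_lad_vine,
            lai_un, om_un, st.x_lad_cc,
            t_ov, t_un, t_soil, config.optics,
        )
        g = soil_heat_flux(budget.rn_soil, "ratio", ratio=sc.g_ratio)
        le_ov, h_ov = pt_canopy_flux(budget.rn_ov, fg_ov, scenario.alpha_ov, delta, gamma)
        le_un, h_un = pt_canopy_flux(budget.rn_un, fg_un, scenario.alpha_un, delta, gamma)
        avail_soil = budget.rn_soil - g
        le_soil = scenario.soil_le_fraction * np.maximum(avail_soil, 0.0)
        h_soil = avail_soil - le_soil

        u_star = friction_velocity(u, config.z_u, d, z0m, l_mo, rc)
        stab = StabilityState(l_mo=l_mo, u_star=u_star, d=d, z0m=z0m, z0h=z0h)
        r_a = aerodynamic_resistance(u, config.z_u, config.z_t, stab, rc)
        r_x, r_s, r_sub = boundary_resistances(
            stab, h_c_ov, lai_ov, st.leaf_width_vine,
            h_c_un, lai_un, st.leaf_width_cc,
            t_sub - t_a, t_soil - t_ac, rc,
        )

        t_prev = np.stack([t_ov, t_un, t_soil, t_ac])

        t_ov_cand = np.clip(t_a + h_ov * r_a / rho_cp, t_a - 60.0, t_a + 80.0)
        t_ov = np.where(day, 0.5 * t_ov_cand + 0.5 * t_ov, t_a)
        delta_un = np.clip(np.where(day, h_un * r_x / rho_cp, 0.0), -60.0, 80.0)

        # Implicit linearized soil-temperature update.  The prescribed
        # soil flux couples to T_soil through the soil's own emission
        # (d Rn_soil / d T_soil = -4 eps sigma T^3), which at large R_s
        # makes a naive fixed point violently unstable; treating that
        # term implicitly is unconditionally stable and leaves the
        # converged state exactly on the resistance equation.
        f_eff = np.where(avail_soil > 0, 1.0 - scenario.soil_le_fraction, 1.0)
        k_s = r_s / rho_cp * (1.0 - sc.g_ratio) * f_eff
        c4 = 4.0 * config.optics.emiss_soil * SIGMA * t_soil ** 3
        rn0 = budget.rn_soil
        t_soil_cand = (t_ac + k_s * (rn0 + c4 * t_soil)) / (1.0 + k_s * c4)
        t_soil_cand = np.clip(t_soil_cand, t_a - 60.0, t_a + 80.0)
        t_soil = np.where(day, 0.7 * t_soil_cand + 0.3 * t_soil, t_a)

        t_un = np.where(day, 0.5 * (t_ac + delta_un) + 0.5 * t_un, t_a)
        t_sub = np.where(day, compose_trad(f_un, t_un, t_soil), t_a)
        ratio = np.clip(r_a / (r_a + r_sub), 0.0, 0.995)
        t_ac_cand = t_a + ratio * (t_sub - t_a)
        t_ac = np.where(day, 0.5 * t_ac_cand + 0.5 * t_ac, t_a)

        h_total = np.where(day, h_ov + h_un + h_soil, 0.0)
        l_mo = obukhov_length(u_star, t_a, rho_cp, h_total, rc)

        t_rad = np.where(day, compose_trad(f_ov, t_ov, t_sub), t_a)
        state = dict(budget=budget, g=g, le_ov=le_ov, h_ov=h_ov,
                     le_un=le_un, h_un=h_un, le_soil=le_soil, h_soil=h_soil)
        dt_max = np.max(np.abs(np.stack([t_ov, t_un, t_soil, t_ac]) - t_prev))
        if dt_max < tol:
            break

    if np.any(t_soil <= 0) or np.any(t_ov <= 0):
        raise ValueError("prescription requires a non-physical (<= 0 K) temperature")

    budget, g = state["budget"], state["g"]
    zero = np.zeros_like(t_a)
    out = pd.DataFrame({"timestamp": met["timestamp"].to_numpy()})
    noisy = t_rad + rng.normal(0.0, scenario.t_rad_noise_sd, len(t_a)) \
        if scenario.t_rad_noise_sd > 0 else t_rad
    out["t_rad"] = noisy
    out["t_rad_true"] = t_rad
    out["l_out"] = SIGMA * noisy ** 4

    le_tot = np.where(day, state["le_ov"] + state["le_un"] + state["le_soil"], 0.0)
    h_tot = np.where(day, state["h_ov"] + state["h_un"] + state["h_soil"], 0.0)
    out["rn_obs"] = np.where(day, budget.rn_total, 0.0)
    out["g_obs"] = np.where(day, g, 0.0)
    out["h_obs"] = h_tot
    out["le_obs"] = le_tot

    for name, arr in (
        ("le_ov", state["le_ov"]), ("le_un", state["le_un"]),
        ("le_soil", state["le_soil"]), ("h_ov", state["h_ov"]),
        ("h_un", state["h_un"]), ("h_soil", state["h_soil"]),
        ("rn_ov", budget.rn_ov), ("rn_un", budget.rn_un),
        ("rn_soil", budget.rn_soil), ("g", g),
        ("t_ov", t_ov), ("t_un", t_un), ("t_soil", t_soil),
        ("t_sub", t_sub), ("t_ac", t_ac),
    ):
        out[name + "_true"] = np.where(day, arr, zero if name.startswith(("le", "h", "rn", "g")) else arr)
    out["daytime_scene"] = day
    return out


def generate_dataset(scenario: SyntheticScenario, config: SiteConfig = None):
    """One-call synthetic site-year: met, daily canopy truth, scene.

    Returns (met frame with l_out and observed fluxes filled in,
    daily canopy table, forward-scene truth frame).
    """
    from .pipeline import align_canopy

    config = config or scenario.to_site_config()
    met = generate_met(scenario)
    lai = generate_lai_season(scenario)
    canopy_daily = truth_canopy(lai, config)
    canopy_hourly = align_canopy(canopy_daily, met["timestamp"])
    scene = forward_scene(met, canopy_hourly, scenario, config)
    met = met.copy()
    met["l_out"] = scene["l_out"].to_numpy()
    for col in ("rn_obs", "g_obs", "h_obs", "le_obs"):
        met[col] = scene[col].to_numpy()
    return met, canopy_daily, scene
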