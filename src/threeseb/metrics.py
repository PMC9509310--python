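"""Flux evaluation statistics and T/ET partition aggregation.

``compute_metrics`` implements the four standard model-evaluation
statistics (RMSD, mean bias, Nash-Sutcliffe efficiency, Pearson r)
over a masked window with pairwise deletion of missing values.
``partition_series`` turns a solved flux table into daily, seasonal
and annual transpiration/evapotranspiration partitions, and
``volumetric_et`` converts latent heat into water depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .thermo import latent_heat

#: seasonal day-of-year breakpoints: winter/spring/summer-fall/leaf-off
SEASON_BREAKS = (90, 150, 330)
SEASON_LABELS = ("winter_to_budbreak", "spring", "summer_to_fall", "leafoff")


@dataclass
class EvalStats:
    """RMSD, bias (model - observed), NSE and Pearson r over n pairs."""

    rmsd: float
    bias: float
    nse: float
    r: float
    n: int


def compute_metrics(model, observed, mask=None) -> EvalStats:
    """Evaluate a modeled series against observations.

    Pairs where either side is missing are dropped; with a constant
    observed series NSE and r are undefined and reported as NaN.
    Requires at least two valid pairs.
    """
    model = np.asarray(model, dtype=float)
    observed = np.asarray(observed, dtype=float)
    valid = np.isfinite(model) & np.isfinite(observed)
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool)
    m = model[valid]
    o = observed[valid]
    if len(m) < 2:
        raise ValueError("need at least two paired values")
    err = m - o
    rmsd = float(np.sqrt(np.mean(err ** 2)))
    bias = float(np.mean(err))
    ss_obs = float(np.sum((o - o.mean()) ** 2))
    if ss_obs == 0.0:
        nse = np.nan
        r = np.nan
    else:
        nse = 1.0 - float(np.sum(err ** 2)) / ss_obs
        sm = m.std()
        r = (
            float(np.mean((m - m.mean()) * (o - o.mean())) / (sm * o.std()))
            if sm > 0
            else np.nan
        )
    return EvalStats(rmsd=rmsd, bias=bias, nse=nse, r=r, n=int(len(m)))


def season_of_doy(doy):
    """Map day of year onto the fixed seasonal windows."""
    doy = np.asarray(doy)
    return np.select(
        [
            doy <= SEASON_BREAKS[0],
            doy <= SEASON_BREAKS[1],
            doy <= SEASON_BREAKS[2],
        ],
        SEASON_LABELS[:3],
        default=SEASON_LABELS[3],
    )


def partition_series(fluxes: pd.DataFrame, timestamps, mask=None,
                     breaks=SEASON_BREAKS) -> dict:
    """Aggregate solved fluxes into T/ET partitioning series.

    Parameters
    ----------
    fluxes : frame with ``le_ov``, ``le_un``, ``le_soil`` columns
        (overstory/understory transpiration and soil evaporation).
    timestamps : aligned DatetimeIndex-convertible.
    mask : optional boolean selector (e.g. the daytime mask).

    Returns
    -------
    dict with
    ``daily`` : per-day daytime-mean component fluxes (W m-2), the
        component fractions of ET and T/ET (ratio of daily sums);
    ``seasonal`` : the same ratios aggregated over the DOY windows;
    ``annual_t_et_mean`` / ``annual_t_et_sd`` : equal-day-weighted
        annual statistics of daily T/ET.
    """
    times = pd.DatetimeIndex(timestamps)
    sel = np.ones(len(times), dtype=bool)
    if mask is not None:
        sel &= np.asarray(mask, dtype=bool)
    sel &= np.isfinite(fluxes["le_ov"].to_numpy(dtype=float))

    df = pd.DataFrame(
        {
            "t_vine": fluxes["le_ov"].to_numpy(dtype=float),
            "t_cc": fluxes["le_un"].to_numpy(dtype=float),
            "e_soil": fluxes["le_soil"].to_numpy(dtype=float),
        },
        index=times,
    )[sel]

    daily = df.resample("1D").agg(["mean", "sum", "count"])
    counts = daily[("t_vine", "count")]
    daily = daily[counts > 0]
    out = pd.DataFrame(
        {
            "t_vine": daily[("t_vine", "mean")],
            "t_cc": daily[("t_cc", "mean")],
            "e_soil": daily[("e_soil", "mean")],
        }
    )
    out["et"] = out["t_vine"] + out["t_cc"] + out["e_soil"]
    sums = (
        daily[("t_vine", "sum")] + daily[("t_cc", "sum")] + daily[("e_soil", "sum")]
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        out["t_et"] = np.where(
            sums != 0,
            (daily[("t_vine", "sum")] + daily[("t_cc", "sum")]) / sums,
            np.nan,
        )
        for comp in ("t_vine", "t_cc", "e_soil"):
            out[f"frac_{comp}"] = np.where(
                sums != 0, daily[(comp, "sum")] / sums, np.nan
            )

    doy = out.index.dayofyear
    out["season"] = season_of_doy(doy)
    seasonal = out.groupby("season", sort=False).agg(
        t_vine=("t_vine", "mean"),
        t_cc=("t_cc", "mean"),
        e_soil=("e_soil", "mean"),
        et=("et", "mean"),
        t_et=("t_et", "mean"),
        n_days=("t_et", "count"),
    )

    t_et = out["t_et"].dropna()
    return {
        "daily": out,
        "seasonal": seasonal,
        "annual_t_et_mean": float(t_et.mean()) if len(t_et) else np.nan,
        "annual_t_et_sd": float(t_et.std()) if len(t_et) > 1 else np.nan,
    }


def evaluation_table(models: dict, observed: pd.DataFrame, timestamps,
                     mask=None) -> pd.DataFrame:
    """Seasonal evaluation statistics, one row per season/flux/model.

    Parameters
    ----------
    models : mapping of model name to a flux frame carrying ``rn``
        (or per-source columns summed beforehand), ``g``, ``h``, ``le``
        columns named ``rn_mod``/``g_mod``/``h_mod``/``le_mod`` or the
        solver output (summed automatically).
    observed : frame with ``rn_obs``, ``g_obs``, ``h_obs``, ``le_obs``.
    timestamps, mask : time axis and record selector.

    Returns
    -------
    Long-format DataFrame with columns season, flux, model, rmsd,
    bias, nse, r, n — the layout used for seasonal model comparison
    tables.  Seasons with fewer than two valid pairs are skipped.
    """
    times = pd.DatetimeIndex(timestamps)
    doy = times.dayofyear.to_numpy()
    seasons = season_of_doy(doy)
    sel = np.ones(len(times), dtype=bool)
    if mask is not None:
        sel &= np.asarray(mask, dtype=bool)

    rows = []
    windows = [(label, seasons == label) for label in SEASON_LABELS]
    windows.append(("all_seasons", np.ones(len(times), dtype=bool)))
    for name, fluxes in models.items():
        series = {
            "LE": fluxes[["le_ov", "le_un", "le_soil"]].sum(axis=1).to_numpy(),
            "H": fluxes[["h_ov", "h_un", "h_soil"]].sum(axis=1).to_numpy(),
            "Rn": fluxes[["rn_ov", "rn_un", "rn_soil"]].sum(axis=1).to_numpy(),
            "G": fluxes["g"].to_numpy(),
        }
        obs = {
            "LE": observed["le_obs"].to_numpy(dtype=float),
            "H": observed["h_obs"].to_numpy(dtype=float),
            "Rn": observed["rn_obs"].to_numpy(dtype=float),
            "G": observed["g_obs"].to_numpy(dtype=float),
        }
        for season, in_window in windows:
            for flux in ("LE", "H", "Rn", "G"):
                window = sel & in_window
                valid = window & np.isfinite(series[flux]) & np.isfinite(obs[flux])
                if valid.sum() < 2:
                    continue
                s = compute_metrics(series[flux], obs[flux], mask=window)
                rows.append(
                    dict(season=season, flux=flux, model=name, rmsd=s.rmsd,
                         bias=s.bias, nse=s.nse, r=s.r, n=s.n)
                )
    return pd.DataFrame(rows)


def volumetric_et(le, timestamps, t_a: Optional[np.ndarray] = None) -> float:
    """Integrate a latent heat series into water depth (mm).

    depth = sum(LE dt / lambda(T_A)); missing values (night-time rows)
    contribute zero flux.  ``t_a`` defaults to 293.15 K for the latent
    heat of vaporization if no air temperature series is given.
    """
    le = np.asarray(le, dtype=float)
    times = pd.DatetimeIndex(timestamps)
    if len(times) < 2:
        raise ValueError("need at least two timestamps to infer the time step")
    steps = np.diff(times.asi8) / 1e9
    dt = np.median(steps)
    lam = latent_heat(t_a if t_a is not None else 293.15)
    flux = np.where(np.isfinite(le), le, 0.0)
    return float(np.sum(flux * dt / lam))
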