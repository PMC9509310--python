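"""High-level pipeline: forcing + daily LAI + configuration -> fluxes.

Glues the modules together the way the command-line interface uses
them: radiometric temperature retrieval from the longwave record, LAI
decomposition, canopy assembly, and the chosen energy-balance solver.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .canopy import daily_canopy, partition_lai
from .config import SiteConfig
from .forcing_io import retrieve_trad
from .solvers import solve_3seb, solve_tseb


def align_canopy(canopy_daily: pd.DataFrame, timestamps) -> pd.DataFrame:
    """Broadcast a daily canopy table onto (sub-)hourly timestamps."""
    times = pd.DatetimeIndex(timestamps)
    dates = pd.DatetimeIndex(times.tz_localize(None).normalize())
    daily = canopy_daily.copy()
    daily.index = pd.DatetimeIndex(daily.index).normalize()
    aligned = daily.reindex(dates, method="nearest")
    aligned.index = pd.RangeIndex(len(aligned))
    return aligned


def run_model(
    met: pd.DataFrame,
    lai_eco: pd.Series,
    config: SiteConfig,
    model: str = "3seb",
    g_mode: str = "ratio",
) -> pd.DataFrame:
    """Run 3SEB or the TSEB baseline over a tower time series.

    Parameters
    ----------
    met : canonical met frame; must carry ``l_out`` (and ``l_in`` when
        the retrieval emissivity is below one) for the T_rad retrieval.
    lai_eco : daily ecosystem LAI with a DatetimeIndex.
    config : site configuration.
    model : ``"3seb"`` or ``"tseb"``.
    g_mode : ``"ratio"`` or ``"observed"``.

    Returns
    -------
    Flux frame (see :func:`threeseb.solvers.solve_3seb`) with the
    timestamp column prepended.
    """
    l_out = met["l_out"].to_numpy(dtype=float)
    l_in = met["l_in"].to_numpy(dtype=float)
    have = np.isfinite(l_out)
    t_rad = np.full(len(met), np.nan)
    if have.any():
        t_rad[have] = retrieve_trad(
            l_in[have], l_out[have], config.optics.emiss_trad
        )

    lai_df = partition_lai(lai_eco, config.phenology)
    canopy_d = daily_canopy(lai_df, config.phenology, config.structure)
    canopy_h = align_canopy(canopy_d, met["timestamp"])

    solver = {"3seb": solve_3seb, "tseb": solve_tseb}.get(model)
    if solver is None:
        raise ValueError(f"unknown model '{model}'")
    fluxes = solver(met, t_rad, canopy_h, config, g_mode=g_mode)
    fluxes.insert(0, "timestamp", met["timestamp"].to_numpy())
    return fluxes
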