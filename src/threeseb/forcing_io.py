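"""Tower forcing I/O, radiometric temperature retrieval, daytime mask,
and the energy-balance closure ensemble.

Time series are carried as :class:`pandas.DataFrame` with canonical
column names (below); :class:`MetRecord` / :class:`ObsFluxRecord` are
the validated per-timestamp views used on the read path.

Canonical met columns
    ``timestamp`` (tz-aware), ``sw_in``, ``l_in``, ``l_out`` [W m-2],
    ``t_a`` [K], ``e_a`` [kPa], ``u`` [m s-1], ``p`` [kPa]
Canonical observed-flux columns (optional, missing-aware)
    ``rn_obs``, ``g_obs``, ``h_obs``, ``le_obs`` [W m-2]

Missing values are encoded as NaN throughout; nothing is imputed.
Timestamps mark the end of the averaging interval (tower convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import datetime
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .thermo import SIGMA

logger = logging.getLogger(__name__)

#: columns a met file must provide
MANDATORY_COLUMNS = ("timestamp", "sw_in", "t_a", "e_a", "u", "p")
#: recognized optional columns
OPTIONAL_COLUMNS = ("l_in", "l_out", "rn_obs", "g_obs", "h_obs", "le_obs")

#: strict daytime threshold on shortwave irradiance (W m-2)
DAYTIME_SW_THRESHOLD = 100.0


@dataclass
class MetRecord:
    """One timestamp of meteorological forcing."""

    timestamp: datetime
    sw_in: float
    t_a: float
    e_a: float
    u: float
    p: float
    l_in: float = np.nan
    l_out: float = np.nan
    z_t: float = 5.0
    z_u: float = 5.0

    def __post_init__(self):
        if self.timestamp.tzinfo is None:
            raise ValueError("MetRecord timestamp must be timezone-aware")
        if np.isfinite(self.sw_in) and self.sw_in < 0:
            raise ValueError(f"sw_in must be >= 0, got {self.sw_in}")
        if np.isfinite(self.u) and self.u < 0:
            raise ValueError(f"u must be >= 0, got {self.u}")
        if np.isfinite(self.t_a) and not 180.0 < self.t_a < 340.0:
            raise ValueError(f"t_a={self.t_a} K outside plausible range (180, 340)")
        if np.isfinite(self.e_a) and self.e_a < 0:
            raise ValueError(f"e_a must be >= 0, got {self.e_a}")
        if self.z_t <= 0 or self.z_u <= 0:
            raise ValueError("measurement heights must be positive")


@dataclass
class ObsFluxRecord:
    """Observed surface fluxes at one timestamp (any may be missing)."""

    timestamp: datetime
    rn: float = np.nan
    g: float = np.nan
    h: float = np.nan
    le: float = np.nan


def load_schema(path) -> dict:
    """Read a YAML column map {canonical name: file column name}."""
    with open(path) as fh:
        schema = yaml.safe_load(fh)
    if not isinstance(schema, dict):
        raise ValueError("schema file must contain a mapping")
    return schema


def read_timeseries(path, schema: Optional[dict] = None) -> pd.DataFrame:
    """Read a delimited tower file into the canonical frame.

    Parameters
    ----------
    path : str or Path
        CSV file with a header row and parseable timestamps.
    schema : dict, optional
        Map from canonical column names to the file's column names.
        Identity mapping by default.

    Returns
    -------
    DataFrame indexed 0..n-1 with canonical columns in time order.
    Gaps stay as NaN; nothing is interpolated.

    Raises
    ------
    ValueError
        On a missing mandatory column (named in the message), an
        unparseable timestamp, or duplicate/non-increasing timestamps
        (the offending timestamps are listed).
    """
    raw = pd.read_csv(path)
    schema = schema or {}
    rename = {v: k for k, v in schema.items()}
    raw = raw.rename(columns=rename)

    for col in MANDATORY_COLUMNS:
        if col not in raw.columns:
            raise ValueError(f"mandatory column '{col}' missing from {path}")

    try:
        stamps = pd.to_datetime(raw["timestamp"], utc=False, format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"unparseable timestamp in {path}: {exc}") from exc
    if stamps.dt.tz is None:
        # interpret naive timestamps as UTC rather than guessing a zone
        stamps = stamps.dt.tz_localize("UTC")

    dup = stamps[stamps.duplicated()]
    if len(dup):
        raise ValueError(
            "duplicate timestamps: " + ", ".join(str(t) for t in dup.unique()[:5])
        )
    if not stamps.is_monotonic_increasing:
        bad = stamps[stamps.diff() < pd.Timedelta(0)]
        raise ValueError(
            "timestamps not strictly increasing at: "
            + ", ".join(str(t) for t in bad[:5])
        )

    out = pd.DataFrame({"timestamp": stamps})
    for col in MANDATORY_COLUMNS[1:] + OPTIONAL_COLUMNS:
        if col in raw.columns:
            out[col] = pd.to_numeric(raw[col], errors="coerce").astype(float)
        elif col in OPTIONAL_COLUMNS:
            out[col] = np.nan
    return out


def write_timeseries(frame: pd.DataFrame, path) -> None:
    """Write a canonical frame as CSV with ISO-8601 timestamps."""
    out = frame.copy()
    out["timestamp"] = pd.DatetimeIndex(out["timestamp"]).map(
        lambda t: t.isoformat()
    )
    out.to_csv(path, index=False)


def retrieve_trad(l_in, l_out, emissivity: float = 1.0):
    """Radiometric surface temperature from longwave radiation (K).

    T_rad = [(L_out - (1 - eps) L_in) / (eps sigma)]^(1/4).  With the
    default blackbody emissivity the incoming term drops out.
    """
    if not 0.9 <= emissivity <= 1.0:
        raise ValueError(f"emissivity {emissivity} outside [0.9, 1]")
    l_in = np.asarray(l_in, dtype=float)
    l_out = np.asarray(l_out, dtype=float)
    if np.any(l_out[np.isfinite(l_out)] <= 0):
        raise ValueError("l_out must be positive")
    radicand = (l_out - (1.0 - emissivity) * l_in) / (emissivity * SIGMA)
    if np.any(radicand[np.isfinite(radicand)] <= 0):
        raise ValueError("non-positive radicand: physically inconsistent radiometry")
    return radicand ** 0.25


def emit_lout(t_rad, l_in=0.0, emissivity: float = 1.0):
    """Forward of :func:`retrieve_trad`: outgoing longwave from T_rad."""
    t_rad = np.asarray(t_rad, dtype=float)
    return emissivity * SIGMA * t_rad ** 4 + (1.0 - emissivity) * np.asarray(
        l_in, dtype=float
    )


def daytime_mask(sw_in) -> np.ndarray:
    """True where shortwave irradiance strictly exceeds 100 W m-2."""
    sw = np.asarray(sw_in, dtype=float)
    return (sw > DAYTIME_SW_THRESHOLD) & np.isfinite(sw)


def closure_ensemble(h_obs, le_obs, rn_obs, g_obs, bowen_guard: float = 0.05):
    """Reference turbulent fluxes from the three-way closure ensemble.

    Per timestamp the three corrections are

    1. unclosed: (H, LE) as measured;
    2. residual-to-LE: LE2 = Rn - G - H, H2 = H;
    3. Bowen-ratio: with beta = H/LE, H3 = beta (Rn - G) / (1 + beta),
       LE3 = (Rn - G) / (1 + beta), which closes the balance and
       preserves beta exactly.

    Returns the arithmetic mean of the available methods' H and LE.
    Method 3 is skipped (and logged) where LE = 0 or |1 + beta| <
    ``bowen_guard``; timestamps with any of the four inputs missing
    return NaN.
    """
    h = np.asarray(h_obs, dtype=float)
    le = np.asarray(le_obs, dtype=float)
    rn = np.asarray(rn_obs, dtype=float)
    g = np.asarray(g_obs, dtype=float)
    avail = rn - g

    valid = np.isfinite(h) & np.isfinite(le) & np.isfinite(rn) & np.isfinite(g)

    h2, le2 = h, avail - h

    with np.errstate(divide="ignore", invalid="ignore"):
        beta = h / le
        denom = 1.0 + beta
        bowen_ok = valid & (le != 0.0) & (np.abs(denom) >= bowen_guard)
        h3 = np.where(bowen_ok, beta * avail / denom, np.nan)
        le3 = np.where(bowen_ok, avail / denom, np.nan)

    n_skipped = int(np.sum(valid & ~bowen_ok))
    if n_skipped:
        logger.info(
            "closure_ensemble: Bowen-ratio method skipped at %d timestamps "
            "(LE = 0 or beta near -1)",
            n_skipped,
        )

    n_methods = np.where(bowen_ok, 3.0, 2.0)
    h_ref = np.where(
        valid,
        (h + h2 + np.where(bowen_ok, h3, 0.0)) / n_methods,
        np.nan,
    )
    le_ref = np.where(
        valid,
        (le + le2 + np.where(bowen_ok, le3, 0.0)) / n_methods,
        np.nan,
    )
    return h_ref, le_ref
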