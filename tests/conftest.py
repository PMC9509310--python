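import numpy as np
import pandas as pd
import pytest

from threeseb import SiteConfig, SyntheticScenario, align_canopy, generate_dataset


@pytest.fixture(scope="session")
def summer_scene():
    """One noiseless synthetic month in mid-season, with solved inputs.

    Returns (scenario, met, daily canopy, hourly canopy, truth scene,
    site config) shared across solver/synthetic tests.
    """
    scenario = SyntheticScenario(seed=42, days=30, start="2019-06-01")
    met, canopy_daily, scene = generate_dataset(scenario)
    canopy_hourly = align_canopy(canopy_daily, met["timestamp"])
    return scenario, met, canopy_daily, canopy_hourly, scene, scenario.to_site_config()


@pytest.fixture()
def default_config():
    return SiteConfig()


@pytest.fixture()
def met_csv(tmp_path):
    """Write a tiny canonical met CSV and return its path."""

    def _write(rows, columns=None, name="met.csv"):
        columns = columns or [
            "timestamp", "sw_in", "t_a", "e_a", "u", "p", "l_in", "l_out", "le_obs",
        ]
        path = tmp_path / name
        frame = pd.DataFrame(rows, columns=columns)
        frame.to_csv(path, index=False)
        return path

    return _write


def make_rows(n=3, start="2019-06-01T10:00:00+00:00"):
    times = pd.date_range(start, periods=n, freq="h")
    return [
        [t.isoformat(), 500.0 + i, 295.0, 1.2, 2.0, 100.5, 350.0, 460.0, 120.0]
        for i, t in enumerate(times)
    ]
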