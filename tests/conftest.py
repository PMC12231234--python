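from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from reefmon import mooring_sim


def make_daily(
    start: str,
    st_mean,
    st_max=None,
    st_min=None,
    salinity=39.0,
) -> pd.DataFrame:
    """Build a daily-summary frame from plain value arrays."""
    st_mean = np.asarray(st_mean, dtype=float)
    n = len(st_mean)
    st_max = st_mean if st_max is None else np.asarray(st_max, dtype=float)
    st_min = st_mean if st_min is None else np.asarray(st_min, dtype=float)
    return pd.DataFrame(
        {
            "date": pd.date_range(start, periods=n, freq="D"),
            "st_mean": st_mean,
            "st_max": st_max,
            "st_min": st_min,
            "salinity_mean": np.full(n, salinity, dtype=float),
            "n_bursts": np.full(n, 96),
            "stations_present": "A,B",
        }
    )


def make_ctd_records(rows) -> pd.DataFrame:
    """rows: (iso_ts, temp, sal, station, deployment) tuples."""
    df = pd.DataFrame(
        rows, columns=["timestamp", "temperature_c", "salinity_psu", "station", "deployment"]
    )
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    return df


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260101)


@pytest.fixture(scope="session")
def short_scenario() -> mooring_sim.SyntheticScenario:
    """Two months, no heatwave, small: fast enough for many tests."""
    return mooring_sim.default_scenario(
        start="2021-06-01", end="2021-07-31", gaps=[], heatwaves=[], seed=7
    )


@pytest.fixture(scope="session")
def short_ctd(short_scenario):
    return mooring_sim.generate_ctd(short_scenario)
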