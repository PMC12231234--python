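"""Reading, quality control, and reduction of moored CTD/ADCP records.

The reduction chain for temperature/salinity is

    raw samples -> 30-min burst means (per station, per deployment)
                -> per-station daily statistics
                -> station-combined daily summary

matching a burst-sampling scheme of 10 rapid samples every 30 minutes.
Overlapping deployments of the same station are first averaged within
each deployment and then merged with equal weight per deployment, so a
station duplicated under a second deployment id reproduces the
single-deployment result exactly.

Column contracts
----------------
CTD records:   timestamp (tz-aware UTC), temperature_c, salinity_psu,
               station, deployment
Burst summary: burst_start (tz-aware UTC, on the 30-min grid), station,
               temperature_mean, salinity_mean, n_samples
Daily summary: date (datetime64[ns], local calendar day), st_mean, st_max,
               st_min, salinity_mean, n_bursts, stations_present
ADCP records:  timestamp (tz-aware UTC), station, cell_index, height_m,
               speed_ms, direction_deg  (long format, one row per cell)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (
    DEFAULT_GEOMETRY,
    EmptyInputError,
    FormatError,
    QcBounds,
    StationGeometry,
)

log = logging.getLogger(__name__)

BURST_INTERVAL = "30min"

#: Default UTC offset (hours) used to define local calendar days for the
#: daily statistics; +3 h corresponds to the Red Sea / Arabia Standard Time.
DEFAULT_UTC_OFFSET_H = 3.0


@dataclass(frozen=True)
class CsvDialect:
    """Header-driven CSV column mapping for instrument exports."""

    delimiter: str = ","
    columns: dict = field(
        default_factory=lambda: {
            "timestamp": "timestamp",
            "temperature_c": "temperature_C",
            "salinity_psu": "salinity_PSU",
            "station": "station",
            "deployment": "deployment",
        }
    )


@dataclass(frozen=True)
class AdcpCsvDialect:
    """Column mapping for long-format ADCP CSV (one row per depth cell)."""

    delimiter: str = ","
    columns: dict = field(
        default_factory=lambda: {
            "timestamp": "timestamp",
            "station": "station",
            "cell_index": "cell_index",
            "height_m": "height_m",
            "speed_ms": "speed_ms",
            "direction_deg": "direction_deg",
        }
    )


def _read_csv(path, dialect) -> pd.DataFrame:
    try:
        raw = pd.read_csv(path, sep=dialect.delimiter)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in dialect.columns.values() if c not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}; header is {list(raw.columns)}")
    inverse = {v: k for k, v in dialect.columns.items()}
    return raw.rename(columns=inverse)[list(dialect.columns)]


def read_ctd(
    path,
    dialect: CsvDialect | None = None,
    qc: QcBounds = QcBounds(),
) -> pd.DataFrame:
    """Read a CTD CSV file, apply range QC, and sort by timestamp.

    Rows with unparseable timestamps or values outside the QC bounds are
    dropped with a logged count.  Raises :class:`FormatError` if the
    header does not match the dialect and :class:`EmptyInputError` if no
    valid rows remain.
    """
    dialect = dialect or CsvDialect()
    df = _read_csv(path, dialect)
    n_raw = len(df)
    df["timestamp"] = pd.to_datetime(df["timestamp"], errors="coerce", utc=True)
    for col in ("temperature_c", "salinity_psu"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df = df.dropna(subset=["timestamp", "temperature_c", "salinity_psu"])
    lo_t, hi_t = qc.temperature_c
    lo_s, hi_s = qc.salinity_psu
    ok = df["temperature_c"].between(lo_t, hi_t) & df["salinity_psu"].between(lo_s, hi_s)
    n_dropped = n_raw - int(ok.sum())
    if n_dropped:
        log.info("read_ctd(%s): dropped %d of %d rows failing QC/parse", path, n_dropped, n_raw)
    df = df[ok]
    if df.empty:
        raise EmptyInputError(f"{path}: no valid CTD rows after QC")
    df["station"] = df["station"].astype(str)
    df["deployment"] = df["deployment"].astype(str)
    return df.sort_values("timestamp", kind="mergesort").reset_index(drop=True)


def write_ctd(df: pd.DataFrame, path, dialect: CsvDialect | None = None) -> None:
    """Write CTD records back to CSV in the dialect's column names."""
    dialect = dialect or CsvDialect()
    out = df.rename(columns=dialect.columns)
    out.to_csv(path, sep=dialect.delimiter, index=False, date_format="%Y-%m-%dT%H:%M:%S%z")


def read_adcp(
    path,
    dialect: AdcpCsvDialect | None = None,
    geometry: dict[str, StationGeometry] | None = None,
) -> pd.DataFrame:
    """Read a long-format ADCP CSV and validate cells against geometry.

    Ensembles containing a cell index above the station's configured cell
    count are rejected with a :class:`FormatError`.  Rows with missing
    speed or direction are dropped; directions are normalised to [0, 360).
    """
    dialect = dialect or AdcpCsvDialect()
    geometry = geometry or DEFAULT_GEOMETRY
    df = _read_csv(path, dialect)
    n_raw = len(df)
    df["timestamp"] = pd.to_datetime(df["timestamp"], errors="coerce", utc=True)
    for col in ("cell_index", "height_m", "speed_ms", "direction_deg"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df = df.dropna(subset=["timestamp", "cell_index", "speed_ms", "direction_deg"])
    df["station"] = df["station"].astype(str)
    df["cell_index"] = df["cell_index"].astype(int)
    for station, grp in df.groupby("station"):
        geom = geometry.get(station)
        if geom is None:
            raise FormatError(f"{path}: unknown station {station!r}")
        worst = grp["cell_index"].max()
        if worst > geom.n_cells or (grp["cell_index"] < 1).any():
            raise FormatError(
                f"{path}: station {station} has cell index {worst} outside "
                f"the configured 1..{geom.n_cells} range"
            )
    if (df["speed_ms"] < 0).any():
        raise FormatError(f"{path}: negative current speeds present")
    df["direction_deg"] = np.mod(df["direction_deg"], 360.0)
    if df.empty:
        raise EmptyInputError(f"{path}: no valid ADCP rows")
    if n_raw != len(df):
        log.info("read_adcp(%s): dropped %d of %d rows", path, n_raw - len(df), n_raw)
    return df.sort_values(["timestamp", "station", "cell_index"], kind="mergesort").reset_index(
        drop=True
    )


def write_adcp(df: pd.DataFrame, path, dialect: AdcpCsvDialect | None = None) -> None:
    dialect = dialect or AdcpCsvDialect()
    out = df.rename(columns=dialect.columns)
    out.to_csv(path, sep=dialect.delimiter, index=False, date_format="%Y-%m-%dT%H:%M:%S%z")


def burst_average(records: pd.DataFrame, interval: str = BURST_INTERVAL) -> pd.DataFrame:
    """Collapse raw samples into per-slot burst means.

    The burst grid is anchored at :00/:30 past each hour; a sample belongs
    to the half-open slot containing its timestamp.  Samples are averaged
    within each (station, deployment, slot) group first; duplicate slots
    arising from overlapping deployments are then merged with equal weight
    per deployment, with ``n_samples`` the largest per-deployment count.
    """
    if records.empty:
        return pd.DataFrame(
            columns=["burst_start", "station", "temperature_mean", "salinity_mean", "n_samples"]
        )
    slot = records["timestamp"].dt.floor(interval)
    per_dep = (
        records.assign(burst_start=slot)
        .groupby(["station", "deployment", "burst_start"], sort=True)
        .agg(
            temperature_mean=("temperature_c", "mean"),
            salinity_mean=("salinity_psu", "mean"),
            n_samples=("temperature_c", "size"),
        )
        .reset_index()
    )
    bursts = (
        per_dep.groupby(["station", "burst_start"], sort=True)
        .agg(
            temperature_mean=("temperature_mean", "mean"),
            salinity_mean=("salinity_mean", "mean"),
            n_samples=("n_samples", "max"),
        )
        .reset_index()
    )
    return bursts[["burst_start", "station", "temperature_mean", "salinity_mean", "n_samples"]]


def _local_date(ts: pd.Series, utc_offset_hours: float) -> pd.Series:
    return (ts + pd.Timedelta(hours=utc_offset_hours)).dt.tz_localize(None).dt.normalize()


def daily_aggregate(
    bursts: pd.DataFrame,
    merge: str = "mean",
    utc_offset_hours: float = DEFAULT_UTC_OFFSET_H,
) -> pd.DataFrame:
    """Combine burst means into station-merged daily summaries.

    Two merge policies are provided for "combining both locations":

    ``'mean'`` (default)
        Daily mean/max/min are computed per station, then combined as the
        arithmetic mean of station means, the max of station maxima, and
        the min of station minima.
    ``'pool'``
        All bursts from both stations are pooled before taking the daily
        statistics.

    Calendar days are defined in local time via ``utc_offset_hours``.
    Days without bursts are absent from the output.
    """
    if merge not in ("mean", "pool"):
        raise ValueError(f"unknown merge policy {merge!r}")
    cols = ["date", "st_mean", "st_max", "st_min", "salinity_mean", "n_bursts", "stations_present"]
    if bursts.empty:
        return pd.DataFrame(columns=cols)
    df = bursts.assign(date=_local_date(bursts["burst_start"], utc_offset_hours))
    if merge == "pool":
        daily = (
            df.groupby("date", sort=True)
            .agg(
                st_mean=("temperature_mean", "mean"),
                st_max=("temperature_mean", "max"),
                st_min=("temperature_mean", "min"),
                salinity_mean=("salinity_mean", "mean"),
                n_bursts=("temperature_mean", "size"),
                stations_present=("station", lambda s: ",".join(sorted(set(s)))),
            )
            .reset_index()
        )
    else:
        per_station = (
            df.groupby(["date", "station"], sort=True)
            .agg(
                st_mean=("temperature_mean", "mean"),
                st_max=("temperature_mean", "max"),
                st_min=("temperature_mean", "min"),
                salinity_mean=("salinity_mean", "mean"),
                n_bursts=("temperature_mean", "size"),
            )
            .reset_index()
        )
        daily = (
            per_station.groupby("date", sort=True)
            .agg(
                st_mean=("st_mean", "mean"),
                st_max=("st_max", "max"),
                st_min=("st_min", "min"),
                salinity_mean=("salinity_mean", "mean"),
                n_bursts=("n_bursts", "sum"),
                stations_present=("station", lambda s: ",".join(sorted(set(s)))),
            )
            .reset_index()
        )
    wide = daily["st_max"] - daily["st_min"] > 1.0
    if wide.any():
        log.warning(
            "daily_aggregate: %d day(s) with daily range > 1 degC (max %.2f)",
            int(wide.sum()),
            float((daily["st_max"] - daily["st_min"]).max()),
        )
    return daily[cols]


def reduce_ctd(
    records: pd.DataFrame,
    merge: str = "mean",
    utc_offset_hours: float = DEFAULT_UTC_OFFSET_H,
) -> pd.DataFrame:
    """Full raw-records-to-daily-summary reduction."""
    return daily_aggregate(burst_average(records), merge=merge, utc_offset_hours=utc_offset_hours)


def write_daily(daily: pd.DataFrame, path) -> None:
    out = daily.copy()
    out["date"] = out["date"].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_daily(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["date"] = pd.to_datetime(df["date"])
    return df
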