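"""Daily HotSpots, relative Degree Heating Weeks, and bleaching alerts.

The relative Degree Heating Weeks index accumulates, over an 84-day
(12-week) window ending on day ``i``, every daily HotSpot of at least
1 degC and converts the total from degC-days to degC-weeks:

    HS_j  = ST_j - MMM          (ST_j = daily mean or daily maximum)
    rDHW_i = sum_{j=i-83..i} HS_j * 1[HS_j >= 1] / 7

"Relative" marks the use of in-situ bottom temperature in place of the
satellite sea-surface temperature of the operational DHW product.  A
single day at HS = 7 degC therefore contributes exactly 1 degC-week.

Alert categories follow the extended Coral Reef Watch scale: the HotSpot
drives the low end (Watch below 1 degC, Warning at or above), the rDHW
accumulation drives the alert levels in 4 degC-week steps, with levels
2-5 requiring only the rDHW bound.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import ALERT_LEVELS, UNCLASSIFIED, Climatology

WINDOW_DAYS = 84
HOTSPOT_GATE_C = 1.0
DAYS_PER_WEEK = 7.0

#: Lower rDHW bound (degC-weeks) of each alert level AL1..AL5.
ALERT_RDHW_EDGES = (4.0, 8.0, 12.0, 16.0, 20.0)


def compute_hotspot(daily: pd.DataFrame, clim: Climatology, basis: str = "max") -> pd.DataFrame:
    """Daily HotSpot series: (ST_mean or ST_max) - MMM, in degC.

    Returns a frame with columns ``date`` and ``hs``; negative HotSpots
    are kept (they matter for the Watch/NoStress distinction).
    """
    if basis not in ("mean", "max"):
        raise ValueError(f"basis must be 'mean' or 'max', got {basis!r}")
    col = "st_mean" if basis == "mean" else "st_max"
    out = pd.DataFrame(
        {"date": daily["date"].values, "hs": daily[col].to_numpy(dtype=float) - clim.mmm_c}
    )
    out.attrs["basis"] = basis
    out.attrs["mmm_c"] = clim.mmm_c
    return out


def compute_rdhw(
    hotspots: pd.DataFrame,
    gap_policy: str = "permissive",
    window_days: int = WINDOW_DAYS,
    gate_c: float = HOTSPOT_GATE_C,
    coverage_flag: float = 0.9,
) -> pd.DataFrame:
    """Accumulate gated HotSpots into the rolling rDHW series.

    The series is reindexed to a continuous daily calendar between its
    first and last day; missing days contribute zero to every window they
    fall in and lower ``window_coverage`` (the fraction of the 84-day
    window with data, also partial during the initial ramp-up).

    ``gap_policy='permissive'`` (default) reports rDHW from the first day
    over whatever part of the window exists; ``'strict'`` leaves the
    first ``window_days - 1`` days undefined (NaN).  Days with coverage
    below ``coverage_flag`` are flagged via ``low_coverage``.
    """
    if gap_policy not in ("permissive", "strict"):
        raise ValueError(f"unknown gap_policy {gap_policy!r}")
    if hotspots.empty:
        out = hotspots.copy()
        out["rdhw"] = pd.Series(dtype=float)
        out["window_coverage"] = pd.Series(dtype=float)
        out["low_coverage"] = pd.Series(dtype=bool)
        return out
    s = hotspots.set_index("date")["hs"].sort_index()
    full = s.reindex(pd.date_range(s.index[0], s.index[-1], freq="D"))
    contrib = full.where(full >= gate_c, 0.0).fillna(0.0)
    rdhw = contrib.rolling(window=window_days, min_periods=1).sum() / DAYS_PER_WEEK
    coverage = full.notna().rolling(window=window_days, min_periods=1).sum() / window_days
    if gap_policy == "strict":
        rdhw.iloc[: window_days - 1] = np.nan
    out = pd.DataFrame(
        {
            "date": full.index,
            "hs": full.values,
            "rdhw": rdhw.values,
            "window_coverage": coverage.values,
        }
    )
    out["low_coverage"] = out["window_coverage"] < coverage_flag
    out.attrs.update(hotspots.attrs)
    out.attrs["gap_policy"] = gap_policy
    # drop calendar days that had no observation: they only served as
    # zero-contribution window filler
    out = out[out["hs"].notna()].reset_index(drop=True)
    return out


def classify_alerts(series: pd.DataFrame) -> pd.DataFrame:
    """Assign the bleaching-alert category for every day.

    Classification table (left-closed, right-open rDHW bins):

    ==========  =====================================
    NoStress    HS <= 0
    Watch       0 < HS < 1
    Warning     HS >= 1 and rDHW < 4
    AL1         HS >= 1 and 4 <= rDHW < 8
    AL2..AL5    rDHW in [8,12), [12,16), [16,20), >=20
                (regardless of the day's HotSpot)
    ==========  =====================================

    Days whose rDHW is undefined (strict warm-up) are marked
    ``Unclassified``.
    """
    hs = series["hs"].to_numpy(dtype=float)
    rdhw = series["rdhw"].to_numpy(dtype=float)
    alert = np.full(len(series), UNCLASSIFIED, dtype=object)
    defined = ~np.isnan(rdhw)
    hot = hs >= HOTSPOT_GATE_C
    cond = [
        defined & (rdhw >= 20.0),
        defined & (rdhw >= 16.0),
        defined & (rdhw >= 12.0),
        defined & (rdhw >= 8.0),
        defined & hot & (rdhw >= 4.0),
        defined & hot,
        defined & (hs > 0.0),
        defined,
    ]
    labels = ["AL5", "AL4", "AL3", "AL2", "AL1", "Warning", "Watch", "NoStress"]
    for c, lab in zip(cond, labels):
        alert[c & (alert == UNCLASSIFIED)] = lab
    out = series.copy()
    out["alert"] = pd.Categorical(alert, categories=list(ALERT_LEVELS) + [UNCLASSIFIED])
    out.attrs.update(series.attrs)
    return out


def heat_stress_series(
    daily: pd.DataFrame,
    clim: Climatology,
    basis: str = "max",
    gap_policy: str = "permissive",
) -> pd.DataFrame:
    """Convenience chain: HotSpots -> rDHW -> alerts."""
    return classify_alerts(compute_rdhw(compute_hotspot(daily, clim, basis), gap_policy))


def alert_day_counts(series: pd.DataFrame, year: int) -> dict[str, int]:
    """Per-level counts of classified days within a calendar year."""
    sub = series[series["date"].dt.year == year]
    counts = sub["alert"].value_counts()
    return {level: int(counts.get(level, 0)) for level in ALERT_LEVELS}


def consecutive_weeks_above(
    series: pd.DataFrame,
    threshold_c_weeks: float = 8.0,
    mode: str = "tiled",
) -> int:
    """Longest run of consecutive weeks whose peak rDHW exceeds a threshold.

    ``mode='tiled'`` (default): 7-day blocks tile forward from the first
    day the series exceeds the threshold; a block qualifies when its
    weekly maximum rDHW exceeds the threshold, and only complete blocks
    count.  ``mode='iso'`` groups by ISO calendar week instead.
    """
    if mode not in ("tiled", "iso"):
        raise ValueError(f"unknown mode {mode!r}")
    s = series.set_index("date")["rdhw"].sort_index()
    s = s.reindex(pd.date_range(s.index[0], s.index[-1], freq="D"))
    above = s > threshold_c_weeks
    if not above.any():
        return 0
    if mode == "tiled":
        start = int(np.argmax(above.to_numpy()))
        vals = s.to_numpy()[start:]
        weekly = []
        for k in range(len(vals) // 7):
            block = vals[k * 7 : (k + 1) * 7]
            block = block[~np.isnan(block)]
            weekly.append(block.size > 0 and float(block.max()) > threshold_c_weeks)
    else:
        iso = s.index.isocalendar()
        weekly_max = s.groupby([iso.year, iso.week]).max()
        weekly = (weekly_max > threshold_c_weeks).tolist()
    best = run = 0
    for ok in weekly:
        run = run + 1 if ok else 0
        best = max(best, run)
    return best


def round_c_weeks(value: float) -> float:
    """Round an rDHW value half-even to one decimal for reporting."""
    return float(np.round(value, 1))
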