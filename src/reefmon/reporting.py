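"""Pipeline orchestration and machine-readable surveillance reports.

A single configuration mapping drives the whole chain — input acquisition
(synthetic scenario or CSV files), reduction to daily summaries, the MMM
choice, per-basis heat-stress series, and seasonal current statistics —
and every knob used is echoed into the report's provenance block so each
number is recomputable from the emitted intermediates alone.
"""

from __future__ import annotations

import datetime as _dt
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, climatology, currents, heatstress, mooring_sim, timeseries_io
from .types import DEFAULT_GEOMETRY, ConfigError, EmptyInputError, RoseConfig

SCHEMA_VERSION = 1


def _acquire(config: dict):
    """Return (ctd_records_by_station, adcp_by_station, ledger_or_None)."""
    if "scenario" in config:
        sc = config["scenario"]
        if sc == "default":
            scenario = mooring_sim.default_scenario()
        elif isinstance(sc, mooring_sim.SyntheticScenario):
            scenario = sc
        elif isinstance(sc, dict):
            scenario = mooring_sim.SyntheticScenario.from_dict(sc)
        else:
            raise ConfigError(f"unrecognised scenario spec {sc!r}")
        if "seed" in config:
            scenario.seed = int(config["seed"])
        ctd, ledger = mooring_sim.generate_ctd(scenario)
        adcp, counts = mooring_sim.generate_adcp(scenario)
        ledger.record_counts.update(counts)
        return ctd, adcp, ledger, scenario
    inputs = config.get("inputs")
    if not inputs or "ctd" not in inputs:
        raise ConfigError("config needs either 'scenario' or 'inputs.ctd'")
    ctd = {}
    for path in inputs["ctd"]:
        df = timeseries_io.read_ctd(path)
        for station, grp in df.groupby("station"):
            ctd[station] = pd.concat([ctd.get(station, pd.DataFrame()), grp], ignore_index=True)
    adcp = {}
    for path in inputs.get("adcp", []):
        df = timeseries_io.read_adcp(path)
        for station, grp in df.groupby("station"):
            adcp[station] = pd.concat([adcp.get(station, pd.DataFrame()), grp], ignore_index=True)
    return ctd, adcp, None, None


def _resolve_mmm(config: dict, daily: pd.DataFrame, ledger):
    clim_cfg = config.get("climatology", "ledger")
    if clim_cfg == "ledger":
        if ledger is None:
            raise ConfigError("climatology 'ledger' requires a synthetic scenario")
        from .types import Climatology

        return Climatology(mmm_c=ledger.mmm_c, source="configured")
    if isinstance(clim_cfg, dict):
        return climatology.load_mmm(clim_cfg, daily=daily)
    raise ConfigError(f"unrecognised climatology config {clim_cfg!r}")


def _temperature_summary(daily: pd.DataFrame) -> dict:
    out = {"overall_min_c": round(float(daily["st_min"].min()), 2), "by_year": {}}
    for year, grp in daily.groupby(daily["date"].dt.year):
        out["by_year"][int(year)] = {
            "min_daily_mean_c": round(float(grp["st_mean"].min()), 2),
            "max_daily_mean_c": round(float(grp["st_mean"].max()), 2),
            "max_daily_max_c": round(float(grp["st_max"].max()), 2),
            "n_days": int(len(grp)),
        }
    return out


def _heat_stress_summary(series: pd.DataFrame, years, cw_threshold: float, cw_mode: str) -> dict:
    idx = int(series["rdhw"].idxmax())
    return {
        "max_rdhw_c_weeks": heatstress.round_c_weeks(float(series["rdhw"].max())),
        "max_rdhw_date": str(series.loc[idx, "date"].date()),
        "alert_day_counts": {
            int(y): heatstress.alert_day_counts(series, int(y)) for y in years
        },
        "consecutive_weeks_above": {
            "threshold_c_weeks": cw_threshold,
            "mode": cw_mode,
            "weeks": heatstress.consecutive_weeks_above(series, cw_threshold, cw_mode),
        },
    }


def run_pipeline(config: dict, out_dir=None) -> dict:
    """Execute the full surveillance analysis and return the report dict.

    When ``out_dir`` is given, intermediates (daily summary, per-basis
    heat-stress series, seasonal current stats) are written as CSV next
    to ``report.json``.
    """
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    ctd, adcp, ledger, scenario = _acquire(config)
    if not ctd:
        raise EmptyInputError("no CTD records acquired")
    merge = config.get("merge", "mean")
    utc_offset = float(config.get("utc_offset_hours", timeseries_io.DEFAULT_UTC_OFFSET_H))
    records = pd.concat(ctd.values(), ignore_index=True)
    bursts = timeseries_io.burst_average(records)
    daily = timeseries_io.daily_aggregate(bursts, merge=merge, utc_offset_hours=utc_offset)
    clim = _resolve_mmm(config, daily, ledger)
    gap_policy = config.get("gap_policy", "permissive")
    bases = config.get("basis", ["mean", "max"])
    cw_cfg = config.get("consecutive_weeks", {})
    cw_threshold = float(cw_cfg.get("threshold_c_weeks", 8.0))
    cw_mode = cw_cfg.get("mode", "tiled")
    years = sorted(daily["date"].dt.year.unique())

    report = {
        "schema_version": SCHEMA_VERSION,
        "generated_at": _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds"),
        "provenance": {
            "software_version": __version__,
            "mmm_c": round(float(clim.mmm_c), 4),
            "mmm_source": clim.source,
            "merge_policy": merge,
            "gap_policy": gap_policy,
            "utc_offset_hours": utc_offset,
            "consecutive_weeks_mode": cw_mode,
            "seed": scenario.seed if scenario is not None else None,
            "synthetic": scenario is not None,
        },
        "temperature": _temperature_summary(daily),
        "salinity": {"median_daily_mean_psu": round(float(daily["salinity_mean"].median()), 2)},
        "heat_stress": {},
    }

    hs_series = {}
    for basis in bases:
        series = heatstress.heat_stress_series(daily, clim, basis=basis, gap_policy=gap_policy)
        hs_series[basis] = series
        report["heat_stress"][f"rdhw_st{basis}"] = _heat_stress_summary(
            series, years, cw_threshold, cw_mode
        )
        if out_dir is not None:
            out = series.copy()
            out["date"] = out["date"].dt.strftime("%Y-%m-%d")
            out.to_csv(out_dir / f"dhw_{basis}.csv", index=False)

    if adcp:
        rose_cfg = RoseConfig(**config.get("rose", {}))
        current_stats = []
        geometry = scenario.stations if scenario is not None else dict(DEFAULT_GEOMETRY)
        for station in sorted(adcp):
            for layer in ("surface", "bottom"):
                series = currents.extract_layer(adcp[station], layer, geometry[station])
                stats = currents.seasonal_speed_stats(series)
                for _, row in stats.iterrows():
                    current_stats.append(
                        {
                            "station": station,
                            "layer": layer,
                            "cell_index": series.attrs["cell_index"],
                            "season": row["season"],
                            "season_year": int(row["season_year"]),
                            "mean_speed_ms": round(float(row["mean_speed_ms"]), 4),
                            "max_speed_ms": round(float(row["max_speed_ms"]), 4),
                            "n": int(row["n"]),
                        }
                    )
        report["currents"] = {"seasonal_stats": current_stats, "rose_config": {
            "n_dir": rose_cfg.n_dir,
            "speed_breaks_ms": [b for b in rose_cfg.speed_breaks_ms if np.isfinite(b)],
            "calm_floor_ms": rose_cfg.calm_floor_ms,
            "sector_origin": rose_cfg.sector_origin,
        }}
    else:
        report["currents"] = {"absent": True}

    if ledger is not None:
        report["provenance"]["record_counts"] = ledger.record_counts

    if out_dir is not None:
        timeseries_io.write_daily(daily, out_dir / "daily.csv")
        if report["currents"].get("seasonal_stats"):
            pd.DataFrame(report["currents"]["seasonal_stats"]).to_csv(
                out_dir / "seasonal_currents.csv", index=False
            )
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return report
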