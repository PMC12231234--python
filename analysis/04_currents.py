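"""Seasonal current climatology from the ADCP records.

Extracts the surface and bottom layers at both stations, tabulates the
seasonal direction/speed roses (oceanographic convention: bearings give
where the flow is going toward), and writes the seasonal speed summary
to results/seasonal_currents.csv and the rose tables to
results/rose_tables.csv.  Prints which layer/season was fastest on
average and the single strongest ensemble.
"""

from pathlib import Path

import pandas as pd

from reefmon import currents as cur
from reefmon import mooring_sim as ms
from reefmon import timeseries_io as tio

ROOT = Path(__file__).resolve().parents[1]
DATA_DIR = ROOT / "scratch" / "data"
RESULTS = ROOT / "results"


def main() -> pd.DataFrame:
    if not (DATA_DIR / "adcp_A.csv").exists():
        ms.generate_files(ms.default_scenario(), DATA_DIR)
    scenario = ms.default_scenario()
    RESULTS.mkdir(exist_ok=True)
    stats_rows, rose_rows = [], []
    for station, geom in sorted(scenario.stations.items()):
        ensembles = tio.read_adcp(DATA_DIR / f"adcp_{station}.csv")
        for layer in ("surface", "bottom"):
            series = cur.extract_layer(ensembles, layer, geom)
            stats = cur.seasonal_speed_stats(series)
            stats.insert(0, "station", station)
            stats.insert(1, "layer", layer)
            stats.insert(2, "cell_index", series.attrs["cell_index"])
            stats_rows.append(stats)
            for table in cur.seasonal_rose_tables(series):
                tf = table.to_frame()
                tf.insert(0, "station", station)
                tf.insert(1, "layer", layer)
                tf.insert(2, "season", table.season)
                tf.insert(3, "year", table.year)
                tf["calm_percent"] = table.calm_percent
                rose_rows.append(tf)
    stats = pd.concat(stats_rows, ignore_index=True)
    roses = pd.concat(rose_rows, ignore_index=True)
    stats.to_csv(RESULTS / "seasonal_currents.csv", index=False)
    roses.to_csv(RESULTS / "rose_tables.csv", index=False)

    top_mean = stats.loc[stats["mean_speed_ms"].idxmax()]
    top_peak = stats.loc[stats["max_speed_ms"].idxmax()]
    print(f"{len(stats)} station/layer/season groups summarised")
    print(
        f"fastest mean flow: {top_mean['mean_speed_ms']:.3f} m/s "
        f"({top_mean['station']} {top_mean['layer']}, {top_mean['season']} "
        f"{int(top_mean['season_year'])})"
    )
    print(
        f"strongest single ensemble: {top_peak['max_speed_ms']:.3f} m/s "
        f"({top_peak['station']} {top_peak['layer']}, {top_peak['season']} "
        f"{int(top_peak['season_year'])})"
    )
    print(f"wrote {RESULTS / 'seasonal_currents.csv'} and {RESULTS / 'rose_tables.csv'}")
    return stats


if __name__ == "__main__":
    main()
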