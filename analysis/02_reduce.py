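"""Reduce raw CTD records to the station-combined daily summary.

Reads the synthetic CTD files (generating them first if 01_simulate.py
has not been run), burst-averages them, merges stations under the
default policy, and writes results/daily.csv.  Prints the hydrographic
summary: per-year temperature extremes, the overall minimum, and the
median daily salinity.
"""

from pathlib import Path

import pandas as pd

from reefmon import mooring_sim as ms
from reefmon import timeseries_io as tio

ROOT = Path(__file__).resolve().parents[1]
DATA_DIR = ROOT / "scratch" / "data"
RESULTS = ROOT / "results"


def ensure_data() -> None:
    if not (DATA_DIR / "ctd_A.csv").exists():
        ms.generate_files(ms.default_scenario(), DATA_DIR)


def main() -> pd.DataFrame:
    ensure_data()
    records = pd.concat(
        [tio.read_ctd(p) for p in sorted(DATA_DIR.glob("ctd_*.csv"))], ignore_index=True
    )
    daily = tio.reduce_ctd(records, merge="mean")
    RESULTS.mkdir(exist_ok=True)
    tio.write_daily(daily, RESULTS / "daily.csv")
    print(f"{len(records)} raw samples -> {len(daily)} daily summaries")
    for year, grp in daily.groupby(daily["date"].dt.year):
        print(
            f"  {year}: daily mean {grp['st_mean'].min():.2f}..{grp['st_mean'].max():.2f} degC, "
            f"highest daily max {grp['st_max'].max():.2f} degC ({len(grp)} days)"
        )
    print(f"overall minimum temperature: {daily['st_min'].min():.2f} degC")
    print(f"median daily mean salinity: {daily['salinity_mean'].median():.2f} PSU")
    print(f"wrote {RESULTS / 'daily.csv'}")
    return daily


if __name__ == "__main__":
    main()
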