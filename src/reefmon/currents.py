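"""Depth-layer extraction, seasonal current roses, and speed statistics.

Directions are handled in the oceanographic convention throughout: a
bearing gives where the flow is going *toward* (winds use the opposite,
direction-from, convention — :func:`from_wind_convention` converts).
Seasons are the standard meteorological quarters, with winter (DJF)
attributed to the year of its January/February.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import GeometryError, RoseConfig, StationGeometry

log = logging.getLogger(__name__)

SEASON_OF_MONTH = {
    12: "DJF", 1: "DJF", 2: "DJF",
    3: "MAM", 4: "MAM", 5: "MAM",
    6: "JJA", 7: "JJA", 8: "JJA",
    9: "SON", 10: "SON", 11: "SON",
}

#: Target height of the "bottom" layer above the seabed, in metres.
BOTTOM_TARGET_M = 1.0
#: Minimum depth below the nominal surface for a usable "surface" cell
#: (guards against side-lobe contamination near the air-sea interface).
SURFACE_GUARD_M = 0.5


def season_of(date) -> tuple[str, int]:
    """Map a date to its (season, season-year).

    December belongs to the following winter, so DJF is labelled with the
    year of its January/February: 2021-12-31 -> ('DJF', 2022).
    """
    ts = pd.Timestamp(date)
    season = SEASON_OF_MONTH[ts.month]
    year = ts.year + 1 if ts.month == 12 else ts.year
    return season, year


def _season_columns(timestamps: pd.Series) -> pd.DataFrame:
    month = timestamps.dt.month
    season = month.map(SEASON_OF_MONTH)
    year = timestamps.dt.year + (month == 12).astype(int)
    return pd.DataFrame({"season": season.values, "season_year": year.values})


def layer_cell_index(geometry: StationGeometry, layer: str) -> int:
    """Resolve which ADCP cell represents a named depth layer.

    ``'bottom'``: the cell whose centre is nearest 1 m above the seabed.
    ``'surface'``: the uppermost cell whose centre is at least 0.5 m below
    the nominal surface.  With a single valid cell both layers collapse
    onto it (warned).
    """
    if layer not in ("surface", "bottom"):
        raise ValueError(f"layer must be 'surface' or 'bottom', got {layer!r}")
    cells = range(1, geometry.n_cells + 1)
    if layer == "bottom":
        k = min(cells, key=lambda c: abs(geometry.cell_height_above_bed(c) - BOTTOM_TARGET_M))
    else:
        valid = [c for c in cells if geometry.cell_depth_below_surface(c) >= SURFACE_GUARD_M]
        if not valid:
            raise GeometryError(
                f"station {geometry.station}: no cell at least {SURFACE_GUARD_M} m "
                "below the surface"
            )
        k = max(valid)
    if geometry.n_cells == 1:
        log.warning(
            "station %s has a single cell; it serves both layers", geometry.station
        )
    log.info("station %s %s layer -> cell %d (%.2f m above bed)",
             geometry.station, layer, k, geometry.cell_height_above_bed(k))
    return k


def extract_layer(
    ensembles: pd.DataFrame,
    layer: str,
    geometry: StationGeometry,
) -> pd.DataFrame:
    """Pick the named layer's cell out of long-format ADCP ensembles.

    Returns a per-ensemble frame with columns ``timestamp``, ``speed_ms``,
    ``direction_deg``; ensembles missing that cell (or with missing
    values in it) are skipped.  The chosen cell index is recorded in
    ``attrs``.
    """
    k = layer_cell_index(geometry, layer)
    sub = ensembles[
        (ensembles["station"] == geometry.station) & (ensembles["cell_index"] == k)
    ]
    sub = sub.dropna(subset=["speed_ms", "direction_deg"])
    out = sub[["timestamp", "speed_ms", "direction_deg"]].sort_values("timestamp").reset_index(
        drop=True
    )
    out.attrs["station"] = geometry.station
    out.attrs["layer"] = layer
    out.attrs["cell_index"] = k
    return out


def from_wind_convention(direction_deg) -> np.ndarray:
    """Convert direction-from (wind convention) to direction-toward."""
    return np.mod(np.asarray(direction_deg, dtype=float) + 180.0, 360.0)


@dataclass
class RoseTable:
    """Joint direction x speed frequency table for one season subset.

    ``bins`` holds percentages of all ensembles in the subset (shape
    ``n_dir x n_speed_classes``); ``calm_percent`` is the share below the
    calm floor, so everything sums to 100 for a non-empty subset.
    """

    season: str
    year: int
    station: str
    layer: str
    config: RoseConfig
    bins: np.ndarray
    calm_percent: float
    n_total: int

    @property
    def empty(self) -> bool:
        return self.n_total == 0

    def sector_edges(self) -> np.ndarray:
        width = 360.0 / self.config.n_dir
        offset = -width / 2.0 if self.config.sector_origin == "center" else 0.0
        return offset + width * np.arange(self.config.n_dir + 1)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format view (one row per sector x speed class)."""
        breaks = self.config.speed_breaks_ms
        rows = []
        edges = self.sector_edges()
        for d in range(self.config.n_dir):
            for s in range(self.bins.shape[1]):
                rows.append(
                    {
                        "sector_start_deg": edges[d] % 360.0,
                        "speed_lo_ms": breaks[s],
                        "speed_hi_ms": breaks[s + 1],
                        "percent": self.bins[d, s],
                    }
                )
        return pd.DataFrame(rows)


def rose_table(
    series: pd.DataFrame,
    season: str,
    year: int,
    config: RoseConfig = RoseConfig(),
) -> RoseTable:
    """Bin one season/year of a layer series into a direction/speed rose.

    Each ensemble lands in sector ``floor(direction / width)`` (after
    normalising direction into [0, 360) and, for ``sector_origin=
    'center'``, rotating by half a sector) and in the half-open speed
    class containing its speed.  An empty subset yields an all-zero table
    flagged via ``empty`` rather than an error.
    """
    cols = _season_columns(series["timestamp"])
    mask = (cols["season"] == season) & (cols["season_year"] == year)
    sub = series[mask.values]
    n_speed = len(config.speed_breaks_ms) - 1
    bins = np.zeros((config.n_dir, n_speed))
    station = series.attrs.get("station", "?")
    layer = series.attrs.get("layer", "?")
    if sub.empty:
        return RoseTable(season, year, station, layer, config, bins, 0.0, 0)
    speed = sub["speed_ms"].to_numpy(dtype=float)
    direction = np.mod(sub["direction_deg"].to_numpy(dtype=float), 360.0)
    calm = speed < config.calm_floor_ms
    width = 360.0 / config.n_dir
    if config.sector_origin == "center":
        direction = np.mod(direction + width / 2.0, 360.0)
    sector = np.floor(direction / width).astype(int) % config.n_dir
    speed_class = np.digitize(speed, config.speed_breaks_ms) - 1
    speed_class = np.clip(speed_class, 0, n_speed - 1)
    n = len(sub)
    for d, s in zip(sector[~calm], speed_class[~calm]):
        bins[d, s] += 1
    bins = bins / n * 100.0
    calm_percent = float(calm.sum()) / n * 100.0
    return RoseTable(season, year, station, layer, config, bins, calm_percent, n)


def seasonal_rose_tables(series: pd.DataFrame, config: RoseConfig = RoseConfig()) -> list[RoseTable]:
    """One rose per (season, year) present in a layer series."""
    cols = _season_columns(series["timestamp"])
    groups = sorted(set(zip(cols["season"], cols["season_year"])), key=lambda g: (g[1], g[0]))
    return [rose_table(series, season, year, config) for season, year in groups]


def seasonal_speed_stats(series: pd.DataFrame) -> pd.DataFrame:
    """Mean/max ensemble speed per (season, season-year)."""
    if series.empty:
        return pd.DataFrame(columns=["season", "season_year", "mean_speed_ms", "max_speed_ms", "n"])
    cols = _season_columns(series["timestamp"])
    df = pd.concat([series.reset_index(drop=True), cols], axis=1)
    out = (
        df.groupby(["season_year", "season"], sort=True)
        .agg(mean_speed_ms=("speed_ms", "mean"), max_speed_ms=("speed_ms", "max"), n=("speed_ms", "size"))
        .reset_index()[["season", "season_year", "mean_speed_ms", "max_speed_ms", "n"]]
    )
    out.attrs.update(series.attrs)
    return out


def plot_rose(table: RoseTable, ax=None):
    """Convenience polar plot of a rose table (stacked speed classes)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    width = np.deg2rad(360.0 / table.config.n_dir)
    theta = np.deg2rad(table.sector_edges()[:-1]) + width / 2.0
    bottom = np.zeros(table.config.n_dir)
    for s in range(table.bins.shape[1]):
        lo = table.config.speed_breaks_ms[s]
        hi = table.config.speed_breaks_ms[s + 1]
        label = f"{lo:g}-{hi:g} m/s" if np.isfinite(hi) else f">{lo:g} m/s"
        ax.bar(theta, table.bins[:, s], width=width, bottom=bottom, label=label, edgecolor="w")
        bottom += table.bins[:, s]
    ax.set_title(f"{table.station} {table.layer} {table.season} {table.year}")
    ax.legend(loc="lower left", bbox_to_anchor=(1.0, 0.0), fontsize="x-small")
    return ax
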