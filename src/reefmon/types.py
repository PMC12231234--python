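"""Core domain types shared across the pipeline.

Series-like data (raw records, bursts, daily summaries, heat-stress and
current series) travel as pandas DataFrames with documented column
contracts; small configuration-like objects are frozen dataclasses.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class ReefmonError(Exception):
    """Base class for pipeline errors."""


class FormatError(ReefmonError):
    """Input file header or layout does not match the declared dialect."""


class EmptyInputError(ReefmonError):
    """No valid rows survived parsing and quality control."""


class ConfigError(ReefmonError):
    """Missing or malformed configuration."""


class GeometryError(ReefmonError):
    """Requested depth layer cannot be resolved from station geometry."""


class InsufficientClimatologyError(ReefmonError):
    """Reference period does not cover every calendar month."""


#: Bleaching-alert categories, ordered from no stress to the most severe
#: alert level on the extended Coral Reef Watch scale.
ALERT_LEVELS = (
    "NoStress",
    "Watch",
    "Warning",
    "AL1",
    "AL2",
    "AL3",
    "AL4",
    "AL5",
)

#: Marker for days whose rDHW is undefined under the strict warm-up policy.
UNCLASSIFIED = "Unclassified"

SEASONS = ("DJF", "MAM", "JJA", "SON")


@dataclass(frozen=True)
class StationGeometry:
    """Mooring geometry needed to map ADCP cells to physical heights.

    The profiler sits on a bottom frame looking up.  Cell ``k`` (1-based)
    is centred ``blanking_m + (k - 0.5) * cell_size_m`` above the
    transducer, hence ``instrument_height_m`` higher above the seabed.
    """

    station: str
    seafloor_depth_m: float
    n_cells: int
    instrument_height_m: float = 0.5
    blanking_m: float = 0.2
    cell_size_m: float = 0.5

    def cell_height_above_bed(self, cell_index: int) -> float:
        """Height of a cell centre above the seabed, in metres."""
        return (
            self.instrument_height_m
            + self.blanking_m
            + (cell_index - 0.5) * self.cell_size_m
        )

    def cell_depth_below_surface(self, cell_index: int) -> float:
        """Depth of a cell centre below the nominal sea surface, in metres.

        Negative values mean the cell lies above the surface (side-lobe
        contaminated range that the instrument still records).
        """
        return self.seafloor_depth_m - self.cell_height_above_bed(cell_index)


#: Two-station layout used throughout: A on a 6.5 m bottom with 13 half-metre
#: cells, B on an 8 m bottom with 16, both with a 0.2 m blanking distance.
DEFAULT_GEOMETRY: dict[str, StationGeometry] = {
    "A": StationGeometry("A", seafloor_depth_m=6.5, n_cells=13),
    "B": StationGeometry("B", seafloor_depth_m=8.0, n_cells=16),
}


@dataclass(frozen=True)
class QcBounds:
    """Plausible-range quality control for raw CTD samples.

    Defaults bracket tropical reef conditions with a wide margin; rows
    outside either range are dropped (and counted) at read time.
    """

    temperature_c: tuple[float, float] = (15.0, 40.0)
    salinity_psu: tuple[float, float] = (30.0, 45.0)


@dataclass
class Climatology:
    """Maximum Monthly Mean (MMM) baseline for HotSpot computation.

    ``mmm_c`` is the long-term mean temperature of the climatologically
    hottest month.  It may be supplied directly (``source='configured'``)
    or derived from a multi-year daily series (``source='computed'``),
    in which case ``monthly_means_c`` holds the 12 calendar-month means
    (index 0 = January) and ``mmm_c`` equals their maximum.
    """

    mmm_c: float
    source: str = "configured"
    reference_period: tuple[int, int] | None = None
    monthly_means_c: list[float] | None = None

    def __post_init__(self) -> None:
        if self.source not in ("configured", "computed"):
            raise ConfigError(f"unknown climatology source {self.source!r}")
        if not (20.0 <= self.mmm_c <= 35.0):
            import warnings

            warnings.warn(
                f"MMM {self.mmm_c:.2f} degC outside the plausible 20-35 degC "
                "range for a tropical reef application",
                stacklevel=2,
            )


@dataclass(frozen=True)
class RoseConfig:
    """Binning conventions for current roses.

    ``n_dir`` equal direction sectors partition the circle.  ``sector_origin``
    is ``'edge'`` (sector 0 spans [0, width)) or ``'center'`` (sector 0
    centred on north).  Speeds below ``calm_floor_ms`` count as calm and
    are reported as a single calm fraction rather than binned.
    """

    n_dir: int = 16
    speed_breaks_ms: tuple[float, ...] = (0.0, 0.05, 0.1, 0.2, 0.4, float("inf"))
    calm_floor_ms: float = 0.01
    sector_origin: str = "edge"

    def __post_init__(self) -> None:
        if self.n_dir < 1:
            raise ConfigError(f"n_dir must be positive, got {self.n_dir}")
        if self.sector_origin not in ("edge", "center"):
            raise ConfigError(f"unknown sector_origin {self.sector_origin!r}")
        if list(self.speed_breaks_ms) != sorted(self.speed_breaks_ms):
            raise ConfigError("speed_breaks_ms must be increasing")
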