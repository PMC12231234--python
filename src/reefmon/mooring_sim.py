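"""Synthetic mooring data with a ground-truth ledger.

Generates CTD burst samples and ADCP ensembles with the statistical
structure the reduction pipeline assumes — seasonal harmonic plus small
diurnal cycle, AR(1) noise at burst cadence with white per-sample noise
on top, overlapping deployments, sensor gaps, and rectangular marine
heatwave excursions pinned at a known height above the generating
climatology's MMM — so that every downstream stage can be checked
against closed-form truth without any field data.

During a heatwave of amplitude ``a`` the noise-free daily mean is held at
exactly ``MMM + a``, so a heatwave of duration ``d`` days produces a peak
rDHW of ``a * min(d, 84) / 7`` degC-weeks (for ``a >= 1``); the ledger
records this per event.  Outside heatwaves the seasonal baseline tops out
essentially at the MMM (the hottest-month mean), so its HotSpots stay
below the 1 degC gate and do not contaminate the closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from . import timeseries_io
from .types import DEFAULT_GEOMETRY, StationGeometry

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class Heatwave:
    """Rectangular excursion holding daily-mean temperature at MMM + amplitude."""

    start: str  # ISO date
    duration_days: int
    amplitude_above_mmm_c: float


@dataclass(frozen=True)
class Gap:
    """Interval with no data from one station (instrument out of water)."""

    station: str
    start: str  # ISO date
    end: str  # ISO date, exclusive


@dataclass(frozen=True)
class CurrentRegime:
    """Wrapped-unimodal direction / skewed-speed regime for one layer.

    ``mean_direction_deg`` is direction-toward (oceanographic convention);
    ``concentration`` plays the role of a von Mises kappa (spread of the
    wrapped-normal deviate is ``1/sqrt(concentration)`` radians);
    ``speed_scale_ms`` scales a positively skewed (gamma) speed draw with
    unit mean.
    """

    mean_direction_deg: float
    concentration: float
    speed_scale_ms: float


@dataclass
class SyntheticScenario:
    """Declarative description of a synthetic deployment.

    Temperature model (degC), evaluated at sample timestamps ``t``::

        T(t) = annual_mean
             + annual_amplitude * cos(2 pi (doy - peak_doy) / 365.25)
             + diurnal_amplitude * cos(2 pi (hour - peak_hour) / 24)
             + AR(1) burst noise + white sample noise

    with heatwave days replaced as described in the module docstring.
    ``diurnal_amplitude`` below 0.5 degC keeps the daily range under
    1 degC, matching a deep-ish reef mooring regime.
    """

    start: str = "2021-06-01"
    end: str = "2021-12-31"
    stations: dict[str, StationGeometry] = field(
        default_factory=lambda: dict(DEFAULT_GEOMETRY)
    )
    annual_mean_c: float = 28.5
    annual_amplitude_c: float = 4.5
    peak_doy: int = 227  # mid-August thermal peak
    diurnal_amplitude_c: float = 0.3
    diurnal_peak_hour: float = 15.0
    ar1_phi: float = 0.8
    ar1_sd_c: float = 0.05
    sample_sd_c: float = 0.02
    salinity_mean_psu: float = 39.07
    salinity_sd_psu: float = 0.05
    gaps: list[Gap] = field(default_factory=list)
    heatwaves: list[Heatwave] = field(default_factory=list)
    current_regimes: dict[str, CurrentRegime] = field(
        default_factory=lambda: {
            # NW-to-SE wind-driven surface flow, weaker reversed bottom flow
            "surface": CurrentRegime(135.0, 8.0, 0.12),
            "bottom": CurrentRegime(315.0, 4.0, 0.05),
        }
    )
    burst_interval_min: int = 30
    samples_per_burst: int = 10
    sample_spacing_s: float = 2.0
    deployment_length_days: int = 180
    deployment_overlap_days: int = 2
    utc_offset_hours: float = timeseries_io.DEFAULT_UTC_OFFSET_H
    seed: int = 42

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stations"] = {k: asdict(v) for k, v in self.stations.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticScenario":
        d = dict(d)
        if "stations" in d:
            d["stations"] = {k: StationGeometry(**v) for k, v in d["stations"].items()}
        if "gaps" in d:
            d["gaps"] = [g if isinstance(g, Gap) else Gap(**g) for g in d["gaps"]]
        if "heatwaves" in d:
            d["heatwaves"] = [
                h if isinstance(h, Heatwave) else Heatwave(**h) for h in d["heatwaves"]
            ]
        if "current_regimes" in d:
            d["current_regimes"] = {
                k: v if isinstance(v, CurrentRegime) else CurrentRegime(**v)
                for k, v in d["current_regimes"].items()
            }
        return cls(**d)


def default_scenario(**overrides) -> SyntheticScenario:
    """The reef-like reference scenario used in docs and reports.

    Two and a half years of two-station monitoring with a severe 70-day
    late-summer heatwave in the final year, a short winter service gap at
    each station, and the hydrographic regime of a hot, very saline sea:
    annual mean 28.5 degC with 4.5 degC seasonal amplitude (daily means
    ~24-33 degC), salinity near 39.07 PSU.  All values are generator
    parameters, not measurements.
    """
    base = dict(
        start="2021-06-01",
        end="2023-12-31",
        gaps=[
            Gap("A", "2022-01-10", "2022-01-17"),
            Gap("B", "2022-11-03", "2022-11-08"),
        ],
        heatwaves=[Heatwave("2023-08-05", 70, 2.2)],
        seed=42,
    )
    base.update(overrides)
    return SyntheticScenario(**base)


def load_scenario(path) -> SyntheticScenario:
    import yaml

    with open(path) as fh:
        return SyntheticScenario.from_dict(yaml.safe_load(fh))


def save_scenario(scenario: SyntheticScenario, path) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(scenario.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# deterministic truth (no noise)
# ---------------------------------------------------------------------------

def _seasonal(doy: np.ndarray, sc: SyntheticScenario) -> np.ndarray:
    return sc.annual_mean_c + sc.annual_amplitude_c * np.cos(
        2 * np.pi * (doy - sc.peak_doy) / DAYS_PER_YEAR
    )


def _diurnal(hour: np.ndarray, sc: SyntheticScenario) -> np.ndarray:
    return sc.diurnal_amplitude_c * np.cos(2 * np.pi * (hour - sc.diurnal_peak_hour) / 24.0)


def true_mmm(scenario: SyntheticScenario) -> float:
    """MMM of the generating climatology: max calendar-month mean of the
    seasonal harmonic (heatwaves and noise are anomalies, not climate)."""
    doy = np.arange(1, 366, dtype=float)
    months = pd.date_range("2022-01-01", "2022-12-31", freq="D").month
    temp = _seasonal(doy, scenario)
    return float(pd.Series(temp).groupby(pd.Index(months)).mean().max())


def _burst_grid(scenario: SyntheticScenario) -> pd.DatetimeIndex:
    # anchored to local midnight so every local calendar day of the scenario
    # is covered by a complete set of bursts
    shift = pd.Timedelta(hours=scenario.utc_offset_hours)
    return pd.date_range(
        pd.Timestamp(scenario.start, tz="UTC") - shift,
        pd.Timestamp(scenario.end, tz="UTC") + pd.Timedelta(days=1) - shift,
        freq=f"{scenario.burst_interval_min}min",
        inclusive="left",
    )


def _noise_free_burst_temp(
    grid: pd.DatetimeIndex, scenario: SyntheticScenario, mmm: float
) -> np.ndarray:
    doy = grid.dayofyear.to_numpy(dtype=float)
    hour = grid.hour.to_numpy(dtype=float) + grid.minute.to_numpy(dtype=float) / 60.0
    temp = _seasonal(doy, scenario) + _diurnal(hour, scenario)
    for hw in scenario.heatwaves:
        # heatwave dates are local calendar days, so each affected local day
        # is fully inside the event and the a*d/7 ledger value is exact
        t0 = pd.Timestamp(hw.start, tz="UTC") - pd.Timedelta(hours=scenario.utc_offset_hours)
        t1 = t0 + pd.Timedelta(days=hw.duration_days)
        mask = (grid >= t0) & (grid < t1)
        temp[mask] = mmm + hw.amplitude_above_mmm_c + _diurnal(hour[mask], scenario)
    return temp


@dataclass
class GroundTruthLedger:
    """Everything the tests need to verify the pipeline end to end.

    ``daily`` has the noise-free per-local-day ``true_st_mean`` /
    ``true_st_max`` (no gaps applied — truth exists even where sensors
    were out).  ``heatwave_peak_rdhw`` lists the expected peak rDHW
    contribution ``a * min(d, 84) / 7`` per scripted event.  The ledger
    is a pure function of scenario + seed and can always be regenerated.
    """

    mmm_c: float
    daily: pd.DataFrame
    heatwave_peak_rdhw: list[float]
    record_counts: dict[str, int]


def ground_truth(scenario: SyntheticScenario) -> GroundTruthLedger:
    mmm = true_mmm(scenario)
    grid = _burst_grid(scenario)
    temp = _noise_free_burst_temp(grid, scenario, mmm)
    local_day = (grid + pd.Timedelta(hours=scenario.utc_offset_hours)).tz_localize(None).normalize()
    df = pd.DataFrame({"date": local_day, "temp": temp})
    daily = (
        df.groupby("date")
        .agg(true_st_mean=("temp", "mean"), true_st_max=("temp", "max"))
        .reset_index()
    )
    peaks = [
        hw.amplitude_above_mmm_c * min(hw.duration_days, 84) / 7.0 for hw in scenario.heatwaves
    ]
    return GroundTruthLedger(mmm_c=mmm, daily=daily, heatwave_peak_rdhw=peaks, record_counts={})


# ---------------------------------------------------------------------------
# CTD generation
# ---------------------------------------------------------------------------

def _ar1(n: int, phi: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    if n == 0:
        return np.zeros(0)
    eps = rng.normal(0.0, sd, size=n)
    if phi > 0:
        # stationary start so early bursts are not artificially quiet
        eps[0] = rng.normal(0.0, sd / np.sqrt(1.0 - phi**2))
        return lfilter([1.0], [1.0, -phi], eps)
    return eps


def _gap_mask(grid: pd.DatetimeIndex, scenario: SyntheticScenario, station: str) -> np.ndarray:
    """True where the station is recording (outside its gaps)."""
    keep = np.ones(len(grid), dtype=bool)
    for gap in scenario.gaps:
        if gap.station != station:
            continue
        t0 = pd.Timestamp(gap.start, tz="UTC")
        t1 = pd.Timestamp(gap.end, tz="UTC")
        keep &= ~((grid >= t0) & (grid < t1))
    return keep


def _deployment_ids(grid: pd.DatetimeIndex, scenario: SyntheticScenario, station: str):
    """Yield (deployment_id, mask over grid) with overlapping handovers."""
    start = grid[0]
    end = grid[-1]
    length = pd.Timedelta(days=scenario.deployment_length_days)
    overlap = pd.Timedelta(days=scenario.deployment_overlap_days)
    d = 0
    while True:
        d0 = start + d * length
        if d0 > end:
            break
        lo = d0 - (overlap if d > 0 else pd.Timedelta(0))
        hi = d0 + length
        mask = (grid >= lo) & (grid < hi)
        if mask.any():
            yield f"{station}-dep{d + 1:02d}", mask
        d += 1


def generate_ctd(
    scenario: SyntheticScenario,
) -> tuple[dict[str, pd.DataFrame], GroundTruthLedger]:
    """Generate raw CTD sample records per station plus the truth ledger.

    Stations share the same noise-free signal (the site has no
    between-station temperature difference) but carry independent noise.
    Returns records in the column contract of :mod:`reefmon.timeseries_io`.
    """
    ledger = ground_truth(scenario)
    grid = _burst_grid(scenario)
    base = _noise_free_burst_temp(grid, scenario, ledger.mmm_c)
    out: dict[str, pd.DataFrame] = {}
    for si, station in enumerate(sorted(scenario.stations)):
        rng = np.random.default_rng([scenario.seed, 11, si])
        burst_noise = _ar1(len(grid), scenario.ar1_phi, scenario.ar1_sd_c, rng)
        burst_temp = base + burst_noise
        keep = _gap_mask(grid, scenario, station)
        frames = []
        for dep_id, dep_mask in _deployment_ids(grid, scenario, station):
            mask = dep_mask & keep
            n_b = int(mask.sum())
            if n_b == 0:
                continue
            k = scenario.samples_per_burst
            t0 = np.repeat(grid[mask].values, k)
            offsets = np.tile(
                (np.arange(k) * scenario.sample_spacing_s * 1e9).astype("timedelta64[ns]"),
                n_b,
            )
            temp = np.repeat(burst_temp[mask], k) + rng.normal(
                0.0, scenario.sample_sd_c, size=n_b * k
            )
            sal = rng.normal(scenario.salinity_mean_psu, scenario.salinity_sd_psu, size=n_b * k)
            frames.append(
                pd.DataFrame(
                    {
                        "timestamp": pd.DatetimeIndex(t0 + offsets, tz="UTC"),
                        "temperature_c": temp,
                        "salinity_psu": sal,
                        "station": station,
                        "deployment": dep_id,
                    }
                )
            )
        records = (
            pd.concat(frames, ignore_index=True)
            .sort_values(["timestamp", "deployment"], kind="mergesort")
            .reset_index(drop=True)
        )
        ledger.record_counts[f"ctd_{station}"] = len(records)
        out[station] = records
    return out, ledger


# ---------------------------------------------------------------------------
# ADCP generation
# ---------------------------------------------------------------------------

def _circular_interp(dir_bottom: float, dir_surface: float, w: float) -> float:
    """Interpolate two bearings along the shorter arc (w=0 -> bottom)."""
    d0 = np.deg2rad(dir_bottom)
    d1 = np.deg2rad(dir_surface)
    v = (1 - w) * np.array([np.sin(d0), np.cos(d0)]) + w * np.array([np.sin(d1), np.cos(d1)])
    return float(np.rad2deg(np.arctan2(v[0], v[1]))) % 360.0


def generate_adcp(
    scenario: SyntheticScenario,
) -> tuple[dict[str, pd.DataFrame], dict[str, int]]:
    """Generate long-format ADCP ensembles per station.

    Each cell's regime interpolates between the bottom and surface
    regimes by relative height.  Depth correlation comes from shared
    per-ensemble deviates: a wrapped-normal angular offset and a gamma
    speed factor common to the whole profile, with small per-cell jitter.
    """
    bottom = scenario.current_regimes["bottom"]
    surface = scenario.current_regimes["surface"]
    out: dict[str, pd.DataFrame] = {}
    counts: dict[str, int] = {}
    grid_full = _burst_grid(scenario)
    for si, station in enumerate(sorted(scenario.stations)):
        geom = scenario.stations[station]
        rng = np.random.default_rng([scenario.seed, 23, si])
        keep = _gap_mask(grid_full, scenario, station)
        grid = grid_full[keep]
        n_ens = len(grid)
        cells = np.arange(1, geom.n_cells + 1)
        heights = np.array([geom.cell_height_above_bed(c) for c in cells])
        w = np.clip(heights / geom.seafloor_depth_m, 0.0, 1.0)
        mean_dir = np.array(
            [
                _circular_interp(bottom.mean_direction_deg, surface.mean_direction_deg, wi)
                for wi in w
            ]
        )
        kappa = (1 - w) * bottom.concentration + w * surface.concentration
        scale = (1 - w) * bottom.speed_scale_ms + w * surface.speed_scale_ms
        sigma_deg = np.rad2deg(1.0 / np.sqrt(np.maximum(kappa, 1e-12)))
        # shared profile deviates -> vertical correlation
        z = rng.normal(size=n_ens)
        g = rng.gamma(shape=2.0, scale=0.5, size=n_ens)
        # per-cell jitter shrinks with concentration so a degenerate regime
        # (kappa -> inf) collapses onto the mean direction exactly
        jitter_dir = rng.normal(size=(n_ens, geom.n_cells)) * (sigma_deg / 4.0)[None, :]
        jitter_spd = rng.lognormal(mean=0.0, sigma=0.15, size=(n_ens, geom.n_cells))
        direction = np.mod(
            mean_dir[None, :] + z[:, None] * sigma_deg[None, :] + jitter_dir, 360.0
        )
        speed = scale[None, :] * g[:, None] * jitter_spd
        df = pd.DataFrame(
            {
                "timestamp": np.repeat(grid.values, geom.n_cells),
                "station": station,
                "cell_index": np.tile(cells, n_ens),
                "height_m": np.tile(heights, n_ens),
                "speed_ms": speed.ravel(),
                "direction_deg": direction.ravel(),
            }
        )
        df["timestamp"] = pd.DatetimeIndex(df["timestamp"], tz="UTC")
        out[station] = df
        counts[f"adcp_{station}_ensembles"] = n_ens
        counts[f"adcp_{station}_rows"] = len(df)
    return out, counts


def generate_files(scenario: SyntheticScenario, out_dir) -> GroundTruthLedger:
    """Write per-station CTD/ADCP CSV files and the scenario to a directory."""
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ctd, ledger = generate_ctd(scenario)
    for station, df in ctd.items():
        timeseries_io.write_ctd(df, out_dir / f"ctd_{station}.csv")
    adcp, counts = generate_adcp(scenario)
    for station, df in adcp.items():
        timeseries_io.write_adcp(df, out_dir / f"adcp_{station}.csv")
    ledger.record_counts.update(counts)
    save_scenario(scenario, out_dir / "scenario.yaml")
    return ledger
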