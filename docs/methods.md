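# Methods

## Reduction of burst-sampled mooring records

Moored CTD probes record bursts of 10 rapid samples every 30 minutes;
two stations (A on a 6.5 m bottom, B on 8 m) run overlapping deployments
so the site is never unmonitored. The reduction is strictly
hierarchical: samples → burst means → per-station daily statistics →
station-combined daily summary. Averaging bursts before days keeps a
burst with a failed sample from being over- or under-weighted, and
averaging stations at the daily level keeps a station outage on part of
a day from biasing the combined mean.

Conventions that the data do not determine by themselves, and the
choices made here:

- **Burst grid.** Slots are anchored at :00/:30 past each hour; a sample
  belongs to the half-open 30-minute slot containing its timestamp. The
  instruments define a cadence, not an anchoring, so the grid is a
  package convention.
- **Overlapping deployments.** When two deployments of one station cover
  the same slot, per-deployment burst means are merged with equal
  weight. A station duplicated wholesale under a second deployment id
  therefore reproduces the single-deployment result exactly.
- **Station merge.** Default policy `mean`: daily mean = mean of station
  daily means, daily max = max of station maxima, daily min = min of
  station minima. The alternative `pool` policy pools all bursts before
  the daily statistics; both are exposed because either reading of
  "combining both locations" is defensible when the stations track each
  other closely.
- **Day boundaries.** Timestamps are stored in UTC; calendar days are
  defined at a configurable UTC offset, default +03:00 (Arabia Standard
  Time), because daily extrema depend on where midnight falls.
- **Quality control.** Plausible-range screening only (defaults
  15–40 °C, 30–45 PSU, configurable), dropping and counting offending
  rows. Calibration and despiking belong to the instrument lab, not to
  this pipeline.

## Climatology

The MMM baseline can be configured directly or computed from a
multi-year daily series as the maximum of the 12 calendar-month means
(every month must be represented). A configured value takes precedence
— monitoring deployments are usually too short to carry their own
climatology, so the baseline is typically an external, documented
choice, and the report's provenance block always records the value used.
No satellite-era recentering is applied: the index here is built on
in-situ bottom temperature, and that adjustment is specific to satellite
SST products.

## Heat stress index

`HS_j = ST_j − MMM` per day (mean or max basis);
`rDHW_i = Σ_{j=i−83..i} HS_j·1[HS_j ≥ 1] / 7` °C-weeks. Numerical
conventions:

- The window is 84 days inclusive of both endpoints; a single day at
  HS = 7 °C contributes exactly 1 °C-week.
- The 1 °C gate is applied per day before summation; HS = 1.0 exactly
  contributes its full 1.0.
- Missing days contribute zero to every window they fall in. Each day
  carries `window_coverage` (fraction of its 84-day window with data)
  and a `low_coverage` flag below 0.9. The default warm-up policy is
  permissive — rDHW is reported from day one over the partial window —
  with a strict mode that leaves the first 83 days undefined; permissive
  matches how an operational product ramps up, strict is available for
  analyses that must not understate early uncertainty.
- Alert bins are left-closed/right-open at 4/8/12/16/20 °C-weeks on the
  extended (post-2023) Coral Reef Watch scale; levels 2–5 are driven by
  rDHW alone, Warning/Level 1 additionally require the day's HS ≥ 1.
- Reported rDHW values are rounded half-even to one decimal.
- "Consecutive weeks above a threshold" tiles 7-day blocks forward from
  the first exceedance day and counts the longest run of complete blocks
  whose weekly maximum exceeds the threshold; an ISO-calendar-week mode
  is provided because "week" is genuinely ambiguous. The mode used is
  recorded in the report.

The implementation satisfies, and the test suite enforces, the order
properties that make the index trustworthy: warming any day never
lowers any rDHW; the max basis dominates the mean basis pointwise;
raising the MMM never raises rDHW; and editing a day outside a window
cannot affect it.

## Currents

ADCP profilers sit on the bottom frames looking up, with 0.5 m cells
after a 0.2 m blanking distance (13 usable cells at station A, 16 at B).
Cell *k* is centred `0.5 + 0.2 + (k − 0.5)·0.5` m above the bed (the
0.5 m being the instrument's height on its frame). The **bottom** layer
is the cell nearest 1 m above the seabed (cell 1 at both stations); the
**surface** layer is the uppermost cell at least 0.5 m below the nominal
surface (cell 11 at A, cell 14 at B), a geometry-based guard against
side-lobe contamination — a stated convention rather than a universal
criterion.

Roses default to 16 sectors of 22.5° starting at north
(centre-on-north selectable), speed classes 0–0.05–0.1–0.2–0.4–∞ m s⁻¹,
and a 0.01 m s⁻¹ calm floor reported as a separate calm fraction so
every non-empty table closes to 100 %. Seasons are meteorological
quarters; winter (DJF) is labelled by the year of its January/February,
so December rolls into the following winter.

## Synthetic scenarios and what they do (not) show

The generator emulates the statistical structure the reduction assumes:
a seasonal harmonic (default annual mean 28.5 °C, amplitude 4.5 °C,
peak at day 227) plus a diurnal harmonic (0.3 °C, keeping the daily
range under 1 °C), AR(1) noise at burst cadence (φ = 0.8, innovation
0.05 °C) with white per-sample noise (0.02 °C) on top — so both
averaging stages are genuinely exercised — salinity near 39.07 PSU,
deployment handovers with 2-day overlaps, scripted gaps, and
rectangular heatwaves. Heatwave days (local calendar days) hold the
noise-free daily mean at exactly MMM + a, so each event's peak rDHW has
the closed form `a·min(d, 84)/7` recorded in the ground-truth ledger;
the generating MMM is the hottest calendar-month mean of the seasonal
harmonic. Currents come from wrapped-normal directions and gamma speeds
interpolated between a bottom regime (toward 315°, 0.05 m s⁻¹ scale)
and a wind-driven surface regime (toward 135°, 0.12 m s⁻¹ scale), with
per-ensemble shared deviates providing vertical correlation.

The reference scenario spans 2021-06-01 to 2023-12-31 with one 70-day
heatwave at 2.2 °C above MMM starting 2023-08-05 — a severe late-summer
event of the magnitude that drives mass-bleaching alerts (peak rDHW
22 °C-weeks class). All of these numbers are generator parameters
chosen to be realistic for a hot, very saline reef sea; they are not
measurements.

What passing on synthetic data does **not** show: real moorings have
biofouling drift, despiking needs, tidal and weather-band variability,
seasonally varying current regimes (the generator's regimes are
season-invariant), and calibration offsets between deployments. The
pipeline's correctness on its stated conventions transfers; claims
about any real site require running it on that site's records.

## Degenerate inputs and edge behaviour

Empty inputs yield empty outputs (reads of fully invalid files raise);
an empty seasonal rose subset is a flagged empty table, not an error; a
single-cell profile serves both layers with a warning; direction 360°
normalises to 0°; days where max − min exceeds 1 °C are warned about
(the site's regime makes them suspicious) but kept. Pipeline runs are
deterministic given a seed: reports are byte-identical apart from their
generation timestamp.

## Problem sizes

The reference scenario produces ~910,000 CTD samples and ~1.3 million
ADCP cell rows, reduced in a few seconds; tests use scenarios of two
weeks to one year so the whole suite runs in well under a minute.
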