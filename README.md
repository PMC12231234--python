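# reefmon

Environmental surveillance analysis for moored coral-reef monitoring
stations: reduces burst-sampled CTD and ADCP records to daily summaries,
computes the **relative Degree Heating Weeks (rDHW)** thermal-stress index
and the Coral Reef Watch style bleaching-alert timeline from in-situ
bottom temperature, and summarises seasonal current regimes as
direction/speed roses.

It is written for reef monitoring programmes that keep CTD probes and
acoustic Doppler current profilers (ADCPs) permanently moored on a reef:
the instruments produce bursts of rapid samples every 30 minutes across
overlapping deployments at multiple stations, and the scientific questions
— *is the reef accumulating bleaching-level heat stress, and what is the
flow regime carrying larvae, nutrients, or treatments across the site?* —
need those records turned into a small set of defensible daily statistics.

## The statistic at the core

Daily bottom temperature is compared against the **Maximum Monthly Mean**
(MMM), the long-term mean temperature of the climatologically hottest
month. The daily **HotSpot** on day *j* is

```
HS_j = ST_j − MMM            ST_j = daily mean (STmean) or daily maximum (STmax)
```

and the relative Degree Heating Weeks on day *i* accumulates the
HotSpots of at least 1 °C over the trailing 12 weeks (84 days),
converted from °C-days to °C-weeks:

```
rDHW_i = ( Σ_{j = i−83}^{i}  HS_j · 1[HS_j ≥ 1] ) / 7
```

"Relative" marks the use of in-situ temperature measured at the reef
(here 6.5–8 m deep) instead of the satellite sea-surface temperature of
the operational DHW product; the two are methodologically parallel but
not numerically comparable. Alert categories follow the extended
Coral Reef Watch scale: **No Stress** (HS ≤ 0), **Watch** (0 < HS < 1),
**Warning** (HS ≥ 1, rDHW < 4), **Alert Level 1** (HS ≥ 1, 4 ≤ rDHW < 8),
and **Alert Levels 2–5** at rDHW ≥ 8, 12, 16, 20 °C-weeks regardless of
the day's HotSpot.

Current directions follow the oceanographic convention (bearing the flow
is going **toward**); roses are joint direction × speed frequency tables
per station, depth layer, season, and year.

## Worked example

The numbered drivers under `analysis/` run the whole study on the
package's reference synthetic deployment (2.5 years, two stations, one
severe 70-day late-summer heatwave scripted at 2.2 °C above the MMM —
expected peak rDHW 2.2 × 70 / 7 = 22.0 °C-weeks):

```bash
python analysis/01_simulate.py   # raw CTD/ADCP CSVs + ground-truth ledger
python analysis/02_reduce.py    # burst averaging + daily station merge
python analysis/03_heatstress.py
python analysis/04_currents.py
python analysis/05_report.py    # orchestrated end-to-end report bundle
```

`03_heatstress.py` prints, among other lines:

```
climatology MMM: 32.946 degC (generator ground truth)
rDHW_STmean: peak 22.0 degC-weeks on 2023-10-13
rDHW_STmax: peak 26.1 degC-weeks on 2023-10-13
alert-day counts 2023 (STmax basis): {'NoStress': 217, 'Watch': 16, 'Warning': 10,
    'AL1': 11, 'AL2': 22, 'AL3': 21, 'AL4': 21, 'AL5': 47}
longest run with weekly max rDHW_STmax > 8 degC-weeks: 16 weeks
```

The STmean peak lands exactly on the scripted 22.0 °C-weeks — the
heatwave is the only signal clearing the 1 °C gate on the mean basis —
while the STmax series accumulates extra gated HotSpots from daily
maxima around the event and therefore peaks higher, illustrating why the
two bases are reported separately. Intermediate tables land in
`results/`, raw synthetic data in `scratch/data/`.

The same computations are available programmatically
(`reefmon.timeseries_io`, `reefmon.climatology`, `reefmon.heatstress`,
`reefmon.currents`, `reefmon.mooring_sim`, `reefmon.reporting`) and
through the `reefmon` CLI (`simulate`, `reduce ctd|adcp`, `dhw`,
`report`, `run`), which accepts real instrument exports in the same
header-driven CSV formats.

## Documentation

`docs/methods.md` describes the model, the reduction conventions (burst
grid anchoring, station-merge policies, local-day boundaries), the
generator's scope and limitations, and the numerical choices.
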