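# parkdelta

Does a patch of urban vegetation actually lower the particulate-matter
exposure of the people next to it?  `parkdelta` answers that question
for the now-common measurement design of a pair of low-cost optical PM
sensors — one inside a vegetated area ("park"), one at the adjacent
roadside — by turning their raw dual laser-channel logs into defensible
mitigation statistics.

The package implements the full analysis chain for this design:

1. **QA/QC cascade** for dual-channel optical sensors: PM2.5 detection
   limit (default 1.5 µg/m³ on the A/B channel mean), relative-humidity
   cap (readings above 95 % removed), functional temperature range
   (−17 to 54 °C), hourly aggregation requiring at least 12 of the 30
   possible 2-minute readings, the two-regime A/B channel agreement
   rule (below 25 µg/m³ the channels must agree within 5 µg/m³ *and*
   20 %; above, within 20 %), and simultaneity pairing of the two
   sensors — with a cleaning ledger recording the count removed at each
   step.
2. **Background removal**: per sensor and pollutant, the background is
   the 10th percentile (p10) of overnight (00–03 h) hourly values;
   hours below it are discarded and it is subtracted from the rest,
   isolating the local (traffic) enhancement.
3. **Mitigation statistics**: per paired hour, Δ = road − park for
   PM1/PM2.5/PM10 and the meteorological variables, with the percent
   form 100·Δ/road; means by site-specific period of day
   (overnight/daytime/evening) and by 16-point compass wind sector;
   diurnal profiles and per-sector percentile roses of ΔPM2.5.
4. **Stepwise regression** of ΔPM2.5 on the candidate predictors
   {T, H, P} × {park, road} ∪ {WD, WS}: bidirectional selection from
   the full model by information criterion (AIC default, BIC
   available), run on the full hourly data and on the 24-row
   hour-of-day-averaged data.
5. **Lidar site characterisation**: vegetation/building footprint area
   and mean height above ground within a 50 m disc of each sensor,
   nearest-road distance and class, and vegetation-barrier porosity
   proxied by the modal volumetric point density (spherical
   neighbourhoods, points/m³) — a denser point cloud indicates a less
   porous barrier.
6. **Synthetic data generator** producing paired streams with known
   background curve B(h), traffic increment R(h), ground-truth
   mitigation fraction *m* (park sees B + (1−m)·R), wind, and
   data-quality artifacts injected at recorded locations — so every
   stage of the pipeline is testable against exact expected values.

## Worked example

Simulate ten days of a paired deployment, clean it, remove backgrounds,
and summarise mitigation (the `parkdelta` console script wraps the
library; every step is equally available as a function call):

```
parkdelta simulate --seed 11 --out demo
parkdelta clean --park demo/park.csv --road demo/road.csv --out demo/cleaned
parkdelta background --paired demo/cleaned/paired_hourly.csv --out demo/bg
parkdelta mitigate --paired demo/bg/paired_background_removed.csv --site fsp --out demo/mit
```

The cleaning step prints the ledger:

```
detection_limit: removed 1234, remaining 12092 readings
humidity_cap: removed 2, remaining 12090 readings
temperature_range: removed 0, remaining 12090 readings
hourly_completeness: removed 26, remaining 439 hours
ab_agreement: removed 12, remaining 427 hours
simultaneity: removed 15, remaining 412 hours
```

and these counts equal the generator's injected-artifact record
(`demo/truth.json`) exactly.  The background step reports, e.g.,
`road pm25: background 11.82 ug/m3`, and the mitigation summary shows
the daytime rows

```
daytime  pm25  mean_delta 2.16  mean_pct 30.7  n_hours 80
```

i.e. the roadside sensor ran about 2.2 µg/m³ (31 % of its
background-removed concentration) above the park sensor during daytime
hours — the generator's ground truth is m = 0.25 of the road's traffic
increment, and the closed-form expectation of the daytime mean percent
under that truth is ≈ 32 %, recovered here from a fully artifact-laden
stream.

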