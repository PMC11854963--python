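# Methods

## The measurement design

Two identical low-cost optical PM monitors are co-deployed at a site:
one inside the vegetated area (park) and one at the adjacent roadside.
Each monitor carries two independent laser particle counters (the A and
B channels) whose agreement is the main internal quality signal, plus a
meteorological sensor (temperature, relative humidity, pressure).
Readings arrive every 2 minutes, so a full hour holds 30 readings.  The
analysis is entirely clock-hour based; timestamps are treated as local
time and an optional fixed UTC offset is applied once at ingest.

## Cleaning cascade

Steps are applied in a fixed order and each is tallied in a ledger
(`step, removed, remaining, unit`):

| step | rule | unit |
|---|---|---|
| detection limit | A/B-mean PM2.5 ≤ 1.5 µg/m³ removes the whole reading | 2-min readings |
| humidity cap | RH strictly above 95 % | 2-min readings |
| temperature range | outside −17…54 °C, endpoints inclusive | 2-min readings |
| hourly completeness | fewer than 12 readings in the clock hour | hours |
| A/B agreement | two-regime rule on hourly PM2.5 channel means | hours |
| simultaneity | hour present on only one side of the pair | hours |

Design choices where the rules underdetermine behaviour:

* **Detection limit basis.** The limit is defined for PM2.5 without
  naming a channel; it is applied to the A/B mean per reading, and the
  whole reading (all size fractions) is removed — the 2-minute reading
  is the atomic unit of the pre-hourly steps.
* **A/B agreement** is evaluated on hourly channel means (it sits after
  hourly averaging in the cascade), on PM2.5 only, with the percent
  difference taken against the channel mean m = (a+b)/2.  The regime
  boundary m = 25 µg/m³ is routed to the percent-only rule, closing the
  gap left by strict "<25"/">25" phrasings.  The PM2.5 verdict is
  applied hour-wise to all three size fractions, since the channels
  share optics; m = 0 passes (the channels agree at zero).  The ledger
  reports this step in hours.
* **Combined concentration** = mean of the two channel means.
* **Met variables** are averaged over whatever readings survive the
  per-reading filters in that hour; there is no separate completeness
  rule for them.
* The detection-limit and humidity filters are both per-reading
  predicates, so permuting them changes only the attribution of
  removals, never the final retained set — this is a tested property.

## Background

The background of each sensor and pollutant is the 10th percentile of
its overnight hourly values (clock hours {0, 1, 2}, i.e. midnight to
3 a.m., when traffic is minimal and the boundary layer stable).  The
percentile convention — used everywhere in the package — is linear
interpolation between order statistics at rank 1 + p·(n−1) (the numpy
default).  Hours strictly below the background are removed for that
pollutant (a value exactly at the background is kept as 0); the
background is subtracted from the rest, so outputs are ≥ 0.  Background
is a concentration concept only: T/H/P are never touched.  Removal is
applied after simultaneity pairing (switchable), per pollutant and per
side; an hour that loses a pollutant on either side drops out of that
pollutant's paired analyses.

## Mitigation statistics

Per paired hour, Δv = road_v − park_v; positive PM deltas mean cleaner
air in the park.  The percent form is road-based,
pct = 100·Δ/road, computed on background-removed PM (raw T/H/P) and
defined only where the denominator is strictly positive.  Period means
average the per-hour percent over hours (each hour weighted equally);
the mean of deltas is reported alongside because the two conventions
answer different questions and neither determines the other.  Periods
are three labeled clock-hour intervals that must partition 0–23; the
two built-in configurations (small-park: 00–09/10–18/19–23; forest
site: 00–07/08–15/16–23) reflect sites whose diurnal transitions occur
at different times.

Wind directions map to 16 compass sectors centred on the compass points
(N = 0°, half-width 11.25°); an edge tie goes to the higher sector via
floor((wd + 11.25) mod 360 / 22.5), so the assignment partitions
[0, 360) exactly.  The percentile rose reports, per sector, the
{10, 25, 50, 75, 90, 99} percentiles of ΔPM2.5 (same interpolation
convention) plus the per-sector mean percent and hour count.

A caveat the package inherits from the percent convention: in periods
where the background-removed road concentration is near zero
(overnight, by construction of the background), per-hour percentages
are unstable and can take large values of either sign even when the
mean delta is small.  Daytime percentages, the quantity of interest for
exposure, have comfortably positive denominators.

## Stepwise regression

Response: hourly ΔPM2.5.  Candidates: park and road temperature,
humidity and pressure, plus wind direction (as a linear 0–360° value —
circular encoding exists but is off by default so each predictor has a
single coefficient) and wind speed, untransformed, no interactions, no
standardisation.  Selection is bidirectional from the full model: the
single add/drop move that most reduces the information criterion is
taken until no move improves it, ties resolved toward the smaller
model; perfectly collinear columns are dropped with a warning before
selection; a perfect fit (zero residual) is treated as criterion −∞ so
the tie rule shrinks to the smallest exactly-fitting model.  Reported
coefficients are the plain OLS fit of the selected terms, so refitting
them reproduces the report exactly.

The default criterion is AIC, the common stepwise default.  AIC is
efficient but not consistent: with k pure-noise candidates it retains
each with probability P(χ²₁ > 2) ≈ 0.16, so the chance of keeping the
intercept-only model under a null response is only ≈ 0.25 at k = 8,
independent of sample size.  Checks that assert null retention or exact
selected-set recovery therefore run with BIC (penalty log n, consistent;
at n = 5000 the null model is retained ≳ 95 % of the time), and the
criterion is an explicit argument everywhere.

The same fit is run on the hour-of-day-collapsed dataset (every
variable averaged by clock hour, ≤ 24 rows).  Collapsing averages out
observation noise while preserving the shared diurnal structure, so the
selected model's R² on the collapsed data is at least the full-data R²
on generator data — a tested property.

## Lidar site characterisation

Clouds arrive classified (ground / vegetation / building / other; LAS
numeric codes 2, 3/4/5, 6 are mapped accordingly) as x,y,z,class
delimited text.  Within a disc (default radius 50 m) around the sensor,
the disc is gridded at 1 m cells; a class's area is the number of cells
containing at least one of its points times the cell area, and its
height per cell is the class's maximum z minus the ground reference
(minimum ground-class elevation in the disc — sites are locally flat;
a per-cell ground option would be needed on slopes).  Nearest-road
distance is the minimum point-to-polyline Euclidean distance over WKT
road geometries, returning the owning road's class.

Barrier porosity is proxied by volumetric point density: each point's
neighbour count within a 1 m sphere (self excluded), divided by the
sphere volume, histogrammed; the modal density is the centre of the
most populated bin, and of two barriers measured with identical bins
the one with the higher modal density is the less porous.  The 1 m
neighbourhood and 1 m grid cells resolve individual crowns at typical
airborne-lidar densities; both are configurable.  The k-d-tree
neighbour search is required to match the brute-force O(n²) reference
exactly on test clouds.  Absolute density values depend on scan density
and are not comparable across acquisitions — only the ordering of
barriers scanned together is meaningful.

## Synthetic generator

Road PM2.5 at a reading in hour h is B(h) + R(h) + ε and park PM2.5 is
B(h) + (1−m)·R(h) + ε, where B is a 24-h cosine peaking overnight
(base 9 µg/m³, amplitude 1, peak 02 h — shallow nocturnal mixing),
R is a two-Gaussian traffic profile (peaks 16 and 14 µg/m³ at 08 h and
18 h, width 3 h), m is the ground-truth mitigation (default 0.25), and
ε ~ N(0, 1.5 µg/m³).  Each channel observes the value with independent
multiplicative noise (σ = 2 %) shared across size fractions; PM1 and
PM10 are fixed ratios (0.7, 1.2) of PM2.5.  Temperature follows a
diurnal cosine (27 ± 4 °C, peak 14 h) with humidity inversely coupled;
pressure is constant plus jitter; wind draws a sector per hour from a
16-vector of probabilities with gamma-distributed speeds.  Optionally,
mitigation can be restricted to hours whose wind sector lies in a
configured "upwind" set, to emulate a road upwind of the park for only
some directions.

Artifacts are injected so the cascade can be audited exactly:

* clean readings are floored at LOD + 0.5 µg/m³ (channel-mean PM2.5)
  and their RH capped at 94 %, so only injected artifacts trip the
  first two filters;
* below-LOD readings (both channels set to ≈ 0.5 µg/m³) and RH spikes
  (> 96 %) are injected per reading inside otherwise-clean hours only,
  at most 10 per hour so no hour accidentally falls under the 12-reading
  threshold;
* short hours (thinned to 6 readings) and discordant hours (channel B
  inflated ×1.5, which fails both branches of the agreement rule) are
  injected at the same clock hour on *both* streams, so they are
  counted by their own cascade step and never leak into the
  simultaneity count; unmatched hours delete one side's hour entirely
  (alternating sides), producing exactly one simultaneity removal each;
* all whole-hour artifact types occupy mutually disjoint hours.

Default artifact rates (10 % below-LOD readings, 0.02 % RH spikes, 5 %
short hours, 2 % discordant, 7 % unmatched) are of the magnitudes seen
in year-long low-cost deployments.  Everything derives from one seeded
generator: same seed and configuration, bit-identical output.

Closed forms used by the tests come from the generator itself:
the noise-free hourly means B(h) + factor·R(h) (averaged over the 30
in-hour reading times), the implied background p10 over the overnight
window, and the implied daytime mean percent delta *after background
subtraction* — the pipeline subtracts per-sensor p10 before computing
percentages, so the consistent expectation is
mean over daytime h of 100·[m·R(h) + (q_park − q_road)] / [B(h) + R(h) − q_road],
with q the respective noise-free backgrounds.  A 30-day run recovers
this expectation to within a few percentage points; the residual gap
comes from the sampled p10 sitting slightly below its noise-free value
(hourly means carry σ_obs/√30 ≈ 0.27 µg/m³ of noise) and from
Monte-Carlo error over ~9 daytime hours × 30 days.

### What the generator does not emulate

Day-to-day synoptic variability (an optional background offset per day
is deliberately absent by default), humidity-driven optical overcount,
sensor drift, size-distribution changes (the fixed PM1:PM2.5:PM10
ratios make all three fractions' percent mitigation identical), and
wind-dependent dispersion unless the upwind-sector option is used.  Two
consequences to keep in mind when transferring conclusions to real
data: the generator's background-to-average ratio (~0.65) is higher
than typical field values (~0.35), because field backgrounds are pulled
down by between-day variability the generator omits; and passing the
recovery tests shows the *pipeline arithmetic* is right, not that a
field deployment of this size would estimate m with this precision.

## Problem sizes and numerical choices

Tests and the acceptance script use 10-day pairs (14 400 readings per
stream) for ledger audits, 30-day pairs (~600 paired hours) for
mitigation and regression recovery, 1000 random vectors for percentile
oracles, 7³ lattices and 8000-point slabs for the lidar oracles, and
100 replicates at n = 5000 for the null-retention rate — sizes at which
every expected value is sharp while a full run stays within a few
minutes on one core.  Criterion ties in stepwise selection use an
absolute tolerance of 1e−8; percentile computations delegate to
`numpy.percentile` with the linear convention stated above; the
cleaning cascade treats boundary cases exactly as listed (LOD removal
at ≤, RH removal strictly above, temperature endpoints inclusive,
completeness at ≥ 12, background removal strictly below).
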