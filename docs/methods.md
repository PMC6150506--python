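# Methods

This note documents the models, numerical choices and limitations of
`slowzone` the way a maintainer would want them written down: what each
stage assumes, which knobs matter, and what the synthetic scenarios do and
do not establish about real monitoring data.

## Geodesy and geometry

Positions are geographic (degrees); all distance-bearing computations use a
spherical Earth of radius 6371.0088 km (1 nm = 1852 m). At estuary scale
(~100 km) the sphere-vs-ellipsoid error is below 0.1%, far under AIS
positional noise, and keeps every oracle closed-form. Planar operations —
polygon clipping, gridding, gate crossings — go through a local spherical
Lambert azimuthal equal-area projection centred on the study-area centroid;
lengths within the study area are preserved to ~10⁻⁴ relative. Longitude/
latitude are used for I/O only.

Zone layouts used in tests and scenarios are synthetic rectangles laid out
like the real estuary (a west–east channel, a ~5.4-nm slow-down zone
mid-channel, a no-go area on the north side downstream of the pilot
station, island reference gates, transit-time gates at both ends); the
official zone coordinates are published on nautical notices, not in the
study, so no attempt is made to reproduce them. Zone sets read/write
GeoJSON; the measure calendar (which measures are in force on which days)
is day-resolution CSV, with the historical default: slow-down and no-go
areas June–October 2013, plus the recommended route May–October 2014–2016.

## AIS ingest

Cleaning removes, in order: fixes outside the study-area bounding box,
SOG outside [0, 35] kn, duplicate (vessel, timestamp) reports, and fixes
implying a point-to-point speed above 50 kn. The source data name these
filter categories without thresholds; the values here are deliberately
generous for merchant traffic and are keyword arguments. Cleaning is
idempotent.

Transit building groups fixes per vessel, splits passages at silent gaps
longer than 30 min, and keeps a passage only if it has ≥ 5 fixes and spans
both halves of the study area along the channel axis (the principal axis of
the study-area polygon, oriented so that positive displacement points
toward the upstream gate). The completeness rule is a declared
reconstruction — the source describes "incomplete transits" without a
criterion. Direction comes from the sign of net along-channel displacement
(upstream = toward Saint-Siméon, i.e. southwest); the measures-active flag
from the calendar at the passage mid-time. Vessels missing from the
metadata table are kept with class/flag "unknown" and logged.

Segment speed is the mean of endpoint STW rather than length/duration, so
the current correction applied at fixes propagates into every
distance-weighted statistic; length/duration stays available for QC.

## Currents and speed through water

The current field mirrors the operational product: u/v in m/s on a regular
planar grid, hourly snapshots, bilinear interpolation in space and linear
in time (NetCDF via xarray, CSV fallback for tiny fixtures). STW is the
magnitude of the ground-velocity vector (from SOG and COG) minus the
interpolated current. Course over ground stands in for heading — the real
conversion module makes the same approximation, which mis-attributes a
small crab-angle component.

The synthetic tide is a 12.42-h (semidiurnal M2) along-channel sinusoid,
default amplitude 2 kn, modulated ~40% weaker at the channel edges, with a
15% quadrature cross-channel component. The simulator integrates ship
motion against the *same discretised field* the conversion uses, so at zero
emission noise the STW round trip is exact to 1e-9 — this isolates the
conversion algebra from field-interpolation error. Emission noise is
Gaussian per ground-velocity component, default 0.36 kn, chosen so the
recovered STW error budget (~0.5–0.7 kn s.d.) matches the operational
module's stated 0.7-kn uncertainty, which is dominated by the current
model.

## Compliance indicators

All slow-down-zone indicators use STW; route-choice and no-go-area
*geometry* use the ground track (route choice is a ground property), while
the no-go speed check uses STW for symmetry. Boundary convention: a fix at
exactly the limit is compliant ("10 knots or less"); a segment is
non-compliant distance iff its speed strictly exceeds the limit.

- **I₁ strict compliance**: transit compliant iff *every* in-zone fix
  ≤ limit; denominator = transits with ≥ 1 in-zone fix; an empty
  denominator reports absent, not 0%.
- **I₄ slow-down effort**: DWAS difference between a 3-km *along-track*
  window before the first zone entry and the in-zone portion.
  Distance-weighted averages are used on both sides (the source says only
  "average speed") for consistency with I₅ and robustness to emission-rate
  bias; the along-track window realises "before entering" as a track
  property rather than a Euclidean buffer polygon.
- **I₅ DWAS**: segment speeds weighted by in-zone geodesic length, segments
  clipped exactly at zone boundaries.
- **I₆/I₇**: share of in-zone distance above the limit, and the DWAS of
  that distance only (absent when I₆ = 0).
- **I₂ NGA usage**: partial user iff the path intersects the area;
  "complete" use is not defined in the source and is operationalised as:
  the path crosses both the area's upstream and downstream chords and stays
  inside the area between them (chords are part of the zone fixture).
- **I₃ route choice**: north iff the track crosses exactly one of the two
  island reference gates (the north one); both/neither → logged
  unclassifiable and excluded from the denominator.

The portfolio aggregates per (year, active/inactive): counts, I₁, pooled I₆
(all transits' in-zone distance pooled), pooled distance-weighted I₇,
median I₅, and the share of transits slowing ≥ 1 kn. Empty periods produce
rows with zero counts and absent indicators.

## Speed models and tests

"Mixed model" here means a Gaussian linear mixed model (identity link) on
transit DWAS with a year random intercept — the published estimates are
lmer-style and the response is continuous, so no other family is
supported. Estimation is REML (statsmodels `MixedLM`); intervals and
p-values are Wald with the normal reference, matching the source's
"Wald-statistics approximation"; the REML-vs-ML and degrees-of-freedom
conventions are not stated there, so this combination is the declared
choice. The three designs: (1) active vs inactive; (2) one dummy per
active year against a common inactive intercept; (3) covariates with
reference levels tanker / no pilot / Canadian / upstream absorbed into the
intercept. Constant or aliased factors are dropped greedily (in declaration
order) with a warning after an explicit design-rank check.

The two-sample KS test wraps `scipy.stats.ks_2samp` (asymptotic p). Note
the orientation: our `alternative="greater"` means *sample a stochastically
greater than b* — its CDF lies below — which maps to scipy's `"less"`; the
year table tests whether the earlier year's speeds are stochastically
greater (compliance improving).

Simulation checks showed 95% Wald intervals covering a planted −2.8 kn
effect at ≈ 94% over replicates of the 5-year × 400-transit design —
close to nominal; the empirical coverage over only 100 replicates has
±2.2 pp noise of its own, so the test suite uses 500 replicates.

## Lethality, risk, effectiveness

The speed–lethality logistic is calibrated from the two published anchor
points (31% at 10 kn, 50% at 11.8 kn) rather than copying the original
regression coefficients, keeping the package self-contained; the resulting
curve agrees with the published one to rounding.

The gridded procedure (the published step-by-step supplement is not
available; this reconstruction follows the main text and the co-occurrence
framework it cites, with every choice config-exposed and recorded in
output metadata): 1-km square cells on the local equal-area projection;
each track segment split exactly across the cells it crosses; each cell
accumulates distance $d$ and $d\cdot P(v)$ with STW as the encounter speed
(SOG available for sensitivity); risk ∝ distance travelled, not time;
species density surfaces normalised to sum to 1 (effectiveness is invariant
to density rescaling — relative risk only); per-transit normalisation ON
when comparing periods of unequal traffic volume. Effectiveness over a
region sums cells whose centres fall inside. For single-speed fleets on a
common route over uniform density this collapses to
$100(1 - P(v_2)/P(v_1))$ exactly, which the tests use as a closed-form
oracle. Gridding conserves distance to 1e-6 relative.

Transit-time cost interpolates each gate-crossing instant linearly between
the straddling fixes and reports mean gate-to-gate minutes by direction and
period.

## Synthetic scenarios

The generator's defaults are the study conditions where stated: cruising
(inactive) speeds 14.1 ± 2.6 kn; active-period zone targets 11.3 ± 1.7 kn
(truncated above the limit so non-strict transits never plant accidental
compliance); 10% strictly compliant transits (targets drawn in
8.5–9.5 kn); ≥ 93% north-route share when the route recommendation is in
force, 90% historically; ~9.5% complete no-go-area crossings; pilotage on
all international transits and 80% of domestic ones. Emission intervals
follow max(2 s, 60 s · 6 kn / SOG) capped at 180 s plus 10% Bernoulli
dropout — enough to produce the real slow-ship over-representation without
modelling the AIS protocol. Kinematics are waypoint-following with linear
(in distance) 3-km deceleration ramps and crabbing across the current so
the ground track stays on the route; a behavioural agent model is
explicitly out of scope. Every planted quantity (true DWAS, compliance
flag, slow-down, route, covariates) goes to a truth log keyed so recovered
per-transit indicators can be joined back exactly.

Transits of each (year, period) share a ~3-day window (mid-July for active
periods, August for the pre-measure baseline year, March otherwise) so the
hourly current field stays small; the default scenario runs tens of
transits per period rather than the study's hundreds-to-thousands — chosen
so the full pipeline and suite run in minutes while leaving binomial noise
on recovered percentages small relative to the contrasts being tested.
Model-recovery scenarios (`table1_scenario`, `table5_scenario`) plant
effects directly at the transit-DWAS level at the published truths and
sample sizes (5 × 400; 2000), since the estimator consumes per-transit
DWAS regardless of how tracks were sampled.

What passing tests show — and do not. The synthetic data validate the
*computations*: bias correction, clipping, conversion algebra, estimator
calibration, risk accounting. They do not validate antenna coverage
models, real current-model error structure (only its headline magnitude),
behavioural realism of ship captains, or seasonal/interannual whale-density
dynamics (densities are static, as in the study's effectiveness analysis).

## Numerical choices and degenerate inputs

Clipping re-normalises away sub-1e-12 slivers so fractions sum to exactly
1; polygon membership uses a 1e-9-degree (geometry) or 1-m (complete-use
probe) tolerance buffer. Zero in-zone distance raises for DWAS/I₆ and
excludes the transit with a log entry; empty indicator denominators report
absent rather than zero. The lethality calibration rejects equal anchor
speeds or probabilities; effectiveness raises on a zero baseline. The
ground-speed solver floors water speed at 0.5 kn against the perpendicular
current component to avoid a stalled integration. All generator randomness
flows from one `numpy` `default_rng(seed)`; identical config + seed gives
byte-identical CSVs, and the pipeline embeds a config hash (excluding the
output path) in every report.

## Known limitations

Real zone coordinates, NMEA decoding, antenna-coverage modelling,
per-company attribution, absolute strike counts and the full current-model
error decomposition are out of scope. The 2016 no-go-area boundary
adjustment is representable only as per-year zone files. The covariate
model drops aliased factors instead of re-parameterising; with very few
years the year-variance estimate often sits on the zero boundary (handled,
with the Wald intervals then matching OLS closely).
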