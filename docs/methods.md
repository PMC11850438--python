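# Methods

## Track model and conventions

All coordinates are WGS84 decimal degrees with longitude in (-180, 180];
all timestamps are UTC, carried timezone-naive at second resolution.
Argos location classes form the closed vocabulary {3, 2, 1, 0, A, B, Z}.
Two filtering modes reflect how the classes are trusted: *stationary*
analyses (stopover detection, site centroids) use classes {3, 2, 1};
*moving* analyses (departure/arrival timing, flight speeds, wind
annotation) additionally accept {0, A, B}. Class Z is always discarded.
Duplicate timestamps keep the better class (3 > 2 > 1 > 0 > A > B; ties
keep the first occurrence) — the choice is ours; the upstream processing
of near-simultaneous Doppler fixes is not standardised.

## Geodesy

Distances are haversine on a sphere of radius **R = 6371.0088 km** (the
IUGG mean radius). At migratory leg lengths this differs from ellipsoidal
geodesics by well under 0.5%, smaller than Argos position error; absolute
path totals therefore carry a ~0.3% radius/ellipsoid ambiguity. Bearings
are initial forward azimuths on the sphere (degrees clockwise from true
north, [0, 360)); treating the per-segment bearing as constant is an
accepted approximation at these leg lengths. An ellipsoidal azimuth (as
computed by R's geosphere) differs from the spherical one by ~0.1° on a
2300-km midlatitude leg — the regression and support statistics are
insensitive at that scale.

Track interpolation assumes ground speed and direction constant within
each leg: points are placed on the great circle (vector slerp) in
proportion to elapsed time, on a grid of whole step-multiples from the
leg start, with the original fixes always preserved. Interpolation adds
no path length on a geodesic (checked to 0.1%).

## Stopover segmentation

The criterion — fixes within ~150 km for more than 2 days, bounded by
directional movements > 150 km — does not dictate an algorithm, so the
package uses the simplest deterministic one consistent with it: greedy
sequential clustering against a running mean-coordinate centroid. A
cluster closes at the first fix beyond the radius; closed clusters are
accepted when their first-to-last fix span exceeds `min_days`, and
consecutive accepted clusters closer than the radius are merged. The
procedure is order-deterministic and idempotent. Mean-coordinate
centroids are adequate because clusters are < 150 km wide and far from
the poles and antimeridian.

Durations are span-based: the 48-h transmitter gaps count toward a stay
when their bounding fixes sit in the same cluster, and the reported
duration is the whole-day calendar difference departure − arrival. With
the 10 h on / 48 h off duty cycle (58-h cycle), any stay of **5 days or
more** necessarily intersects two transmission windows at least 58 h
apart and is always detectable; an exactly-3-day stay is covered by two
windows for only ~41% of duty phases and is otherwise invisible — the
same resolution floor the transmitter schedule imposes on the real track.
One published stopover row (4→6 May printed as "3 days") is inconsistent
with the departure − arrival convention that reproduces every other row;
we treat it as an erratum and print 2.

### Phase classification

The breeding site is the stationary period longer than
`breeding_min_days` (default 46 days, the time needed for a successful
arctic breeding attempt) with the highest latitude; if none qualifies the
cycle is left without a breeding phase and a warning is logged. The
southward onset is the departure of the first post-breeding site whose
leg to the next site heads within ±45° of due south (configurable, and
overridable by an explicit date). A wider "any southward component"
band (90°–270°) was rejected: the westward Taymyr staging leg has an
initial bearing of 246°, which such a band would misclassify as the start
of southward migration even though the subsequent displacement is
dominantly zonal. First/last clusters containing the track endpoints are
treated as the wintering site and excluded from migratory stopovers.

## Wind annotation

Wind grids are 4-D (time, level, latitude, longitude) u/v fields in m/s,
levels restricted to {surface = 10 m AGL (coded 0), 1000, 850, 700,
500 mbar} (~10 m, 100 m, 1500 m, 3000 m, 5500 m asl) — a band wide
enough to bracket plausible shorebird flight heights. Files are read and
written as NetCDF (classic format via xarray's scipy engine), with CF
alias handling and normalisation of descending axes.

Support is computed from the components projected onto the track bearing
rather than from speed/direction angles, which is algebraically identical
to v_w·cos(α) under the direction-toward convention but immune to the
meteorological direction-from trap. Interpolation is trilinear (bilinear
in space, linear in time), applied to u and v independently; it
reproduces any field affine in lat/lon/time exactly and converges at
second order on smooth fields. Levels are never interpolated between —
each pressure level is analysed independently. Queries outside the grid
hull raise (single-point queries) or are skipped with a logged count
(batch annotation); silent extrapolation would corrupt support values.
Each segment is sampled once, at its great-circle midpoint at mid-time;
the alternative (endpoint sampling) differs only at second order in leg
length for smooth fields.

The multi-year climatology applies a fixed calendar window to each
year's grid, evaluates support at every path-leg midpoint for every grid
time in the window, and reports per year × level mean ± SD plus pairwise
interval-overlap flags. Route comparison densifies each waypoint route
along the great circle (default 100 km) and aggregates the same way.

## Speed models

Apparent speeds below 20 km/h are excluded before modelling (a slow
apparent speed across a 48-h gap is more likely an undetected stop);
exactly 20.0 km/h is kept, since the exclusion is strict inequality.
Segments are assigned to migration periods by their mid-time. Each
period × level model is simple OLS with intercept — coefficient, SE,
two-sided p from t(n−2), R² — fitted via statsmodels and cross-checked in
the tests against hand-coded normal equations and a permutation test.
Periods with fewer than `min_period_n` (default 5) segments are skipped,
mirroring the small-sample exclusion of the post-breeding period. Support
enters in m/s by default; the original analysis never states its
regression units, so a km/h flag is provided (slopes scale by exactly
1/3.6 and p/R² are unchanged). No multiple-testing correction is applied
across the ten models, matching the original design.

## Synthetic data

The generator realises a waypoint plan (site, arrival, departure) as a
duty-cycled Argos-like track: fixes only inside 10-h on-windows of a 58-h
cycle, hourly within a window; the bird sits at a waypoint between
arrival and departure and otherwise flies the great circle at the
constant speed the timing requires (plans needing more than the airspeed
ceiling are rejected). Position jitter is isotropic Gaussian per class —
0.25 / 0.5 / 1.5 km for classes 3/2/1 (their stated accuracy bands) and
conventional 5 / 10 / 20 km for 0/A/B. Class draws depend on behaviour:
settled fixes are mostly good classes, flight fixes mostly poor ones,
reflecting how Doppler quality collapses on a moving platform. All
generators are bit-reproducible under a fixed seed, with independent
streams for track and wind noise.

The **timetable reconstruction** plan sets the waypoints to the published
2018 site centroids and dates (arrivals at 06:00, departures at 18:00
UTC; the Altay departure and Yuncheng arrival are set to 02:00/22:00 so
the ~2329-km overnight leg stays under the 80 km/h airspeed ceiling).
Flight fixes draw only classes 0/A/B and a class-3 anchor fix is emitted
at each arrival/departure instant, so the stationary-class filter
isolates exactly the tabulated site occupancies. This is the regime under
which a date-exact timetable is recoverable at all: good-class fixes
scattered along the slow multi-day inter-site gaps would necessarily blur
cluster boundary dates.

The **recovery experiment** plants 3 stopovers of 5-9 days, 400-800 km
apart, on a broadly northward path with randomised duty phase, full class
mixes and jitter, and no anchor fixes; sites count as recovered within
50 km. Stay lengths start at 5 days deliberately — see the duty-cycle
resolution argument above; shorter plants measure the transmitter
schedule, not the detector.

**Wind plans** produce uniform, affine, or sinusoidal analytic fields
together with their closed forms, used as exact oracles for interpolation
and support. The **coupled generator** lays out segment times so that
realised ground speed equals airspeed + slope·support(+ Gaussian noise,
truncated at 1 km/h), with support taken from the closed form at the leg
midpoint in a time-constant field — the planted slope is therefore exact,
and the regression recovery experiment (100 seeds × 50 segments, noise SD
5 km/h) measures estimator calibration, observed as ~95/100 CI coverage.

### What the synthetic data does not emulate

Real Argos error is elliptical and heavy-tailed, not isotropic Gaussian;
real birds drift within stopovers, make exploratory flights and do not fly
great circles at constant speed; and the bundled wind fields are smooth
analytic stand-ins, not reanalysis extracts. Passing tests therefore
demonstrate that the algorithms are correct under the stated sampling
regime and recover known structure planted under realistic noise scales —
not that the original reanalysis-based regression coefficients are
reproduced. Those coefficients (and the published fix-based distance
totals) depend on the original telemetry deposit and an ERA5 extract,
plus unstated class-filtering and unit choices; the package exposes each
of those choices as configuration instead of guessing. The centroid-path
distances computed here are strict lower bounds on the fix-based totals.

## Problem sizes and determinism

Default experiment sizes — 50 seeded tracks for recovery, 100 seeds ×
50 segments for coverage, 10,000 samples for the formula-equivalence and
geodesy cross-checks, 2° analytic wind grids — are the package's chosen
balance of statistical resolution against run time; each completes in
seconds on one core. Every random draw flows from an explicit seed, and
`run_all` is byte-deterministic given config and inputs.
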