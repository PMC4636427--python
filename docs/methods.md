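# Methods

This note documents the statistical procedures `reefrange` implements,
the defaults it ships, the design choices that were genuinely open, and
what the synthetic-data tests do and do not demonstrate about real
telemetry data.

## Study clock and geometry

All timestamps carry one fixed UTC offset per study (default +10:00,
Australian Eastern Standard Time, no daylight-saving transitions). A
fixed offset makes calendar-day and half-hour binning reproducible and
keeps hour-of-day bins stable across the year; it deviates from
wall-clock almanac times by up to an hour during DST months, which only
relabels bins, never re-orders events.

Receiver and release positions are WGS84 decimal degrees. Planar
coordinates for COA and kernel estimation come from an equirectangular
projection centred on the array, x = R·Δλ·cos(φ₀), y = R·Δφ with
R = 6371000 m, valid within a 1° box (distortion over a few kilometres of
array is millimetric; the projection errors out beyond the box rather
than degrade silently). Great-circle distances use the haversine formula
on the same sphere radius. Each receiver keeps one fixed position across
redeployments. Where land blocks a straight line, a per-station waypoint
route can be supplied; distances are then summed along the route.

Printed coordinate strings in degrees-minutes-seconds parse via
`parse_dms`, and day/month/two-digit-year dates pivot at 2000.

## Detection quality control

1. **False-detection filter.** A detection is retained iff another
   detection of the same tag on the *same* receiver lies within ±24 h
   (closed interval). The window is a rolling neighbourhood, not a
   calendar day: calendar binning would misclassify pairs straddling
   midnight, and the rolling form makes the filter idempotent. The rule
   is applied per receiver — constant presence at station B does not
   rescue a lone record at station A.
2. **Acclimation.** Each fish's first 36 h post-tagging are dropped
   (strict `<` at the boundary: a record at exactly +36.0 h is kept).
3. **Window restriction.** Only local dates inside the study window and
   outside the excluded ranges are analysed; excluded ranges are closed
   on both ends.

The stages compose in that order, each only removes rows, and each is
individually idempotent.

## Residency

RI = distinct detected dates / available dates. Each fish's denominator
starts at the later of the window start and the date its acclimation
exclusion ends, so fish tagged after the window opens are not charged
for days they could not be detected. Residency *classification* is
finer: clock-aligned half-hour bins (:00/:30) are counted on the same
available dates, and a fish is resident iff strictly more than 65% of
bins contain a detection. Day-level RI upper-bounds the bin criterion; a
fish can be present nearly every day yet fail the bin threshold, which
is exactly the published pattern for intermittently detected fish.

MLD uses the release position recorded at tagging (not the first
detection) and depends only on the *set* of stations detected, never on
detection multiplicity.

## Centres of activity

For bin length Δt (which must divide 24 h; bins align to local
midnight), the COA is x̄ = Σnᵢxᵢ/Σnᵢ over receivers i with nᵢ detections
in the bin — the classical mean-position estimator. Weights are raw
counts with no short-interval de-duplication. Fish whose every occupied
bin involves a single receiver yield zero-variance COAs and are flagged
and excluded from kernel estimation.

The Δt diagnostic scores each candidate (default 10–60 min) by the mean
(± SE across fish) receivers and detections per *occupied* bin —
averaging over occupied bins only is a choice; all-bin averages would be
dominated by absence — and selects the smallest Δt whose mean receiver
count reaches 2. The diagnostic will score candidates such as 50 min
that the production COA path rejects (50 does not tile the day), since
its purpose is comparison, not product.

## Kernel utilization distributions

Bivariate Gaussian product kernel, one bandwidth for both axes:
h = ½(sd_x + sd_y)·n^(−1/6), the bivariate reference rule (the Silverman
constant is exactly 1 for d = 2, and this is the `href` convention of
the R home-range packages practitioners use). The bandwidth is
overridable. Density is evaluated on a grid of 10 m cells padded 3.5h
beyond the point extent and renormalised to unit mass (the padding
truncates ≤ ~0.1% of kernel mass, which renormalisation folds back).
Contour areas use density-ranked cell accumulation: sort cells by
density, count the fewest cells whose mass reaches p, multiply by cell
area. This is deterministic and adequate for area reporting;
polygonized isolines would add geometry for no statistical gain. Area
estimates change by <2% when the cell size is halved (verified in
tests).

Two systematic effects are worth knowing when comparing against analytic
truth: kernel smoothing inflates the effective variance by h²
(≈ +4–6% area at n in the thousands), and averaging positions within a
Δt bin deflates it (a bin-mean of an OU path has variance
(2τ/T)[1−(τ/T)(1−e^(−T/τ))]·σ² < σ²). At the defaults these partially
cancel; the Gaussian-oracle and OU-recovery tests below quantify the
net effect.

Seasonal splits assign points by calendar month — spawning
August–October, non-spawning January–May, the remaining four months
dropped so the seasons cannot overlap. Daily day/night 95% areas define
the "day" of date d as sunrise(d)→sunset(d); the *night* of date d joins
d's post-sunset points with d+1's pre-sunrise points, so one behavioural
night is one row (the alternative, splitting a night across two calendar
dates, would halve night sample sizes and blur the diel contrast). A
log₁₀ transform and the modelling covariates (phase, season, moon
illumination, maturity, optional water temperature) are attached for
downstream mixed modelling.

Areas are not clipped to water: with no habitat mask available the
island's land area is included in the kernel support, so very small
printed areas cannot distinguish masked from unmasked conventions. This
is a known limitation.

## Diel astronomy

Sunrise/sunset come from the NOAA solar position algorithm at zenith
90.833° (civil convention: refraction plus solar semi-diameter),
evaluated once at local solar noon; accuracy is within ~2 min of
standard ephemerides for |lat| < 66°, beyond which the code refuses to
guess. Moon illumination uses the mean synodic cycle,
(1−cos(2π·age/29.530588))/2 with age measured from the 2000-01-06 18:14 UT
new moon; true phase leads or lags the mean cycle by up to ~0.7 day, so
values are good to ~0.05 except near the quarter-phase inflections where
the curve is steepest. An external almanac table can be substituted when
exact agreement with published tables matters.

## Model support

AICc = −2logL + 2k + 2k(k+1)/(n−k−1), defined only for n > k+1.
ΔAICc is relative to the candidate minimum, weights are the normalized
relative likelihoods, support is flagged at Δ < 4, and ties order by
label so output is deterministic. Model fitting itself is out of scope
by design: the module consumes (label, logL, k, n) or AICc values from
any fitter, which keeps the selection arithmetic testable in isolation
and reusable across fitting engines. k is taken at face value from the
caller (fixed effects + variance parameters). Model averaging follows
the full-average convention (absent coefficient = 0); the relative
importance of a term is the summed weight of candidates containing it.

The paired Wilcoxon test enumerates all 2ⁿ sign assignments exactly for
up to 15 non-zero pairs (valid under ties, which get mid-ranks) and
falls back to the tie-corrected normal approximation beyond. Spearman's
ρ uses mid-ranks with exact permutation p-values for n ≤ 8 (full n!
enumeration) and the t-approximation otherwise. Mann–Whitney U follows
scipy's exact/asymptotic switching.

## Synthetic data and what the tests show

The generator mirrors the target study's design parameters: 30 fish
tagged over 3 days, uniform 120–180 s transmission intervals, a hard
400 m detection radius (optional logistic fall-off), an 18-station array
(ten on a ring of radius 600 m around a ~1 km island footprint, six on
outlying reefs, two distant gates), a 2:1 day:night detectability ratio,
a fifth of fish emigrating at a uniformly random date (designed
residency therefore spans 0–1), and isolated false detections injected
at 0.5 per fish-day (~0.07% of records).

Movement is exact-discretised OU: step factor e^(−Δt/τ), innovation sd
σ√(1−e^(−2Δt/τ)), so the stationary law is N(centre, σ²I) on any time
grid. Defaults σ = 100 m and τ = 180 min describe a strongly
site-attached reef fish whose position decorrelates over a few hours;
with 30-min COA bins this keeps the bin-mean variance within ~5% of σ²,
so kernel home ranges remain comparable to the closed form
π·χ²₂(0.95)·σ² ≈ 0.188 km². Two-centre fish switch centres with daily
probability 0.3, producing the bimodal space use seen in real snapper.
The day:night ratio acts as per-transmission thinning between sunset and
sunrise — deliberately agnostic between "fish shelter in the reef at
night" and "night-time noise suppresses detections", which detection
data cannot distinguish. Injected false detections are rejection-sampled
to be genuinely isolated (> 24 h from any same-tag-same-station record),
matching the operational definition the filter targets; filter recall on
them is therefore a check that the filter never misses an isolated
single, while precision measures how many genuine range-edge singletons
the rule sacrifices.

Ground-truth recovery runs at two geometries:

* the **default ring array** for residency recovery, classification
  agreement and filter precision/recall — COAs there are centroids of
  ring stations and are *not* expected to reproduce the OU area;
* a **dense 150 m grid** (11×11, fish centred in its interior) for the
  KUD-vs-closed-form check, where the in-range station centroid tracks
  the true position to within a few metres. Problem sizes (30 fish ×
  60 days for recovery; 5 fish for the dense-grid check) were chosen to
  give stable statistics while keeping a full suite run around a minute
  of simulation time.

What passing these tests shows: the pipeline arithmetic is correct, the
filter implements its definition exactly, and the KUD engine is unbiased
to within the documented smoothing/averaging effects. What it does not
show: robustness to real-world features the generator omits — tidal and
thermal detection-efficiency cycles, tag collisions between many
co-located transmitters, receiver fouling and drift, non-stationary
home-range shifts, or mortality that mimics emigration. Conclusions
about real arrays still require range testing and sentinel tags.

## Numerical conventions

* Sphere radius fixed at 6371.0 km everywhere.
* Closed intervals wherever the procedures state inclusive bounds
  (±24 h partner window, excluded date ranges, deployment intervals);
  the acclimation cut alone is strict-less-than.
* χ²₂ quantiles used for analytic areas: −2ln(0.5) = 1.386294,
  −2ln(0.05) = 5.991465.
* Degenerate inputs raise (`empty study window`, `degenerate point set`,
  `insufficient COAs`, `AICc undefined`) rather than return sentinels;
  seasonal/daily subsets that are merely sparse are skipped and counted.
* All randomness flows from a single `numpy` Generator seeded by the
  config; identical configs produce byte-identical CSV output.
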