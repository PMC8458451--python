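# Methods

This note documents the models implemented in `sounderspace`, the defaults
and why they were chosen, the numerical decisions, and what the synthetic
validation does and does not demonstrate.

## Temporal design

Telemetry is partitioned per cohort into three scales. The **season** scale
is a single window (27 Mar–12 Jul by default, both cohorts). **Months** are
the calendar months fully contained in the cohort's tracking range — a
partially covered month would mix a truncated sample into a monthly UD, so
it is excluded (this yields Apr–Jun for a 27 Mar–12 Jul range and Feb–Jul
for 22 Jan–31 Jul). **Weeks** are consecutive 7-day blocks from the cohort
anchor (the range start by default). The trailing remainder shorter than a
week is discarded *together with the complete week preceding it*, so every
retained week is followed by at least a week of telemetry and the final
retained week cannot lean against the truncation boundary; the same ranges
thus yield 14 and 26 weekly periods. Periods whose sub-trajectory holds
fewer than `min_fixes = 24` fixes (one day of 2-h fixes, and a floor below
the 29-fix estimation window) are dropped with a log entry. Date boundaries
are midnight UTC with a configurable local offset; the telemetry itself
carries full UTC timestamps.

## Dynamic Brownian bridge movement model

The dBBMM treats the animal's path between consecutive fixes as a Brownian
bridge conditioned on the two fixes, with per-axis variance at fractional
time α of a bridge of duration T:

    var(α) = T·α·(1−α)·σ²ₘ + (1−α)²·δ² + α²·δ²,

where σ²ₘ (m²/s) is the Brownian motion variance and δ (default 20 m) the
isotropic GPS location-error SD of the anchoring fixes.

**Motion-variance estimation.** σ²ₘ is allowed to vary along the track. A
window of 29 fixes slides in steps of one fix; within each window every
odd-indexed interior fix is predicted by the bridge spanning its
even-indexed neighbours, with a bivariate-normal leave-one-out likelihood
whose mean is the linear interpolation between the neighbours and whose
per-axis variance is the bridge variance above **plus δ² for the predicted
fix's own location error** (omitting that term biases σ̂²ₘ upward by roughly
1.5·δ²/(T/4) — about +28% at the default schedule — and is therefore
included). Within each window a single-σ²ₘ model competes against every
one-change-point split leaving at least `margin = 11` fixes on each side;
candidates are scored by BIC with the number of leave-one-out fixes as the
sample size. Each fix accumulates the σ²ₘ of the segment covering it from
every window holding it in its margin interior (the central
window − 2·margin positions), and the final per-fix estimate is the mean of
the accumulated values; fixes never covered (track ends) inherit the nearest
covered value. Per-segment likelihoods are maximised on a log-spaced σ²
grid (8 points per decade across [1e−8, 1e4] m²/s) followed by parabolic
refinement of the grid optimum — the profile likelihood is smooth and
single-peaked in log σ², and on simulated Brownian tracks (σ²ₘ = 0.4 m²/s,
300 fixes, 2-h interval, δ = 20 m) the median estimate lands within a few
percent of truth (the test suite requires 20%). Tracks shorter than the
window fall back to a single maximum-likelihood σ²ₘ with a logged notice.
One change point per window keeps the search O(window) and is sufficient at
window 29; windows overlap, so faster variance changes are still tracked by
the per-fix averaging.

**UD integration.** Each consecutive fix pair contributes `n_int = 10`
isotropic Gaussian kernels at the midpoints of equal time sub-intervals,
with mean on the straight line between the fixes, variance from the bridge
formula using the pair's mean σ̂²ₘ, weight proportional to sub-interval
duration, and truncation at 4 SDs (mass error < 4e−4 per kernel). Kernels
are evaluated at cell centres of the cohort-shared 50-m grid and the surface
is normalized to unit mass; cell-centre evaluation is adequate because the
kernel SD is never below the 20-m location error, i.e. comparable to the
cell size. Doubling `n_int` moves no cell by more than 1% of total mass on
smooth tracks (tested). Consecutive gaps longer than `max_gap = 8 h` (four
missed fixes on the 2-h schedule) are not bridged — a bridge over a long gap
asserts knowledge the data do not contain; if every gap exceeds the limit
the UD raises rather than returning a misleading surface. Grids snap their
origin down to a multiple of the cell size so all animals of a cohort share
cell boundaries exactly; the default 1000-m buffer keeps 4-SD kernels of
edge fixes on the grid.

## Isopleths, dyads and overlap

An isopleth region is the smallest set of cells whose cumulative density
reaches the level (0.95 = home range, 0.50 = core area), built by sorting
cells by density descending with (row, col) lexicographic tie-breaking for
determinism. Two sows form a **dyad** if their 95% isopleths intersect in
any period at any scale; the dyad set is fixed per cohort thereafter.

For each dyad-period, 2D overlap is **directional** — the proportion of each
animal's region lying inside the other's — because the per-sow modeling
responses average the sow's own side of each dyad; a symmetric
intersection-over-union variant would discard that asymmetry. VI is the sum
of cell-wise minima of the two unit-mass UDs. At a given isopleth level each
UD is first truncated to its own region and renormalized ("home-range VI",
"core-area VI"); whether the original analysis renormalized after
truncation is not documented, so the renormalizing variant was chosen as
the one that keeps VI a proper overlap of probability distributions (the
un-renormalized min-sum over cores is not bounded away from trivially small
values by construction). Per-sow responses are the means of the sow's
dyad values within each (period, scale, level).

## Dynamic interaction

Two fixes are simultaneous in time when |Δt| < 600 s (strict, matching the
"< 10 min" design) and in space when their distance is < 50 m. Temporal
matching is one-to-one and globally greedy on |Δt| (smallest first, ties to
the earlier fix): greedy matching in scan order of one animal is not
symmetric in the argument order, whereas the globally greedy rule is, and
the two agree on regular 2-h schedules where each fix has at most one
candidate partner. Prox = matched pairs closer than 50 m / all matched
pairs.

HAI over a shared polygon counts joint events (temporally matched pair,
both fixes inside the polygon, distance < 50 m) against solitary fixes
inside the polygon. A joint event consumes both fixes — a fix cannot be
both joint and solitary — and solitary counts include *all* period fixes
inside the polygon, not only temporally matched ones (the literature varies;
counting all fixes makes the denominator an occupancy measure rather than a
schedule-dependent one). Point-in-polygon tests are boundary-inclusive.
Indices are computed only for dyad-periods whose home-range VI exceeds 0.1,
and undefined indices (zero denominators, polygon never entered) propagate
as missing values — coercing them to 0 would bias the summary means toward
avoidance.

## Beta regression

Overlap responses live in [0, 1], so they are modeled with a beta
likelihood: mean μ = logit⁻¹(Xβ), shapes (μφ, (1−μ)φ), constant precision
φ. Responses exactly at the boundary are shrunk by y′ = (y(n−1)+0.5)/n
before fitting. Continuous covariates are standardized (mean 0, SD 1)
before interaction products are formed, and the scalers stored with the
model. The likelihood, analytic score and observed information
(finite-differenced score) are implemented directly; the fit is L-BFGS-B on
(β, log φ) started from a logit-scale least-squares fit, and agreement with
an independent implementation is enforced in the test suite to ~1e−9 in
log-likelihood. Wald SEs come from the inverse observed information;
odds ratios are exp(β̂) per standardized unit with 90% intervals using
z = 1.6449. Models are ranked by AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1) (+∞ with
a warning when n ≤ k+1), plausible when ΔAICc < 2. The candidate sets are
configuration — defaults combine the landfill, sow, cover and weather
covariate groups with UD-level interactions up to third order, and weather
and year terms enter only sub-season models, where repeated periods make
them identifiable. The study design's random intercepts for sow and sample
period are deliberately rendered as fixed-effects beta regression: the
likelihood stays self-contained and verifiable, at the cost of
overstated precision when sows contribute many periods (a cluster-robust
correction would be the natural extension). UD *size* is not modeled with
the beta family (it is not a proportion); log-scale Gaussian modeling is the
documented simplification and is out of the beta-regression scope here.

## Synthetic generator

Animals move as stationary Ornstein–Uhlenbeck processes: relaxation time
τ = 6 h, per-axis stationary SD s = 326 m, updated by the exact transition
X_{t+Δ} = C + e^{−Δ/τ}(X_t − C) + ε, ε ~ N(0, s²(1−e^{−2Δ/τ})I), so there
is no discretization bias at any fix interval. The defaults put the
analytic 95% home range π·χ²₀.₉₅,₂·s² at ≈ 200 ha and keep consecutive 2-h
fixes correlated (ρ ≈ 0.72), matching the scale of tracked sows; cohorts
default to 7 (2014-style) and 11 (2016-style) animals on a ring around a
central landfill attractor. Nightly attractor excursions replace a short
run of fixes (default 2) in the 00–06 h window with attractor positions
plus 15-m scatter and midpoint approach/return fixes, keeping the fix
schedule intact; under `attraction` coupling all animals share the same
visit nights and dwell offsets, under `avoidance` animals visit on disjoint
night classes. GPS error (default 20 m) is added last; fixes can be dropped
independently. All randomness derives from one seed via per-animal
substreams, so cohorts are reproducible and stable under animal reordering.

The **territorial** dyad preset places centres 3.5·s apart. Two stationary
isotropic Gaussian UDs at separation d have VI = 2Φ(−d/2s) in the
long-track limit, so 2s separation converges to VI ≈ 0.32 — far above the
low shared intensity the territorial pattern requires — while 3.5·s gives a
smooth-limit VI ≈ 0.08 with ≈ 20% directional areal overlap of the 95%
isopleths. That choice was made from the closed form, not tuned on test
outcomes, and reproduces the defining signature: substantial 2D overlap
(> 0.1) with low VI (< 0.1) at season length.

What the generator does *not* emulate: tortuosity and diel rhythm beyond
the nightly excursions, habitat-driven movement, interactions other than
the attractor coupling, home-range drift, and collar failure patterns other
than independent fix loss. Validation against it therefore demonstrates
that the estimators recover known structure under the analysis' own
assumptions (stationary home ranges, Gaussian-scale location error), not
that those assumptions hold for field data.

## Validation experiments and problem sizes

The experiments in `sounderspace.evaluation` (run by the test suite and by
`scripts/acceptance.py`) use: 100 randomized fixtures (≤ 20×20 grids,
≤ 50-fix tracks) for exact brute-force agreement of VI, 2D overlap, Prox
and HAI; 5 stationary OU tracks of 2004 fixes for the closed-form
home-range area (median ratio within 15%); 10 Brownian tracks of 300 fixes
for σ²ₘ recovery (median within 20%); 200 beta-regression simulations at
n = 500, φ = 30 for 90%-interval coverage (target 90 ± 5 points); 20 paired
seeds for each scenario contrast (territorial vs shared VI at 107-day
season length; attraction vs avoidance HAI at 40 days, which is where the
contrast is decided since HAI depends on nightly co-visits, not on season
accumulation); 50 seeds for the independence null of Prox; and a 16-day
one-cohort pipeline run executed twice for byte-identical determinism.
These sizes keep the full validation around a minute while leaving each
statistical criterion with a comfortable margin.

## Known limitations

- Fixed-effects beta regression understates uncertainty relative to the
  mixed-effects design it stands in for (see above).
- The dBBMM window scheme estimates at most one change point per window;
  variance shifts faster than ~margin fixes are smoothed.
- Isopleths are cell sets, so areas are quantized to 0.25 ha at the 50-m
  default; dyad detection through single-cell touches is correspondingly
  grid-dependent.
- No geographic CRS handling: all coordinates are planar metres, and
  reprojection is the caller's responsibility.
- The core-area VI definition (truncate-and-renormalize) is one of two
  defensible readings; both are available via the `level` argument of
  `volume_of_intersection` (pass `None` for raw full-UD VI).
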