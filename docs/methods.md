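# Methods

`camarray` evaluates camera-trap study designs — the number of clustered
cameras per site and the season length — by Monte Carlo subsampling of a
yearlong detection dataset. This note documents the models, estimators,
numerical choices and limitations; everything quantitative stated here is
recomputed by the test suite or by `scripts/acceptance.py`.

## Detectability model

Sites are assumed occupied throughout the year (occupancy fixed at 1), so a
zero in the detection record is a detection failure, never a true absence.
The year (indexed day 1–365; leap days are not modelled) is cut into
replicates of length *L* days; for a design with *N* sites and *k*
replicates the survey detection probability is the cell ratio

    p = ΣP / (N·k),        P ∈ {0, 1} per (site, replicate),

and the cumulative season detection probability under replicate
independence is

    p* = 1 − (1 − p)^k.

`p*` is non-decreasing in both `p` and `k`, equals `p` at `k = 1`, and hits
the boundaries only at `p ∈ {0, 1}`; these are enforced as property tests.
Non-integer `k` is rejected rather than rounded — flooring happens upstream
in the subsampler.

## Independence rule (event deduplication)

Raw trigger events of a species at a site are merged by a *sliding* window:
an event joins the open chain iff its gap to the chain's **latest** event is
strictly below the window (30 minutes by default), regardless of camera. A
chain is one independent detection, dated by its first event. Sliding
(rather than fixed-from-first) chaining treats continuous activity as a
single visit; with sorted events it is equivalent to splitting at
consecutive gaps ≥ window, and also to connected components of the
pairwise within-window graph — the test suite exploits the latter as an
O(n²) union-find oracle.

When a Monte Carlo draw selects a camera subset, the rule is re-applied to
the subset's events (default `attribution="rededuplicate"`): the
counterfactual record that array would actually have produced. The
alternative (`"first_camera"`: deduplicate the full site once, attribute
each chain to the camera of its earliest event, filter) is available as a
switch; the two differ only when chains span cameras, which the generator
makes deliberately possible but rare.

## Monte Carlo subsampling

Each iteration draws, uniformly over configured ranges: array size
*m* ∈ 1–10 (cameras per site, without replacement), season start day
1–365, season length *S* (uniform in `random` mode; from an explicit grid
in `grid` mode, for season-length sweeps at fixed designs), and replicate
length *L* ∈ 1–28 days — the range of replicate lengths reported across
camera-trap studies. `k = ⌊S/L⌋`, discarding trailing remainder days to
avoid short heteroscedastic final replicates; (S, L) pairs with L > S are
rejected and redrawn. Seasons wrap modulo 365, mirroring the practice of
looping a single year of data. Per-iteration RNG substreams are spawned
from the master seed by counter-based seeding (`SeedSequence(seed,
spawn_key=(i,))`), so results are bit-reproducible and independent of
iteration order.

Whether season start and end are drawn independently (a triangular implied
length distribution) or length is drawn directly was left open by the
source methodology; the package draws length directly, which makes the
length distribution explicit and controllable, and offers the grid mode for
curve sweeps.

Two extraction paths exist deliberately: a readable per-draw reference
(`extract_replicate_matrix`, built on the public `deduplicate`) and a fast
pre-sorted index used inside `run_monte_carlo`. Tests pin their exact
equivalence, and both are checked against an exhaustive (site, replicate,
day) enumeration oracle.

## Curve fitting and design inversion

Season detectability against season length is modelled as
`p*(S) = A(1 − e^(−RS))`, A ∈ [0, 1], R > 0 per day. Fitting is bounded
nonlinear least squares (trust-region reflective) with the analytic
Jacobian, tolerances 1e-12; starting values are A₀ = max observed p*
(clipped to (0, 1]) and R₀ from log-linearizing the two smallest-S points,
falling back to 1/mean(S). Fits default to per-iteration points; averaging
within season-length bins first is available (`binning=True`) to de-weight
heavily sampled lengths.

Confidence intervals are 95% Wald t-intervals from the Gauss–Newton
covariance `σ²(JᵀJ)⁻¹`, `σ² = RSS/(n−2)` — the standard nls-style
intervals. Profile-likelihood intervals were considered and not used: for
this well-conditioned two-parameter model the Wald intervals are
empirically well calibrated (coverage ≈ 0.93 at the acceptance settings,
within the accepted band), and profile root-finding adds failure modes on
degenerate fits. Degenerate inputs (fewer than 3 distinct S, p* outside
[0, 1]) raise; all-zero p* returns `converged=False` with NaN intervals
rather than silent defaults, since R is then unidentified.

The inverse `S = −ln(1 − p*/A)/R` returns `inf` when the target is at or
above the asymptote. The design calculator combines it with budget
arithmetic: `⌊cameras/m⌋` simultaneous sites, feasibility = (minimum season
≤ budget), and `⌊budget/min-season⌋` back-to-back deployments when arrays
can be relocated to fresh sites.

## Array-size comparison

Per-draw survey detectabilities are compared between array sizes with
all-pairs Welch-type contrasts (per-group sample variances, no pooling —
heteroscedasticity-consistent for a groupwise-means model) and a
single-step max-|t| familywise adjustment. The joint null equicoordinate
probability is evaluated by a seeded parametric simulation of the
group-mean vector (20,000 draws by default; with two groups the exact
two-sided normal p-value is used). The reference distribution is normal
rather than t: intended group sizes are thousands of Monte Carlo
iterations, where the difference is below 1e-3 in level. For small groups
or strong skew the max-statistic permutation method (`method=
"permutation"`) is the better-calibrated choice. Adjusted p-values are
floored at the unadjusted ones by construction.

Two caveats are attached to every result object: iterations resampled from
one year of data are not independent observations (pseudo-replication), so
p-values are anti-conservative to an unquantified degree; and with very
large draw counts statistical significance stops being interesting —
effect sizes are reported alongside.

The compact letter display uses insertion–absorption: start from one letter
holding all groups, split on each significant pair, absorb subset letters.
Sharing a letter is then exactly equivalent to non-significance; minimality
is verified against an exhaustive search oracle for small group counts.

## Synthetic data generator

The generator emulates the clustered field design end-to-end so every
downstream stage is testable without field data.

**Geometry.** Each site holds `clusters_per_site` 1-ha clusters of
`cameras_per_cluster` cameras at uniform random coordinates,
rejection-sampled until the realized mean pairwise spacing lies in a band
around 65.2 ± 7.9 m; cluster centroids are placed 589.3 m apart and sites
10 km apart (all configurable). Defaults: 4 sites × 2 clusters × 5 cameras
= 40 cameras, active the whole simulated year starting 2015-01-01; an
optional per-camera failure mode truncates active intervals and is off by
default because the analysis assumes continuously active cameras.

**Encounters.** Per camera-day event counts are Poisson with rate
`λ · season(day) · camera_effect`: trigger events of independently passing,
unmarked animals are well approximated by a point process. `season(d) =
1 + a·sin(2πd/365 + φ)` with amplitude a ∈ [0, 1); camera effects are
log-normal with mean 1, fixed per (camera, species), so arrays gain
realistically — not all cameras are equal. Event times are uniform within
the day at minute resolution; each event spawns, with probability
`within_day_cluster_prob`, a companion event +U{1..29} minutes later at a
uniformly chosen camera of the same cluster, exercising the deduplication
window.

**Default community.** Rates are illustrative, not calibrated to any field
dataset (none is publicly available): deer 1.2 and raccoon 0.5 events per
camera-day with moderate heterogeneity (log-sd 0.5 / 0.7), opossum 0.015
and bobcat 0.008 with strong heterogeneity (log-sd 2.0 / 2.2). The strong
heterogeneity is the load-bearing choice: with homogeneous Poisson
encounters even ~10 events/camera/year drives season detectability to 1
over long seasons, whereas real rare-species records concentrate on a few
"hot" cameras. These defaults reproduce the qualitative design pattern the
package is about — a second camera roughly doubles rare-species mean
survey detectability while moving common-species detectability by under
2%, and single-camera season curves for rare species stay low (fitted
p*(180 d) well below 0.6) while a single camera detects deer with
p* > 0.75 within 30 days.

**What the generator does not emulate** (hence what passing tests do not
show about field data): animal movement and home ranges (no spatial
autocorrelation between clusters beyond shared camera effects), temporal
clumping beyond the 30-minute companion mechanism (real detections come in
multi-day bouts), camera-level detection-probability drift (vegetation,
snow), imperfect species identification, and between-year variation.

## Problem sizes and runtime

Default analyses use 5,000 Monte Carlo iterations per species, matching
standard practice for this design-evaluation workflow (~6 s for the
40-camera yearlong default community). The estimator-consistency check
uses 10 independent synthetic years × 500 iterations so its standard error
can be estimated between datasets; curve-recovery uses 200 replicate
datasets of 20 points; oracle-equivalence checks use 1,000 random event
lists and dozens of random draws/letter patterns. The whole test suite
runs in well under a minute.

## Known limitations

- The pseudo-replication caveat above: all inference treats iterations as
  independent; a draw-overlap-aware variance would require a different
  resampling scheme.
- The 30-minute rule dates a merged chain by its first event, so a chain
  spanning midnight assigns its detection to the earlier day; the "adding
  a camera never removes a detection" monotonicity therefore holds up to
  this (rare) corner, and property tests exclude events within 30 minutes
  of midnight.
- Wald intervals undercover mildly for asymptotes pinned at the A = 1
  bound (common for easily detected species), where the curve is nearly
  flat in A.
- Calibration of the comparison's familywise error is nominal (empirically
  ≈ 5% for same-distribution groups); a binary 100-repetition spot check
  of that rate is itself binomially noisy, which the acceptance machinery
  surfaces honestly rather than hiding.
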