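# Methods

This note documents the models, calibrations and numerical conventions
behind the pipeline, the design choices made where more than one
reasonable convention exists, and what the synthetic-data experiments do
and do not demonstrate about real telemetry.

## Coordinate frame and time

All metric computation happens in a local azimuthal-equidistant plane
about the study-site centre, on a sphere of mean Earth radius
(6 371 008.8 m). This projection preserves distances from the centre
exactly, which is what the 1000 m plausibility filter measures; over a
park-sized extent (≤ a few km) the distortion of other distances is well
below GPS error. Agreement with the geodesic meridian arc at 52.5° N is
within ~0.1 m per 111 m.

Timestamps are handled in local time (Europe/Berlin by default). The
activity window "19:00–07:00" is a clock-time convention; study seasons
(August–September) avoid DST transitions, so no special handling is
needed. The night window is half-open, [19:00, 07:00): a record at
exactly 07:00 belongs to no night. Post-midnight records are labelled
with the previous evening's date, so one `night_id` spans one biological
night.

## GPS cleaning

Order of operations: site-distance filter on raw fixes → burst averaging
→ night assignment → speed filter on burst-averaged records. The
distance filter removes fixes strictly more than 1000 m from the centre
(1000.0 m is kept). Each GPS burst (five fixes, 1 s apart) collapses to
the coordinate-wise mean of its surviving fixes, timestamped by the
first fix; a burst whose fixes were all removed disappears.

The speed filter walks each individual-night in time order and removes
the *destination* record of any step implying strictly more than 2 m/s,
then re-tests the step from the last retained record — the standard
forward-pass convention, which guarantees that afterwards every
remaining consecutive within-night speed is ≤ 2 m/s and makes the filter
idempotent. Exactly 2 m/s is kept. Steps (and speeds) are only defined
between records at most 20 min apart (two missed 10-min schedules);
longer gaps form no step and reset the filter's anchor. A config switch
applies the speed filter before burst averaging instead, since field
protocols are not always explicit about this ordering.

## Space-use metrics

*MCP95.* Peeling is by distance from the arithmetic-mean centroid — the
classical convention — keeping the ⌈p/100 · n⌉ nearest positions, ties
broken by input order (keep-more). The hull area of collinear or
near-empty sets is 0. A night needs ≥ 5 positions for any area metric;
sparser nights are excluded and logged (field studies exclude sparse
days; no universal threshold exists, 5 is the hull minimum plus one).

*KDE50.* Isotropic Gaussian kernel with the ad hoc bandwidth
h_ref = σ · n^(−1/6), σ = sqrt((var_E + var_N)/2), evaluated on a
200 × 200 grid covering the data bounding box padded by 3 h on each
side; the isopleth region is the smallest set of cells holding ≥ 50% of
total density (the volume method), its area the cell count × cell area.
The grid trades contour fidelity against runtime; at 200² the area
discretisation error is ≪ the night-to-night variance.

*Centroids.* The nightly centroid is the mean of the positions (not the
polygon centroid; both are offered, the positions mean is the default —
the two differ whenever interior points are asymmetric). Centroid
deviations are |centroid − mean pre-phase centroid| per axis, per
night; individuals without pre-phase nights cannot be normalised and
are excluded with a warning.

*Search intensity* is path length divided by the night's MCP95 area in
m², per day (each night is one day), in m/(m²·d).

## Turning angles and their comparison

Absolute turning angles are the unsigned differences of successive step
headings, wrapped to [0, π]; zero-length steps carry no heading and are
skipped. Treatment groups are compared by drawing 200 angles per group
without replacement, applying the asymptotic two-sided two-sample KS
test, and repeating 1000 times; the fraction of p < 0.05 and the median
p summarise the comparison. The protocol's "randomly sampled" could also
mean label permutation; both modes are implemented (`mode="permute"`),
subsampling is the default. The subsample size (200) and the aggregation
rule are interpretation, flagged as such and configurable.

## ACC behaviour classification

The 25-feature set is a standard wildlife-ACC reconstruction (the
original predictor list is not publicly documented):
per-axis mean, SD, min, max, skewness (15); mean ODBA, computed against
each axis's burst-mean static component (1); pairwise axis correlations
(3); per-axis dominant FFT frequency (3) — deliberately the only three
burst-length-dependent members, honouring the published remark that
exactly 3 of 25 predictors depend on burst length; per-axis spectral
entropy, normalised to [0, 1] (3). Constant axes get correlation 0 and a
flag. Feature extraction is pure: identical bursts give bit-identical
vectors.

"Joining multiple SVMs" is implemented as one RBF SVM per class against
the rest with sigmoid-calibrated probabilities normalised across
classes (C = 10, gamma = "scale", 3-fold internal calibration,
deterministic given the seed). Features are standardised by
training-set mean/SD stored in the model; the model serialises to a
single joblib file. Classification takes the argmax class if its
probability is ≥ 0.7 (inclusive at the threshold), else "other" — so
behaviours outside the training classes are not forced into one.
Budgets are per-day class proportions over complete days only (≥ 1430
of 1440 minute records, so days and nights contribute equally).

## Degree of Functional Coupling

Per-minute activity intensity is the summed per-axis sample SD of each
burst. Each 3-day window (after the complete-day rule; interior gaps
≤ 10 consecutive minutes linearly interpolated, longer gaps invalidate
the window) is mean-removed and autocorrelated (biased estimator,
r(0) = 1); the correlogram is evaluated at the window's Fourier periods
T/m, m = 1…2160 (periods 3 d down to 2 min, DC excluded), which for the
biased ACF equals the periodogram of the original series — non-negative,
and leak-free for signals with an integer number of daily cycles.

Components "harmonizing with the 24 h rhythm" are those with period
p ≤ 24 h and 24 h/p an integer (m a multiple of 3). Harmonics *of*
24 h that are longer than a day (36 h, 72 h) are excluded from the
numerator but remain in the denominator.

Two conventions are implemented:

- **`mode="peaks"` (default).** Significant components are local
  spectral maxima exceeding mean + 3 SD of the spectrum; DFC is the
  significant harmonic power over all significant power (0 when nothing
  is significant). A pure 24 h signal gives 1.000; a non-harmonic (e.g.
  31 h) oscillation gives 0 — its finite-window leakage onto the 24 h
  bin rides the shoulder of the true peak and is not itself a local
  maximum; white noise fluctuates around the harmonic bin share
  (720/2160 ≈ 1/3).
- **`mode="full"`.** Harmonic share of total power. Smoothly sensitive
  to partial rhythm degradation, but a 3-day window leaks ~20% of a
  31 h oscillation's power into harmonic bins, so non-harmonic rhythms
  are not cleanly rejected.

The peak mode is the default because it reproduces the endpoint
behaviour the statistic is defined by (1 for full coupling, 0 for a
non-harmonic rhythm). Its cost is a saturation plateau: while a genuine
24 h peak remains the only significant component, the ratio stays
exactly 1 even as the rhythm's amplitude degrades, so the DFC responds
to moderate rhythm disruption only once the peak approaches the noise
floor. The full mode declines smoothly over the whole disruption range
(the generator sweep gives Spearman ≈ −0.97 between disruption level
and full-mode DFC, vs ≈ −0.82 for the peak mode, whose upper levels tie
at 1). Windows slide by one day; each DFC is assigned to its window's
first day; arcsin(√x) is the variance-stabilising transform used before
modelling.

## Nesting

Nest identity: a daily record within 2 m (inclusive) of an
already-known nest of the same individual is that nest (nearest wins);
otherwise it founds a new nest at its position. Individuals with fewer
than 5 distinct nests are excluded (exactly 5 is kept). Occupation
intervals are maximal runs of consecutive observed days in one nest;
an interval is right-censored (a minimum duration) when it touches the
study boundaries or abuts any missing survey day — a missed day means
the occupation's true extent is unknown, so intervals are split and
censored rather than bridged (threshold configurable). Survivorship is
the Kaplan–Meier product-limit estimator (via lifelines) with Greenwood
variance; group comparisons use the log-rank test, treating "Mantel
test" as its synonym as the survival literature does. Next-day reuse is
the fraction of consecutive observed day-pairs with the same nest.

## Group-comparison models

Responses are fitted with a cell-means design over the six
treatment × sex cells, a per-individual random intercept, and REML
(statsmodels MixedLM). Wald χ² tests for treatment (df 2), sex (df 1)
and interaction (df 2) are built from marginal-mean contrasts on the
cell means; with balanced cells — the generator's designs — these equal
the classical Type II ANOVA table, and in the no-random-effect limit
they reduce exactly to ordinary least-squares ANOVA (verified against
an independent ANOVA oracle). The six study contrasts are fixed rows
over the cells (each summing to zero); family-wise adjustment is
single-step max-|z| under the contrasts' joint normal, evaluated by
seeded Monte Carlo (20 000 draws, ~0.5% accuracy), with the guarantee
that adjusted p ≥ unadjusted p.

Variance weighting (optional) estimates the power δ in
SD(ε) ∝ |fitted|^δ by regressing log |residual| on log |fitted|, then
refits with rows scaled by |fitted|^−δ — the power-of-the-mean variance
structure, using the fitted-values convention for the variance
covariate. A singular or non-convergent mixed fit falls back to fixed
effects only, with a note in the result. Spatially explicit
autocorrelation corrections are out of scope; serial dependence of
search intensity can be approximated by the night-order AR(1) residual
option.

## The synthetic generator

The generator's defaults are the study conditions: control mean speeds
0.040 (pre) / 0.038 (festival) / 0.049 (fragmented) m/s; control MCP95
targets 2.55 ha (females) and 4.71 ha (males); festival centroid shifts
(35, 30) m for females and (65, 105) m for males; next-day nest reuse
0.661 (female control), 0.578 (male control), 0.455 (male festival);
GPS noise 15 m SD (within the 10–40 m error the loggers showed);
4 animals per sex per site. Values the study reports only directionally
were fixed once at plausible magnitudes: festival areas 1.5/2.4 ha
(both sexes contract), fragmented areas 4.8/5.4 ha (female increase
large, male slight, sexes converging), female festival reuse 0.70
(females kept or extended nest use), fragmented reuse 0.60/0.55.

*Movement.* Within a night, a velocity-autocorrelated random walk at
the 10-min burst grid: v_k = φ v_{k−1} + ζ, with the per-axis
stationary variance fixed at 2d²/π (d = mean step = speed × 600 s) so
the Rayleigh mean step length equals d for every persistence φ. φ is
calibrated per sex × treatment by bisection on a 256-night noise-free
pilot (common random numbers) until the mean nightly MCP95 hits the
target area; no closed form links φ to the hull area of 73 correlated
positions. A positional Ornstein–Uhlenbeck process cannot represent
these data: at 24 m steps a diffusive path saturates near 4.4 ha,
below the male control target, while the velocity walk spans small
(anti-persistent) through large (ballistic) areas at exact speed.
Across nights, each night's path is translated so its centroid equals
the individual's home centre (displaced by the configured shift under
the festival) plus isotropic 12 m jitter — centre attraction acting at
the between-night scale, giving realistic nightly-centroid stability
(tens of metres) independent of within-night tortuosity. Node steps are
capped at 3 × speed × 600 s (a > 3-Rayleigh-mean tail event,
probability ~10⁻³) so the minute-interpolated path is continuous.
Injected outliers displace single fixes 1.5–4 km from the site centre
and are labelled in a hidden column; burst averaging dilutes a single
displaced fix five-fold, so record-level speed violations are exercised
with constructed cases rather than injected ones.

*ACC.* One burst per scheduled minute. Resting: gravity plus 0.03 g
noise; walking: a 2 Hz gait oscillation across axes plus noise;
balling: a 0.6 s high-amplitude transient then near-static. Night
minutes draw active states (80% walking / 15% resting / 5% balling),
day minutes resting ones (98% / 2% balling). Rhythm disruption r puts
each minute into a disruption set with probability r and randomly
permutes the states within the set — count-preserving, and time-uniform
at r = 1. (Relocating night activity into the daytime block instead
would merely invert the phase of a still perfectly daily rhythm, which
a phase-invariant coupling statistic cannot distinguish from the
undisturbed schedule.)

*Nests.* Each day the animal keeps its nest with the sex × treatment
reuse probability, else founds a new one ≥ 10 m from all its previous
nests (so the 2 m identity rule never merges distinct true nests).

*What the generator does not emulate:* habitat structure and barriers
(movement is isotropic), GPS fix failure and HDOP-dependent error,
behaviour-dependent GPS error, inter-individual interactions, weather,
and seasonal drift. Passing recovery tests therefore shows the
estimator chain is unbiased at realistic signal and noise magnitudes —
not that it is robust to habitat-driven sampling artefacts.

## Experiment sizes and numerical conventions

Parameter-recovery experiments run noise-free (GPS noise and outliers
off) with 2 animals per sex and 20-night phases: recovery isolates
estimator bias, while burst-averaged 15 m noise adds a known ~12%
inflation to 10-min step speeds that is a property of the sampling
design, not of the estimators. Rhythm experiments use one animal,
3-day windows, 10 replicates per disruption level; classification
trains on one day and tests on a second (2880/1440 bursts); the null
calibration of the inference layer uses 200 replicates of the
study-sized design (4 individuals per cell × 15 nights). The
acceptance script runs all of these in about a minute.

Determinism: every simulation consumes an explicit seed; independent
streams are derived per purpose and per individual, so subsetting the
roster does not shift other individuals' draws. Hectares are
10 000 m²; all areas convert centrally. Probabilities compared to the
0.7 threshold use ≥; the 1000 m, 2 m/s and 1430-record thresholds use
strict "more than" / "fewer than" readings of their definitions.

## Known limitations

- The 25-feature set and SVM topology are a reconstruction, not a
  replication of the original (unavailable) training pipeline; absolute
  classification accuracies on real loggers will differ.
- The peak-significance DFC saturates at 1 under moderate rhythm
  degradation (see above); for dose-response questions use
  `mode="full"` alongside.
- Mixed-model Wald p-values are asymptotic; with very few individuals
  per cell they run slightly anticonservative (the study-sized design
  is approximately calibrated; see the null-calibration check).
- The KDE isopleth area is grid-quantised; at 200² the bias is
  negligible for ranges of ≥ tens of cells but the polygon outline is
  blocky (`build_polygon=True` returns the cell union).
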