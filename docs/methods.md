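# Methods

This note documents the models, conventions, and design choices behind the
package, in the spirit of a statistical software methods appendix. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Ideal observers

Both observers are conjugate Dirichlet-multinomial learners with closed-form
posterior predictives p(i) = (cᵢ + αᵢ) / (Σc + Σα). Choices:

* **Prior.** "Uninformative" is operationalized as the symmetric Laplace
  prior α = 1 per cell, for both the unigram counts and every row of the
  transition matrix. α is a parameter everywhere it appears.
* **Log base.** Surprisal is reported in bits (−log₂ p). Because the
  regressions standardize surprisal, every downstream coefficient, test
  statistic, and p-value is invariant to the base (a property test asserts
  this); the choice only affects reported magnitudes such as axis units.
* **First event under the transitional model.** There is no preceding
  event, so it is scored by the marginal prior — identical to the unigram
  first-event score, log₂ 3 ≈ 1.585 bits in the 3-object design.
* **State resets per sequence.** Objects are new on every trial, so counts
  never carry across trial boundaries.
* **Update timing.** Event *t* is scored against the belief formed from
  events 0..t−1, then absorbed. Equivalently, when the transitional model
  scores event *t* it has seen all t−1 transitions in the prefix. (Note the
  familiarity consequence: an object's surprisal decreases strictly along
  uninterrupted repeat runs, but intervening objects can make a later
  occurrence *more* surprising again — monotonicity across all occurrences
  of an object does not hold and is not asserted.)

## Stimulus sequences

The design is 3 boxes × 3 objects, one pop-up per 1500 ms event (750 ms up,
750 ms down), no gaps, with a fixed bijective object↔box binding per
sequence. Defaults mirror the study scale: 80 sequences, every sequence
shown to every subject in per-subject random order.

Sequence length is configurable with a default of 30 events — long enough
for posterior beliefs to differentiate across sequences, short enough for
desk-scale simulation.

The published stimuli were generated to maximize the spread of the
sequences' theoretical information properties; the exact procedure is not
public, so `generate_sequence_set` uses a concrete, reproducible stand-in:
candidates are drawn with per-candidate Dirichlet(1,1,1) object weights
(so marginal pop-up probabilities genuinely vary), each candidate is
summarized by (mean, SD, max) of its unigram surprisal trace, and a greedy
maximin rule — seeded at the summary farthest from the pool centroid, ties
to the lowest index — keeps the most mutually spread candidates. The set's
`dispersion_score` is the mean nearest-neighbour distance among selected
summaries; an acceptance test verifies the selection beats size-matched
random subsets on this score across 100 seeds. Treat the generated set as
statistically comparable to, not identical with, the published stimuli.

Box centers sit on a jittered 3×3 screen grid (1920×1080 px, origin
top-left). The central cell is reserved for the between-event fixation
point, and grid spacing plus the ±20 px jitter bound guarantee pairwise
center separation ≥ 2 × AOI radius, so AOIs can never overlap and the
fixation point is always well outside every AOI.

## Gaze measures

* **AOI geometry.** Circular, radius 150 px (configurable), boundary
  inclusive, centered on box centers. No published AOI shape was available;
  a circle is the minimal convention.
* **RT** is the time from pop-up onset to the first sample inside the
  event's AOI (0 if already inside at onset; absent if never inside during
  the event). There is no saccade/fixation parsing stage: sample-level AOI
  entry is the minimal assumption, with an optional minimum-dwell parameter
  (default 0 ms) for robustness variants.
* **Predictive-looking** is defined only on an object's first appearance,
  as gaze inside that box's AOI over the pre-onset window (default: the
  single sample at onset − 1 ms). Event 0 has no pre-onset sample, so
  first appearances at index 0 are undefined (absent) in both the measures
  and the simulator.
* **Look-away** is the event containing the start of the first run of
  ≥ 750 ms (half an event) that is off-screen *or* track-lost — a head turn
  that defeats the tracker is behaviourally a look-away. All later events
  are flagged `included=False` and their measures censored, mirroring the
  trial-terminating convention of the infant look-away paradigm.
* **Covariates.** `is_repeat` = same object as the previous event;
  `distance_px` = Euclidean distance between consecutive pop-up box centers
  (absent at event 0); `trial_number` = 1-based session position. The
  latter two are standardized inside controlled fits.

## Synthetic agents

The simulator draws outcomes from the generative models stated in the
README, standardizing surprisal over the stimulus set's full event pool.
Default ground truth — log-RT (5.5, −0.05, 0.04) with residual SD 0.25,
look-away logit (−2.2, −0.6, 0.35), predictive logit (−1.0, −0.5), subject
intercept SD 0.3 — was chosen to produce detectable U-shaped effects at the
study's scale (5 × 80 × 30 events) without saturating: the intercepts give
~245 ms median RTs and a ~10% per-event look-away hazard.

Rendering inverts the measurement stage exactly: gaze rests at the fixation
point with 3 px jitter; a drawn RT becomes AOI entry at onset + RT with a
300 ms dwell (capped 100 ms before the event's end); a drawn predictive
look parks gaze on the box for the last 100 ms before onset, which also
makes the measured RT 0 (the truth table records 0 — such anticipatory
events are excluded from log-RT fits anyway); a drawn look-away becomes an
800 ms off-screen excursion starting 100 ms into its event. Because the
fixation point is structurally outside every AOI and dwells are
scheduled to vacate each event's tail, re-extraction recovers every drawn
outcome bit-for-bit (an acceptance test asserts 100% agreement at full
scale). Drawn latencies ≥ 1200 ms are recorded as "never fixated" so every
programmed behaviour fits inside its event window.

What the simulator does *not* emulate: saccade kinematics and oculomotor
noise, smooth pursuit, partial AOI entries, drift or calibration error, and
baseline track loss. Passing round-trip and recovery tests therefore
demonstrate that the pipeline is correct and well-calibrated on idealized
gaze, not that the measures are robust to real tracker noise — robustness
knobs (minimum dwell, pre-onset window, AOI radius) exist but default to
the idealized settings.

## Inference

* **Log-RT model.** statsmodels `MixedLM` (REML) of log RT on z, z²
  (+ covariates) with a subject random intercept. Rows with RT = 0 are
  excluded (log-undefined, and they are predictive looks, analyzed
  separately). p-values use the normal approximation to the Wald statistic,
  consistent with reporting large-sample t/z values without degrees-of-
  freedom bookkeeping.
* **Logistic models.** Random-intercept logistic likelihoods are maximized
  with adaptive Gauss-Hermite quadrature (25 nodes recentred and rescaled
  at each group's conditional mode — the same scheme as lme4's
  `glmer(nAGQ>1)` for a scalar random effect), implemented in
  `mixed_logit.py` because the Python stack offers no Laplace/AGQ GLMM.
  The test suite cross-checks it against ordinary logistic regression in
  the σ→0 limit and against `lme4::glmer` via Rscript on a fixture
  (agreement to ~1e-3). If the optimizer fails, a cluster-robust ordinary
  logistic fit is returned flagged `converged=False`; a structurally
  degenerate outcome (all 0/all 1) returns an empty flagged result.
* **Quadratic coding.** z and z² are raw polynomial terms; z is
  standardized pooled across subjects (a within-subject option exists on
  `standardize_surprisal` via pre-grouping, and `scope` controls the
  reference rows). By default the reference is the *included* analysis
  rows. Parameter-recovery tests instead use `scope="all"`, which matches
  the simulator's event-pool standardization: look-away censoring shifts
  the included-row mean of z, which would rescale coefficients relative to
  ground truth and turn a recovery test into a scale-mismatch test. In
  real-data analyses only the included-row convention is available, and the
  attenuation it induces (visible in the README example) affects magnitudes,
  not signs or significance of the U-shape terms.
* **Predictive-looking** uses a linear surprisal term only, and its
  controlled fits drop `is_repeat`, which is structurally constant (first
  appearances are never repeats).
* **GAMs.** statsmodels `GLMGam` with a 10-df cubic B-spline in raw
  surprisal; identity link for log RT, logit for binary outcomes;
  covariates enter controlled variants as linear terms. The penalty weight
  is selected by GCV for gaussian fits and by AIC for binomial fits (the
  GCV criterion implementation degenerates under a binomial family,
  collapsing to a linear fit). Outputs: a 100-point curve with pointwise
  95% band and SE band on the response scale, plus raw means ± SEM of
  three evenly spaced surprisal bins.

## Problem sizes and calibration checks

The acceptance suite runs at the study's scale (5 subjects × 80 sequences ×
30 events) for exactness checks, with replicate counts chosen for
desk-scale runtime: 100 replicates for coefficient recovery (3-SE coverage
and sign agreement), 200 for null calibration of the quadratic term at
α = 0.05, 100 seeds for the stimulus-dispersion comparison, and 40 for
GAM/regression concordance. Concordance is assessed on the look-away
outcome — the paradigm's canonical U-shaped curve, whose default quadratic
(0.35 per z² on the logit scale) is well inside what a penalized spline
resolves; the default log-RT quadratic (0.04 against a residual SD of 0.25)
sits at the smoother's resolution limit, where an over-smoothed monotone
curve can coexist with a clearly significant parametric z² term.

## Known limitations

* The maximin stimulus generator is a documented stand-in for the
  unpublished generation procedure.
* Exact predictive-look and look-away operationalizations in the original
  paradigm live in footnotes/appendices that are not public; the defaults
  here (onset − 1 ms sample; 750 ms off-screen-or-lost run) are the closest
  literal readings and are configurable.
* Random intercepts only (matching the reported models); no random slopes,
  no model comparison, no learned hyperparameters or forgetting variants of
  the observers.
* RT analyses drop never-fixated events rather than imputing them.
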