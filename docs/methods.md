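# Methods

## The measurement model

Two imperfect instruments observe the same latent daily state: whether a
person performed a health-enhancing exercise bout on a given day.

* The **accelerometer channel** reports minute-level step counts and a
  device-assigned intensity category per minute.  Exercise is *derived*:
  a day counts as an exercise day when some consecutive window of
  `bout.window_minutes` (default 30) contains at least `bout.active_minutes`
  (default 24) minutes whose intensity lies in `bout.intensity_set`
  (default moderate+vigorous).  The 24-of-30 default generalizes the
  conventional bout rule that allows a short fraction of below-threshold
  minutes (rest, traffic lights) inside a continuous exercise period.
* The **self-report channel** is a single end-of-day yes/no item about
  ≥30 minutes of moderate-or-vigorous exercise.

Agreement on the included person-days is chance-corrected with Cohen's
kappa.  For a 2×2 table with cells a (yes/yes), b (EMA yes/accel no),
c (no/yes), d (no/no) and n = a+b+c+d:

    p_o = (a+d)/n,   r = (a+b)/n,   s = (a+c)/n,
    p_e = r·s + (1−r)(1−s),   κ = (p_o − p_e)/(1 − p_e).

Per-participant kappas are summarized by mean ± SD, range, and median; the
pooled kappa is computed on the element-wise sum of participant tables.
Its standard error uses the Fleiss–Cohen–Everitt large-sample variance
(the standard asymptotic variance for a single kappa; the docstring of
`agreement._fce_variance` states the formula).  A day-resampling bootstrap
SE is provided as a cross-check and agrees within a few percent at the
table sizes this pipeline produces.

**Degenerate participants.** A participant whose included days are constant
on either measure (e.g. never reports exercise) has an uninformative table:
the kappa is flagged undefined, counted, and excluded from cross-participant
moments rather than imputed as 0, which would bias the mean toward zero.

**Mean vs median.** Both are computed.  The cross-participant mean carries a
t-interval; the median carries a seeded percentile-bootstrap CI and is the
default quantity on the sweep figure, since a median is the more robust
center for the small, skewed per-participant kappa samples this design
yields.

## Minute-epoch processing rules

* **Social day**: 03:00 to 02:59 the next civil day, indexed by its start
  date, in naive local clock time (no timezone arithmetic — the day
  boundary is a local-clock concept).  If clock anomalies map two civil
  minutes onto one slot, the first occurrence wins, consistent with the
  reader's de-duplication rule.
* **Non-wear**: more than 60 consecutive minutes with fewer than 10 steps.
  The phrase is ambiguous, so both readings are implemented behind
  `nonwear.interpretation`:
  * `run_total` (default): non-wear is the union of all intervals of
    length ≥ 61 whose *total* steps are < 10, computed with a two-pointer
    maximal-window algorithm.  This attaches the step budget to the whole
    span, as the phrase's grammar suggests.
  * `per_minute`: maximal runs of minutes each individually under 10 steps,
    flagged when the run is ≥ 61 minutes.
  Every `run_total` non-wear minute is also `per_minute` non-wear; the
  modes differ on "trickle" spans (e.g. 1 step every minute).  Neither
  reading is asserted as the original instrument's intent; the choice is
  logged per run.
* **Unobserved minutes** (no data row) contribute zero steps and may join
  non-wear runs, matching continuous-wear devices where an absent row means
  no registered movement; an isolated short gap stays wear so brief sync
  gaps are not deleted.  Non-wear runs never bridge the 02:59→03:00
  boundary: days are processed independently.
* **Valid day**: ≥ 600 wear minutes (10 h), boundary inclusive.
* **Windows** for bout classification are confined to the 1440-slot day and
  may cover non-wear minutes, which are simply inactive; total wear is
  filtered separately by the validity rule.  The sliding count is a
  running-sum O(n) pass, validated in the tests against a quadratic
  brute-force enumeration.

## The synthetic cohort

The generator emulates the study conditions this pipeline is designed for:
79 participants observed for 365 days.

| parameter | default | rationale |
|---|---|---|
| true exercise prevalence | 0.32 cohort mean | observed accelerometer-derived rate in year-long intermittent exercisers |
| between-person prevalence | Beta, concentration 7 | gives SD ≈ 0.17 across participants |
| bout MVPA minutes | uniform 25–60 | always satisfies the primary 24-of-30 rule; upper end typical of deliberate sessions |
| embedded rest minutes | uniform 0–6 | the rule's below-threshold allowance |
| EMA sensitivity / specificity | 0.70 / 0.78 | chosen once so self-reported prevalence ≈ 37% at true prevalence 0.32, the observed gap between self-report and device |
| EMA compliance | 0.64 | observed end-of-day response rate |
| wear compliance | 0.68 | observed fraction of days with ≥10 h wear |
| overnight non-wear (valid day) | uniform 120–420 min from 03:00 | charging/late wear; keeps the day valid |
| overnight non-wear (low-wear day) | uniform 860–1320 min | forces the day under 10 h |
| incidental moderate episodes | Poisson(0.5)/day, 5–20 min | walks etc.; the accelerometer's false-positive channel at lenient bout definitions |
| background | sedentary Poisson(6) steps, 15% light minutes | keeps worn time above the non-wear step budget |

Accelerometer error is therefore *mechanistic* (bouts near the duration
threshold, non-wear masking, incidental activity), while EMA error is
*parametric*.  A second, day-level generator draws (accelerometer, EMA)
outcomes directly from the two-noisy-raters model — both raters
conditionally independent given the truth — whose kappa `analytic_kappa`
computes in closed form from the four joint cells; that oracle anchors the
convergence tests.  Covariates match the study population's margins (57%
female, age 31.9 ± 9.5, BMI 26.4 ± 5.3, stress 22.6 ± 6.0, ...) with no
joint structure.

What the generator does **not** emulate: circadian/weekday structure,
weather, multi-bout days (configurable but off by default), activities a
wrist device misses entirely (swimming, strength training), or any
systematic reporting bias beyond constant sensitivity/specificity.  Passing
tests therefore demonstrate that the pipeline's *machinery* is correct and
that it can express the qualitative phenomena of interest (an interior
maximum of agreement over the bout-duration sweep, compliance-driven
attrition); they do not certify agreement levels in real populations.

## Correlates regression

One observation per participant: κ_i on the predictor set.  Percent-of-days
variables are computed over each participant's included days on a 0–100
scale and centered before squaring, which removes most of the collinearity
between a percentage and its square.  Univariate screens run one simple
OLS per predictor (listwise deletion per predictor); the multivariate model
has two modes because the analysis plan can be read either way —
`significant_only` (default) keeps univariately significant predictors at
α = 0.05, `all_covariates` adjusts for everything at once — and every
output row is labeled with its model.  p-values are two-sided t-tests; no
multiplicity correction is applied to the primary columns, but a
Benjamini–Hochberg column is attached to the univariate output as
clearly-labeled supplementary information.  Rank-deficient designs drop the
offending columns with a warning rather than failing.

## Numerical and design choices

* Duplicate minute rows: first occurrence in file order wins after a stable
  sort by timestamp, making parsing order-insensitive.
* EMA same-day conflicts: latest completion time wins; ties or missing
  timestamps keep the first row; conflicts are counted.
* Kappa is reported undefined (never NaN-propagated silently) with a
  machine-readable reason; undefined values never enter moments.
* The pooled SE formula is evaluated on joint proportions, so duplicating a
  table k times scales the SE by exactly 1/√k — used as an exactness test.
* Bootstrap CIs and the generator are seeded through a single integer;
  identical configuration and seed reproduce byte-identical output files.
* Problem sizes in the test suite and acceptance script (a 79 × 365
  noiseless cohort for identifiability, 12,807 parametric days for
  convergence, 1,000 random days for the window oracle, 200 replicates for
  regression recovery, a 40 × 150 demo cohort for the sweep) were chosen so
  each check's Monte-Carlo error is small relative to its tolerance while
  the whole suite stays fast on a single CPU.

## Known limitations

* The non-wear ambiguity is resolved by configuration, not evidence; on
  real data the two readings can differ materially for slow-trickle wear.
* The asymptotic pooled SE assumes independent person-days; within-person
  correlation in real data would make it anti-conservative.  The bootstrap
  cross-check resamples days, not participants, and shares the assumption.
* With only ~79 participants the correlate regressions are screening tools;
  the package emits them with SEs and labeled model modes, not causal
  claims.
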