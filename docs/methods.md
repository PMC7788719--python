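# Methods

`ordprofile` is a simulation framework for a single question in quality-of-care
research: when hospitals are compared on a patient outcome that is really an
ordinal clinical scale — the Glasgow Outcome Scale (GOS) after traumatic brain
injury, the modified Rankin Scale (mRS) after stroke — how much statistical
power for detecting outlying hospitals is thrown away by dichotomizing the
scale, and how much smaller could a profiling study be if the full ordinal
scale were analyzed with proportional-odds regression instead?

## Outcome scales

Categories are stored worst-to-best and indexed 1-based, so "higher is
better" and a positive center effect means better outcomes. Death and the
worst surviving state are merged before analysis (the common practice for
these scales, and ethically motivated: it is debatable whether vegetative
state, or bedridden mRS 5, is preferable to death). That leaves:

* `gos4` — death/vegetative, severe disability, moderate disability, good
  recovery; *favorable* = moderate disability or better (index >= 3).
* `mrs6` — mRS 6/5 merged, then mRS 4, 3, 2, 1, 0; *favorable* = mRS 0-2
  (index >= 4).

Each scale carries two dichotomizations: the favorable/unfavorable cut, and a
"mortality" cut that isolates the bottom merged category. Note the mortality
endpoint therefore *includes* the worst surviving state — its event rates (32%
for the TBI template, 21% for the stroke template) are rates of
death-or-worst-state, not literal death. The package follows those marginal
rates, not the label.

## Synthetic cohorts

The generator is a cumulative-logit probability model. With baseline category
probabilities `p_1..p_K` (worst to best) and survivor function
`Q_k = P(Y >= k)`, a hospital with center effect `b` produces outcomes from

    logit Q_k(b) = logit Q_k + b,   k = 2..K,

i.e. the same additive shift on every cumulative logit. This makes the
injected effect exactly proportional-odds: a positive `b` raises every "at
least this good" probability, and the ordinal analysis model is correctly
specified. (The alternative — injecting per-category multinomial shifts — is
deliberately out of scope; it would confound the power comparison with
model misspecification.)

Two study templates fix the simulation conditions:

* **impact** (TBI): 4-point GOS with baseline probabilities
  (0.32, 0.16, 0.22, 0.30); age log-normal with median 30 and IQR matched to
  21-45; 78% male; 80% both pupils reactive; 6-level GCS motor score with the
  published frequency table (the printed counts cover 8992 of 9578 patients,
  i.e. the percentages sum to 94%; we renormalise the counts).
* **practise** (stroke): 6-point mRS with baseline probabilities
  (0.21, 0.12, 0.11, 0.14, 0.22, 0.20); age log-normal, median 73, IQR 62-80;
  54% male; atrial fibrillation 18%, diabetes 17%, prior stroke 20%; NIHSS
  from a gamma with mean 8 rounded to integers (spread is not published;
  default SD 6, configurable).

Only the bottom-category and favorable fractions of the outcome distributions
are published (32%/52% for TBI, 21%/56% for stroke). The interior splits
above are fixed package choices made once: the TBI split follows the obvious
two-way division of the favorable mass, the stroke split a typical mRS shape.
Power depends on the outcome distribution mainly through these margins and
the category entropy, so the choice is second-order for the headline ratios.

Covariates default to **zero effect on outcome** in the configured templates:
the published information constrains only the marginal outcome distribution,
and the power comparison is driven by it. The analysis models still adjust
for the covariates (as a real profiling analysis would), so the adjustment
costs degrees of freedom honestly. `fit_generator` can instead fit a
multinomial-logit generator (statsmodels `MNLogit`, reference category =
worst state) to a user-supplied patient table, reproducing the workflow of
deriving the generator from real registry data; with a fitted generator the
covariates carry real prognostic weight.

Age for the stroke template is mildly right-skewed under the log-normal while
real stroke cohorts skew left; since age carries no outcome effect in the
configured templates this affects realism of the covariate table only, not
power.

What the generator does **not** emulate: unequal hospital sizes (the source
design kept patients per hospital constant; an option exists but is not the
default), missing data, outcome misclassification / inter-rater disagreement
(mentioned in the source literature without any stated mechanism or rate —
deliberately not implemented), and non-proportional odds in the true
outcome process. Passing tests therefore demonstrate the efficiency ordering
under a correctly specified proportional-odds world with uninformative
case-mix; with real registry data the ordinal gain is expected to differ in
magnitude (the source analyses, built on confidential patient data with real
covariate effects and imperfect proportionality, report somewhat larger
mortality-versus-ordinal gains than the configured templates produce).

## Analysis models

Per simulated cohort, three fixed-effect models are fitted to the same
patients:

1. *ordinal* — proportional-odds (cumulative-logit) regression on the full
   scale;
2. *favorable* — binary logistic regression on the favorable/unfavorable cut;
3. *mortality* — binary logistic regression on the mortality cut;

each with the template's prognostic covariates plus hospital as a categorical
variable (reference coding, first estimable hospital as baseline). Both
fitters are straight Newton maximizers with analytic gradient and Hessian,
step-halving on any step that fails to improve the likelihood, gradient
tolerance 1e-8, at most 100 iterations. Thresholds are left unconstrained:
the likelihood is -inf whenever a category probability becomes non-positive,
so the line search itself enforces the threshold ordering, and initialisation
at the intercept-only cumulative-logit estimates keeps Newton in the valid
region in practice. Numeric covariates are centered for conditioning (this
changes only intercept/thresholds). Standard errors come from the inverse
observed information.

Hospital estimates are re-expressed as deviations from the mean center
effect, `d_h = b_h - mean(b)`, which sum to zero over the estimable
hospitals. Two standard errors accompany each deviation:

* `se` — the delta-method SE of `d_h` from the full coefficient covariance;
* `se_marginal` — the reference-coded coefficient SE, i.e. the number read
  directly off the categorical fit (the reference hospital, which has no
  coefficient, is assigned the median of the others; centers are equal-sized,
  so these are nearly identical).

**Separation.** A hospital whose outcomes are all one-sided (all the same
binary value; all in the worst or all in the best ordinal category) has no
finite coefficient. Such hospitals are excluded from the fit, reported as
`non_estimable`, never flagged as outliers, and counted per replicate. At
the default event rates this matters only for the mortality dichotomy at
small hospital sizes (about 0.3% of hospitals at 25 patients/hospital in the
stroke template).

## Outlier rule

A hospital is an outlier when its estimated center effect is incompatible
with the overall mean at the 95% level: `|d_h| > z_{0.975} * se_h`. The
critical value always comes from the normal quantile at the configured
alpha. Which SE to use is the one genuinely open design choice, because the
conventional phrase "outside the 95% CI of the overall mean" does not
specify it:

* With `se_marginal` (the **default**), the rule is exactly what the
  standard applied workflow produces — compare each hospital's reference-coded
  CI against the mean. Because `Var(b_h)` (which includes the reference
  hospital's noise) is about twice `Var(d_h)`, the test is conservative:
  effective critical value ~2.77, per-hospital type-I rate ~0.6% at
  alpha = 0.05. This reproduces the observed "false-outlier fraction below
  1%" specificity, and is the default precisely because it reproduces that
  reported behaviour.
* With `se_source="deviation"` the test has asymptotic size alpha exactly
  (5% false flags); it is the statistically exact variant and is kept for
  sensitivity analysis, as is the literal `point_outside_mean_ci` reading
  (point estimate versus the mean's own CI).

No multiple-testing correction is applied: the quantity of interest is the
raw flagged fraction per analysis, and the same rule is applied to all three
analyses, so the comparison is internally consistent either way.

## Monte-Carlo design

Scenario **A** draws true center effects i.i.d. N(0, sd) with sd = 0.35
(log-odds scale) — every hospital deviates, so the flagged fraction measures
sensitivity. Scenario **B** sets all effects to zero — the flagged fraction
measures the false-outlier (type-I) rate. The experiment grid crosses
scenarios with patients-per-hospital in 25..200 (default step 25) at 250
hospitals and 500 replicates per cell; effects are redrawn each replicate.
Within a replicate the three analyses share one simulated cohort, which
removes cohort-level Monte-Carlo noise from between-analysis contrasts.

Randomness: one master seed; every (scenario, cell, replicate, stage) gets
its own `numpy` `SeedSequence` substream, so any replicate is reproducible in
isolation and parallel execution (joblib) is bit-identical to serial.

The `desk` preset (50 hospitals, 100 replicates, grid {25, 50, 100, 150,
200}) is the package's scaled-down standard for routine verification runs,
including the shipped acceptance computations; per-hospital detection
behaviour is essentially independent of the number of hospitals, so shrinking
H mainly widens Monte-Carlo error rather than moving the curves. The full
preset reproduces the source-scale design (250 hospitals, 500 replicates,
8 grid cells).

## Efficiency translation

For each analysis the engine yields a detection-rate curve: mean flagged
fraction versus patients per hospital. Curves are smoothed by isotonic
regression (raw Monte-Carlo curves can dip at modest replicate counts), then
inverted by piecewise-linear interpolation: `required_n(curve, target)` is
the smallest n at which the smoothed curve reaches the target. A target
above the curve's maximum is *undefined* (reported as such, never
extrapolated); a target below the curve's first point returns the smallest
evaluated n — a conservative clamp, since the true requirement is smaller.

The equal-power reduction of ordinal analysis versus a dichotomized
reference is `1 - n_ordinal / n_reference`. Target power levels default to
the reference curve's own achieved (smoothed) detection fractions at its
grid points — each reference grid point yields one comparison — and the
headline "up to X%" figure is the maximum over those targets. Under the
configured templates the asymptotic reduction is the Fisher-information
ratio: per patient, the ordinal analysis carries information
`(1 - sum_k p_k^3) / 3` about a cumulative-logit shift while a dichotomy at
event probability p carries `p(1-p)`, so the expected reductions are ~19%
(TBI) and ~24% (stroke) against the favorable cut and ~30% / ~49% against
the mortality cut, with finite-sample SE inflation at low event counts
pushing the observed mortality numbers above the asymptotic value at small
n.

## Known limitations

* The configured templates carry no covariate-outcome association; with
  prognostically strong covariates (e.g. NIHSS) the dichotomized analyses
  lose relatively more information, so the configured-template reductions are
  conservative for the mortality comparison.
* The outlier rule's default conservatism (see above) shifts all power curves
  together; ratios between analyses, not absolute detection rates, are the
  quantities this package is designed to estimate.
* `point_outside_mean_ci` treats hospital estimates as independent when
  forming the mean's SE; it is included as a literal-reading sensitivity
  check, not as a recommended procedure.
* Fits that fail (singular information, non-convergence) are recorded per
  replicate and excluded from means, never silently dropped; at the shipped
  settings none occur.
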