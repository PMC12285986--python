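# Methods

This note documents the statistical models the package implements, the
synthetic-cohort generator's assumptions and defaults, the numerical
choices, and the known limitations. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## The object-location task and its scoring

The task model: on a 1536 × 2048-pixel touch screen, a subject sees 1 or 3
fractal shapes, and after a 1 or 4 s delay must identify the seen shape
against a foil (identification accuracy, response time) and drag it to its
remembered location (localisation error, the Euclidean distance in pixels
between response and original target position). Four conditions (items ×
delay), 30 trials each over 3 blocks. Trials in which the foil was chosen
are excluded from all location-based measures.

### The resampling misbinding/guessing classifier

For each identified-correct trial the classifier compares three distances
from the placement response: to the target, to the closest of the trial's
own non-targets (3-item trials only), and to one non-target drawn from the
subject's *other* trials (the pool). The minimum labels the comparison a
target, misbinding, or guessing outcome; with `n_resamples = 5000`
(default) the pool point is redrawn each time and class tallies become
per-trial probabilities. `n_resamples="exact"` enumerates the pool once,
which is the sampling estimator's expectation and serves as the
deterministic oracle in tests.

Decisions the procedure's description leaves open, and how they are fixed
here:

- **Pool definition.** All non-targets from the same subject's other trials
  (two per 3-item trial), excluding the current trial. Within-subject
  pooling avoids leaking another subject's display geometry into the
  comparison.
- **1-item trials** have no non-target; the own-non-target term is dropped
  and only target vs pool-point distances are compared, so misbinding is
  identically 0 — consistent with misbinding scores existing only for the
  3-item conditions.
- **Ties** are broken in favour of the target, then the own non-target.
  These are probability-zero events for continuous coordinates; the rule
  matters only for integer-valued fixtures.

**Bias of the classifier (important for interpretation).** The procedure is
a comparative score, not an unbiased mixture-weight estimator. A response
carrying no location information is roughly equidistant from the target,
the two own non-targets and the drawn pool point; by symmetry over four
near-exchangeable distances a true guess classifies as guessing only ≈ 1/4
of the time (≈ 1/2 misbinding, ≈ 1/4 target), regardless of the Gaussian
placement noise or the item separation. Consequently the mean classified
probabilities recover planted mixture weights only when the guessing weight
is (near) zero; at a study-like guessing rate of 0.15 the classified
guessing mean is depressed by roughly three quarters of the true weight and
misbinding inflated by half of it. The test suite asserts both faces of
this: exact recovery of the target/misbinding split when guessing is absent,
and the ≈ 1/4 : 1/2 : 1/4 split of pure guesses. Scores remain comparable
across groups measured with the same procedure, which is how the analysis
uses them.

## Synthetic cohort generator

The generator is first-class, tested code; its defaults are the study
conditions and are not tuned per experiment.

- **Subjects** (n = 53): VVIQ totals as rounded truncated Gaussians clipped
  to [16, 80], drawn per recruitment group — high (10 subjects,
  mean 75.5, SD 2.72), low (10, mean 41.9, SD 11.99), remainder mid-range
  (mean 62.2, SD 9) — matching the reported group summaries; ages 54–80
  around mean 68 (SD 7.2); ≈ 55% female; log-normal head-size scaling
  factors around 1 (SD 0.05). With `plant_extremes` exactly one subject
  carries VVIQ 16 (the aphant) and one VVIQ 80 (the hphant); other draws
  are kept inside (16, 80) so the extremes are unique.
- **Trials.** Item positions uniform over the screen subject to a 200 px
  minimum pairwise separation (the source task says only "randomly
  selected"; the separation keeps the classifier well-posed). Placement
  responses: target-centred isotropic Gaussian (σ = 50 px) with probability
  p_target; Gaussian around a uniformly chosen non-target (misbinding);
  uniform over the screen (guessing). Default 3-item weights
  (0.72/0.15/0.13 at 1 s, 0.68/0.15/0.17 at 4 s) are in line with the
  reported classified rates; 1-item conditions cannot misbind. Screen
  truncation is by resampling, not clipping, to avoid probability atoms at
  the edges. Identification is Bernoulli (0.86–0.95 by condition), response
  times positive-truncated Gaussian (1.5 ± 0.5 s).
- **Subject-level effects.** `mixture_for_subject` tilts p_target linearly
  in centred VVIQ, sex and age covariates (defaults 0.20, 0.05, 0.08 across
  each attribute's range, renormalising misbinding/guessing). The VVIQ
  tilt is sized so the high/low extreme groups differ substantially on all
  three VSTM measures, mirroring the large reported group effects; females
  and younger subjects are slightly more accurate, mirroring the reported
  directions.
- **Volumes.** The 57-volume catalogue (Sets A 11 / B 36 / C 3 / D 7):
  imagery-active large areas (hippocampus, whole hippocampus, V1, fusiform
  gyrus), 12 hippocampal subfields × left/right/bilateral, amygdala
  (control), and motor areas BA4a/BA4p/B4 (control; no bilateral score for
  BA4a/BA4p). Baselines are typical adult volumes in mm³ with
  between-subject SD = 12% of baseline; bilateral volumes are exact
  left + right sums. Planted structure: a ×1.10 multiplier on Sets A and B
  only for subjects with VVIQ ≥ 62 (an ≈ 10% group difference; control sets
  receive exactly 1), a ×1.10 male multiplier on Sets A and B, and
  whole-brain case multipliers 0.85 (aphant) and 1.05 (hphant), which put
  the hphant ≈ 36% above the aphant across sets, similar in scale to the
  reported contrast.

What the generator does **not** emulate: item-level VVIQ responses,
responses-time/condition interactions, spatial inhomogeneity of placements,
correlated volume noise across regions within subject (each region's noise
is independent), or any VSTM–volume coupling at the individual level.
Passing tests therefore demonstrate the pipeline's correctness and
calibration under the assumed structure, not empirical claims about real
cohorts.

## Extreme-groups selection

Bottom-k and top-k by score with the `expand` tie policy by default: all
subjects tied exactly at a boundary value are included, so groups may exceed
k (the age analysis's group of 11). `strict` keeps exactly k with a seeded
tie-break keyed to subject id, so assignment never depends on row order.
The between-group gap (min(high) − max(low)) is computed as a design
diagnostic.

## Split-plot ANOVA

Classical univariate split-plot decomposition with Type III sums of
squares, as SPSS GLM repeated measures computes it:

- For each within-effect stratum, an orthonormal contrast matrix (Kronecker
  product of per-factor Helmert contrasts, with unit mean vectors for
  factors not in the effect) transforms each subject's within-cell response
  vector. With orthonormal contrasts the transformed sums of squares equal
  the classical full-data decomposition exactly.
- The between-subjects design is sum-to-zero effect coded; each effect's
  Type III SS is the SSE difference between the full model and the model
  with that effect's columns removed. Effect coding (not dummy coding) is
  what makes these tests sensible under unbalanced group sizes: the
  between-stratum test reduces to the one-way ANOVA on subject means, and
  within-effect tests target unweighted marginal means. (pingouin's
  `mixed_anova` agrees exactly on balanced designs and differs on
  unbalanced ones, where it uses weighted grand-mean formulas.)
- Between-subject effects are tested against the subject-within-groups
  stratum; each within effect and its interactions with between factors
  against the subject × effect residual stratum. Partial
  η² = SS_effect/(SS_effect + SS_error-of-its-stratum).
- The covariate (a per-subject scalar) is centred and enters the
  between-subject stratum only; it is constant within subject, and no
  covariate × within interactions are fitted.
- Degrees of freedom are reported uncorrected, matching how such tables are
  conventionally printed; a Greenhouse–Geisser correction (ε from the
  stratum residual covariance, floored at 1/q) is available behind
  `sphericity_correction=True` and adjusts p-values only.
- Missing within-cells and rank-deficient designs are hard errors naming
  the offending subjects; nothing is imputed.

## Single-case inference

The Bayesian routine draws the control-population variance from its scaled
inverse-χ² posterior and the mean from the conditional normal posterior,
forms z = (x_case − μ)/√ψ per iteration, and reports the median and
2.5/97.5 percentiles of z plus p_below = mean Φ(z), the estimated
proportion of controls below the case. The two-sided p is
2·min(p_below, 1 − p_below); sidedness is always explicit because
single-case reports often leave it implicit. The posterior-predictive
construction makes p_below converge exactly to the one-tailed p of the
modified t-test t = (x_case − x̄)/(s√((n+1)/n)) on n − 1 df, which the
package also implements as the closed-form oracle; the suite asserts
agreement at 2 × 10⁵ iterations and uniformity of the null p. The
no-covariate variant is implemented; the median (not the mean) is the point
estimate for robustness to heavy-tailed variance draws.

## Composite tests

- Fisher: χ² = −2Σ ln p on 2k df; p = 0 inputs are rejected (infinite
  statistic) rather than clamped.
- Binomial tails are summed in log space (`logsumexp` of log-pmf terms);
  at 57 trials with p = 1/120 the tail is ~10⁻⁴⁷, far below naive
  summation's working range.
- The ordering test requires *strict* descent across the five categories
  (hphant, high-group mean, sample mean, low-group mean, aphant); ties make
  a region a non-match and are reported separately.
- The 2 × 2 χ² applies the Yates correction as max(|O − E| − 0.5, 0)
  before squaring; zero margins are rejected.
- Percent differences demand an explicit denominator (`reference`, `other`,
  `midpoint`) because group-difference percentages are ambiguous without
  one; the pipeline logs the convention next to every value, defaulting to
  `reference` (the high/reference group mean).

## Pipeline conventions

Per-region group comparisons default to two-tailed Welch t-tests with the
tails logged; "significant" for the active/control 2 × 2 means p < 0.05
uncorrected **and** high > low, and no multiple-testing correction is
applied across the 57 region tests (flagged here rather than silently
corrected, since the analysis design treats the 2 × 2 aggregation itself as
the control for multiplicity). The Set C (amygdala) ANOVA drops the Region
factor, having a single region; Set D uses left/right only, bilateral
scores being unavailable for two of its three regions. Every stochastic
stage receives its own seed derived from the run seed via a seed sequence,
making runs reproducible bit for bit.

## Problem sizes in tests

The suite's simulation sizes — 2000 null ANOVA datasets for type-I
calibration, 2000 replicates for single-case p uniformity, 10⁴ trials for
the generator→classifier round trip, 10⁵ regions for the ordering null
rate, 300 seeds for sampling-vs-exact classifier convergence — were chosen
as the smallest runs whose Monte-Carlo standard errors are well inside the
asserted tolerances.

## Known limitations

- The classifier bias described above: classified guessing/misbinding rates
  are not mixture weights. A generator→classifier round trip at the default
  (study-like) mixture does not recover the planted weights to ±0.03 for
  the misbinding and guessing classes, and cannot under any parameters with
  non-negligible guessing; the corresponding acceptance check is expected
  to fail and is retained as an honest record of the procedure's
  properties.
- No REML/random-slope mixed models; the classical split-plot is exact only
  under its compound-symmetry-per-stratum assumptions, with GG correction
  as the mitigation offered.
- The Bayesian single-case variant with covariates is not implemented.
- No figure generation and no MRI image handling; volumes enter as tables
  and only the scaling factor is consumed as a covariate.
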