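# Methods

`braintraj` models volumetric brain development between late childhood and
late adolescence in an accelerated longitudinal cohort: N ≈ 90 participants
enter at staggered baseline ages (7.60–12.90 years) and are scanned up to
12 times (six-month intervals for the first ten waves, one year to wave 11,
three years to wave 12), so a 14-year age span is covered in under nine
calendar years. The package provides the full analysis chain — shape
discovery, structural growth modelling, precision gating, residual QC,
individual maturational timing — plus a synthetic-cohort generator that
stands in for the confidential source data.

## Structural growth models

Three candidate mean functions of age `x` are fit per region:

* **four-parameter logistic**
  `y = A_lower + (A_upper − A_lower) / (1 + (x / Inflection)^(−Hill))`.
  `A_lower`/`A_upper` are the limiting volumes (mm³), `Hill` sets steepness
  and direction, and `Inflection` is the age at which the curve crosses the
  asymptote midpoint — the index of maturational timing. Two caveats are
  deliberate: (i) the parameterization is the power-law-in-x form exactly as
  written above, not the logit-in-x variant (they differ off the log-age
  scale); (ii) `Inflection` is the midpoint age, which for this form is
  slightly offset from the literal maximizer of |dy/dx| on the linear age
  scale. We estimate and report the parameter and note the distinction
  rather than resolving it.
* **logarithmic** `y = a + b·ln(x)` (natural log; the choice of base only
  rescales `b`). `a` is the value at age 1 year, outside the studied range,
  and is not interpreted.
* **linear** `y = a + b·x`.

The asymptote-swap symmetry of the logistic (swap `A_lower ↔ A_upper`,
negate `Hill`, identical curve) is broken deterministically at
initialization: `A_upper` starts at the maximum observed volume, `A_lower`
at the minimum, `Inflection` at the median age, and the sign of `Hill` is
taken from the Spearman correlation of age and volume. Repeated fits are
bit-for-bit identical.

## Mixed-effects estimation

Each structural parameter may carry an additive Gaussian random effect
(diagonal covariance; all parameters by default) and additive covariate
terms (sex with female as the reference level; in-scanner motion as the raw
per-visit mean Euler number; scanner-software epoch as an ordinal code).
Residual error is additive Gaussian with constant variance. The marginal
likelihood is approximated per subject by the Laplace method at the
conditional mode of the random effects, found by a damped batched
Gauss-Newton solve with analytic Jacobians. The approximation is exact for
the linear family, which therefore doubles as an internal consistency
check: the engine must agree with a standard linear-mixed-model solver to
better than 1e-3 relative error, and does (tested against statsmodels
MixedLM).

The outer optimization is L-BFGS-B on a scaled parameter vector
(structural parameters scaled by their own magnitude, covariate
coefficients by attached-parameter magnitude over covariate spread,
variance components on the log scale). When the fitted conditional modes
drift materially off-centre (mean |η̂|/ω > 0.25) the mean is folded into
the fixed effects and the optimizer restarted, up to three rounds; this
removes the flat valley in which a constant offset trades between a fixed
effect and the random-effect mean, which otherwise stalls convergence on
near-degenerate (noise-free) data.

Standard errors come from the central-difference observed information of
the Laplace log-likelihood at the optimum. Precision is gated by the
coefficient of variation, CV = 100·SE/|estimate|, with CV < 20% counted as
adequately precise (the conventional pharmacometric rule); CV = 20% fails
the gate, and a zero estimate has no defined CV. Covariate coefficients get
Wald p-values (estimate/SE against the standard normal).

Model families are compared by AIC = −2ℓ + 2k and BIC = −2ℓ + k·ln(m),
where ℓ is the Laplace log-likelihood, k counts fixed effects + covariate
coefficients + random-effect variances + the residual variance, and m is
the number of subjects (the effective sample size for between-subject
parameters). Criteria are only comparable across models fit to the same
response scale; cortical grey matter and white matter volumes are divided
by 100 before fitting (recorded in dataset metadata) and all their reported
estimates live on that scale. When AIC and BIC disagree, BIC decides and
the disagreement is logged; BIC also drives the greedy forward-stepwise
covariate search (accept the best single addition only if it strictly
lowers BIC). No multiple-testing correction is applied anywhere — p-values
are reported raw, with a note.

Individual-level parameters are empirical-Bayes **conditional modes** (the
posterior mode of η given the population fit; whether the original
analyses used modes or means is not determinable, so modes are implemented
and labelled as such). Subjects with few observations shrink toward their
covariate-adjusted population values. The derived per-subject scalar is the
inflection point (logistic) or rate `b` (logarithmic/linear); subjects
whose inflection falls outside the observed age range are flagged together
with their observation counts, since sparse early-clustered series are the
usual cause. Visit-varying covariates (motion) enter a subject's reported
parameter vector at the subject's mean value.

Fit diagnostics report population predictions (random effects at zero),
individual predictions, the OLS slope/intercept of observed against
individual predictions, and a threshold-free clustering index — the
between-group share of prediction variance under the best two-group split
(exact 1-D 2-means) — which rises toward 1 when predictions collapse into
blobs, the visual failure mode of a mis-specified structural model.

## Penalized-smooth shape model

Trajectory shape is discovered without a parametric form by the mixed
model `y = β0 + β1·sex + s1(age) + s2(age)·male + u_subject + ε`, with sex
ordered-factor coded: `s1` is the reference (female) smooth, `s2` a
centred male-only difference smooth, `u` a per-subject random intercept
(a random slope is available as a sensitivity refit). Smooths use k = 7
cubic B-spline basis functions on equally spaced knots with a second-order
difference penalty (P-splines). This basis dialect was chosen over exact
thin-plate regression splines because its penalty null space is exactly
{constant, linear} — the property the edf-based shape convention rests on —
while being simple and fast; edf agreement with thin-plate fits is
band-level, not bit-level, by design. Each penalized block (two smooths,
random intercept, optional random slope) carries its own smoothing
parameter, all estimated jointly with the residual variance by restricted
maximum likelihood; the random-intercept variance is σ²/λ_u. The REML
search is Nelder-Mead on log smoothing parameters with a balanced
initialization (λ ~ tr(B′B)/tr(S)), one simplex restart, and a ladder of
fallback starts guarded by an edf sanity check — outlier-contaminated data
can otherwise strand the search in a degenerate basin. The implementation
reproduces mgcv REML fits on the same data to within ~1% on variance
components (cross-checked in the test suite).

Shape is classified from the age smooth's effective degrees of freedom
(edf, the trace of the term's block of the influence matrix): |edf − 1| <
0.1 → linear (floating-point edf never hits 1 exactly), 1–2 → weakly
nonlinear, > 2 → nonlinear. Smooth-term significance is a Wald-type
statistic on the penalized coefficients using the top ⌈edf⌉
eigendirections of their covariance, reported as F with residual df; the
"Ref df" column is reported equal to edf, matching the reporting convention
this mirrors. The test's calibration is established empirically — under a
null generator its p-values are approximately uniform (KS-checked across
seeds) — rather than derived.

Structural models are fit for every region regardless of the shape call.
Nonlinear structural fits are scientifically interesting mainly where the
smooth is nonlinear, but linear structural models can still win the
information-criteria comparison for regions with nonlinear smooths; running
all candidates preserves that comparison, and the report records the
shape-conditional logic instead of enforcing it.

## Residual QC

Each region is screened by the adjustment smooth model (age smooth + sex +
age×sex difference smooth + random intercept). Residuals are taken against
the **fixed-effect** prediction, i.e. excluding the random-intercept BLUP:
if the BLUP were subtracted first, a genuinely shifted subject would be
absorbed into their own intercept and escape detection. The alternative
(BLUP-inclusive residuals) is noted here as the documented road not taken.
Two rules at a default 2-SD threshold:

* between-subject: subject-mean residual ≥ 2 SD from the mean of
  subject-mean residuals, standardized by the across-subject SD of those
  means (using each subject's own available visits, so the rule is safe
  under unbalanced designs). Standardizing by the pooled residual SD is the
  documented alternative reading.
* within-subject: deviation from the subject's own mean residual ≥ 2 SD,
  standardized by the pooled within-subject SD times √(1 − 1/nᵢ); the
  finite-sample factor keeps the Gaussian null false-flag rate at the
  nominal 2·Φ(−2) ≈ 4.6%.

Flags carry z-scores and are never silently removed; an explicit exclusion
step drops flagged records to emulate what is, in practice, a
human-adjudicated decision. Degenerate data (zero residual spread) produce
zero flags rather than divide-by-zero artifacts. Flag sets are invariant
under volume rescaling.

## Synthetic cohorts

The generator emulates the study design: baseline ages uniform on
[7.60, 12.90]; wave offsets (0, 0.5, …, 4.5, 5.5, 8.5) years plus Gaussian
timing jitter (SD 0.05 y — visits are near, not on, schedule, small enough
not to distort design statistics); waves 2–12 each dropped independently
with probability 0.31 while the baseline visit is never dropped (a subject
must enter the study to exist), giving ≈ 8.6 expected scans per subject,
matching the source design's 8.3 in distribution; a 53:37 female:male
split; per-visit mean Euler numbers from a Normal(−150, 80) truncated at
zero; and five scanner-software epochs assigned by calendar position.

Generating growth models come from the published group-level estimates
(one preset per region; global volumes on the /100 scale). Subject
parameters are population values + male sex shifts + diagonal Gaussian
random effects; nonpositive inflection draws are resampled with a warning
(the power term requires a positive inflection). Motion acts per visit on
the slope-like parameter (hill or b), mirroring the selected covariate
structure. The published tables include no variance components, so the
defaults are stated conventions: between-subject SD = 5% of |parameter|
and residual SD = 2% of the trajectory midpoint (asymptote midpoint for the
logistic; fitted-line midrange over ages 7.6–21.6 otherwise). The caudate
recovery protocol in `scripts/acceptance.py` uses residual SD 150 mm³ with
the same 5% random-effect convention, as its protocol states. What the
generator does **not** emulate: segmentation error structure, scanner
upgrade discontinuities, age-dependent noise, correlated random effects,
or dropout that depends on the participant — so passing recovery tests
demonstrate estimator correctness under the stated model, not robustness
to those real-data complications.

## Problem sizes and numerical choices

Recovery and selection checks run five to ten cohorts of 90 subjects
(~760 observations each); unit tests use 20–60-subject cohorts. The inner
Gauss-Newton solves to 1e-9 relative movement; the outer L-BFGS-B uses
ftol 1e-10 with a 1e-6 finite-difference step on scaled parameters —
tightening further changes inflection estimates by < 1e-3 years while
roughly doubling run time. Acceptance recovery is judged against the mean
across five seeded cohorts with tolerance twice the empirical across-seed
standard error.

## Known limitations

* Random effects are uncorrelated by construction; a full covariance is a
  stated non-goal, and real asymptote/timing correlations would be missed.
* The Laplace likelihood is an approximation for the logistic family; at
  the noise levels studied the bias is well inside Monte-Carlo error, but
  very sparse subjects or large residual noise would degrade it.
* The smooth-term F-test is calibration-checked, not exact; its p-values
  should be read as approximate.
* eTIV enters the smooth models standardized as a parametric main effect;
  whether head size should instead scale volumes multiplicatively is a
  modelling decision the package leaves to the user (the scale used is
  recorded in dataset metadata and reports).
* Individual timing estimates are strongly shrunk when subjects have few
  visits; per-subject inflection SDs of well under a year should not be
  read off the EB spread without the shrinkage caveat.
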