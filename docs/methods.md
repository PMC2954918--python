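# Methods

This note records the statistical procedures `stabmi` implements, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical choices a maintainer would want
written down.

## Data model

A cohort is a subject-by-variable rectangle with an explicit boolean
missingness mask. The mask is authoritative: masked cells hold NaN in the
numeric payload so arithmetic cannot silently consume them, but every
routine consults the mask, never NaN-ness. Categorical variables are coded
from the declared label order in the variable spec, so codes are identical
across files, imputations and bootstrap replicates. One row per subject;
longitudinal layouts are out of scope.

## Preprocessing chain

**Outcome construction.** Persistence is defined from the relative change
(baseline − follow-up)/baseline of a symptom score; a subject improving
strictly less than the cutoff (default 50%) is persistent. The cutoff can
be derived from the data by scanning every distinct observed change value
(plus midpoints) against an external recovery criterion and taking the
threshold with the lowest total misclassification; ties break toward the
threshold nearest 0.5 (an arbitrary but deterministic rule — only the
minimal misclassification itself is statistically identified).

**Linearity.** For a continuous predictor the logistic model with a linear
term is compared against the same model augmented with quantile-group
indicators (tertiles for 3 groups, median for 2) by a likelihood-ratio
test with n_groups − 1 df. A "linear vs categorised" comparison is not
nested, so the nested augmentation test is used; it has exactly the right
null (the linear shape suffices) and the test level is the selection alpha
(0.157), so ~16% of truly linear predictors will be categorised — the
price of reusing the selection level, accepted for consistency.
Whether a severity score is dichotomised before or after the linearity
check is caller-controlled: the ops are standalone functions sequenced
by the analysis script, not a hard-wired pipeline stage.

**Collinearity.** Pairwise Pearson r on pairwise-complete observations,
computed before imputation. Pairs with |r| ≥ 0.5 are processed in
decreasing |r| (ties lexicographic); the member with the worse (larger)
clinical-priority rank is dropped; an already-dropped variable cannot
trigger further drops. This makes the filter invariant to input ordering.

**Univariable screen.** One logistic fit per candidate (categoricals as
whole dummy blocks, block LRT); retain p ≤ α = 0.157. Per candidate the
rows complete on {outcome, candidate} are used, so the screen also runs on
unimputed data. Perfect separation retains the candidate with p recorded
as 0 plus a warning — dropping a perfectly predictive candidate would be
the wrong failure mode.

**Power check.** Events per variable with events = the minority outcome
class (the conservative reading when "event" is not defined); a warning is
emitted at EPV ≤ 10.

## Imputation

MICE with predictive mean matching. Per imputation chain: initialise
missing cells by random draws from the observed marginals; for `n_iter`
cycles (default 10) visit incomplete variables in increasing-missingness
order, regress each on all other variables (linear conditional model on
the current completed data), and fill each missing cell with the observed
value of a donor drawn uniformly from the `k_donors` (default 5) cases
whose predicted means lie closest to the target's. Matching is Type-1:
donor predictions use a Bayesian draw of the coefficients
(normal–inverse-chi-square), target predictions the posterior mean, which
propagates parameter uncertainty between imputations. PMM is used for all
measurement levels, so every imputed value is an observed value of its
variable and category codes are plausible by construction; the cost is
that conditional models for categorical variables are linear in the codes,
acceptable for 3-level ordinal-ish variables. All variables except
declared id columns — including the outcome and auxiliaries — enter every
conditional model. m defaults to 5 (sufficient for stable pooled results
at these missingness levels; ~20 is a sensible upper advisory). Chains are
seeded by independent spawns of one seed, making the run bit-reproducible.
A singular conditional regression is ridge-stabilised with a warning.
Imputed-outcome rows are kept for modeling by default; callers can drop
them by restricting rows before selection.

## Modeling and selection

The logistic engine is a dense Newton solver with step-halving and
observed-information covariance, written in-package because the bootstrap
procedures need of the order of 10^5 fits per analysis and the fit is the
hot path; its estimates and log-likelihoods are cross-checked against an
independent reference implementation in the test suite. Non-convergence
and perfect separation (all fitted probabilities numerically 0/1, or
diverging linear predictors) set a `converged=False` flag rather than
raising, so resampling callers can count and exclude failed replicates.

**Backward elimination.** Drop-one likelihood-ratio p-values (categorical
predictors as whole dummy blocks); remove the largest p above α = 0.157,
refit, repeat. Ties on p are broken by removing the predictor later in
canonical (column) order, making results invariant to the ordering of the
start set. The retained set is monotone in α.

**Inclusion-fraction selection on imputed data.** The univariable screen
runs within each completed dataset; a candidate enters the pool if
screened-in in ≥ 40% of them. Backward elimination runs from the pool in
each dataset; predictors in ≥ 40% of the m final models qualify. Each
qualified predictor is then confirmed by a pooled drop-one LRT: the
per-imputation LR statistics are combined with the
average-relative-increase-in-variance correction and an F reference
(the Li–Meng–Raghunathan–Rubin statistic-pooling procedure; a median-p
fallback is available by config). Removal is iterative, largest pooled p
first — the conservative reading when the order is unspecified. With
m = 1 the whole chain reduces exactly to screen + backward elimination.
Coefficients pool by Rubin's rules: mean estimate; total variance = mean
within-variance + (1 + 1/m) × between-imputation variance.

## Two-step bootstrap stability

Step 1 draws `b1` (default 500) resamples of n rows with replacement and
re-runs the entire selection path — screen and backward elimination — in
each, because the screen is part of the unstable procedure being studied.
Predictors with inclusion fraction ≥ 40% qualify. Step 2 draws `b2`
(default 500) fresh resamples from an independent random stream and
re-selects from the qualified set only; the selected compositions are
tabulated (count, percent) with ties sorted lexicographically. Replicates
with a one-class resampled outcome or a separated fit are counted as
failed and excluded from denominators, never redrawn (redrawing would bias
toward well-behaved resamples); a warning fires above 5% failures.

On imputed data the procedure runs inside each completed dataset with
split seeds. Step-1 qualification pools the inclusion fraction over all
m × b1 models by default (`qualify: each` requires qualification in every
dataset separately — the hand-off is not uniquely defined, so both are
implemented). The step-2 table pools all m × b2 models (2500 at defaults)
and per-predictor ranks come from the pooled step-2 inclusion fraction.

Shrinking the qualified set concentrates the step-2 tabulation, so the top
model-selection frequency does not decrease — verified on a fixed resample
stream in the test suite.

## Performance and internal validation

The c-index is the all-pairs concordance probability (ties credited 0.5),
computed from midranks; its confidence interval uses the DeLong-type
paired-placement variance with a normal approximation truncated to [0, 1]
(the CI method is a package choice; alternatives differ in the third
decimal at these sample sizes). The calibration slope is the coefficient
of a logistic refit of the outcome on the model's linear predictor; it is
exactly 1 on the derivation data of a converged ML fit (score identity),
so only its out-of-sample/optimism-corrected version is informative.
Nagelkerke's R² rescales Cox–Snell R² by its attainable maximum.

Internal validation refits the *fixed* final composition in each of `b_val`
(default 200) bootstrap resamples; optimism is the mean gap between
bootstrap-sample and original-data performance over converged replicates,
and corrected = apparent − optimism. Re-running the whole selection path
inside validation (the stricter recipe) is available via
`validate: reselect`; the fixed-composition default matches the framing of
testing "each developed model". Optimism is computed for the c-index,
slope and R²; the headline report carries the c-based correction. On
imputed data each completed dataset is validated with its own seed; point
metrics pool as means and the c CI pools DeLong within-variance with
between-imputation variance on the c scale. A validation run aborts if
more than 20% of replicates fail.

## Synthetic cohorts

The generator draws correlated latent normals (Gaussian copula), maps
them column-wise to the declared measurement (affine for continuous,
quantile thresholding for binary/3-level), draws the binary outcome from a
logistic model on the standardised realised columns (so declared log-odds
are comparable across types; 0 = noise), and applies missingness: MCAR as
a flat rate, MAR as a logistic missingness model on fully observed drivers
with the intercept calibrated by root-finding to the requested rate. The
truth record (coefficients, complete outcome, event probabilities) makes
recovery tests possible.

`shoulder_preset()` emulates a primary-care shoulder-pain cohort: n = 587,
31 mixed-type candidates with Table-like means/SDs/prevalences, four true
effects (log-odds 0.35/0.30/0.28/0.25 on low-back pain, duration,
bilateral complaints, baseline disability) and the rest noise, ~12%
MAR outcome missingness likelier for younger/acute-onset subjects,
predictor missingness 0–9% with overlap via shared drivers. The effect
sizes are calibration knobs set once so a selected model's apparent
c-index lands in the mid-0.6 to low-0.7 band typical of musculoskeletal
prognosis models, and complete-case restriction discards ~25–30% of
subjects. The preset emulates marginal moments and missingness structure
only — not any real cohort's joint distribution, nonlinearities,
measurement error, or clinical conclusions; passing recovery tests on it
shows the machinery is sound under its assumptions, not that any
particular clinical model is right.

`recovery_preset()` (n = 600, four true predictors at log-odds 0.7, eight
noise, ~10% MAR on half of each driven by an observed covariate and the
outcome) is the structure-recovery benchmark. `mar_bias_preset()`
(n = 500; x1, x2 bivariate normal r = 0.4, both log-odds 1.0; 35%
missingness on x2 driven by x1 and the outcome) is the textbook design
where complete-case analysis is biased but imputation using the outcome is
valid; 35% was chosen so the bias ordering is measurable at n = 500 over
50 replications.

## Problem sizes used in tests

The acceptance suite scales the bootstrap to 100 + 100 samples (from
500 + 500) for the multiply-imputed stability benchmark and uses 20
replications for MI-5 recovery, 10 for MI-5+B, 50 for the MAR-bias
comparison and 200 for the null-retention calibration — sizes chosen so
the full suite completes in a few minutes while keeping Monte-Carlo error
well inside the asserted margins. The acceptance script runs the four
strategies at the full 500/500/200 defaults.

## Known limitations

* Conditional imputation models are linear in predictors; no interactions
  or splines (matching the standard-methodology scope).
* No MNAR sensitivity analysis; MAR validity rests on including the
  outcome and auxiliaries in the imputation models.
* No shrinkage/penalised estimation and no forward selection.
* The DeLong-based CI and the mean-over-imputations pooling of
  performance are approximations; logit-scale pooling is available by
  config.
* Frequency tables describe stability only; the bootstrap models are not
  aggregated into an ensemble predictor.
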