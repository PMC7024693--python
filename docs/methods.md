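# Methods

This note documents the models and procedures `sdqchange` implements, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical decisions a maintainer would want
written down.

## Reliable change across domains

Each SDQ problem subscale is five items scored 0/1/2 (sums 0–10); the
impact supplement is five items scored 0–3 (sum 0–15). For a subscale with
baseline score x₁ and follow-up score x₂ the Reliable Change Index is
RCI = (x₂ − x₁)/S_diff with S_diff = SD·√(2(1 − r)); negative values are in
the improvement direction because lower SDQ scores are better.

Two classification modes:

- **integer_rcc (default).** Reliable change = raw movement of
  `integer_rcc` points or more (default 3 on all three outcome subscales).
  This is the operational rule under which the published rates were
  produced, so it is the default even though 1.96·S_diff slightly exceeds
  3 for all three subscales.
- **strict_rci.** |RCI| > z_crit (default 1.96). The modes disagree
  exactly at raw changes of ±3 (for every outcome subscale, since
  1.96·S_diff > 3 holds for all three: 3.16, 3.25, 3.35); verified
  exhaustively in the tests.

The published per-subscale criteria (3.2/3.3/3.3) are kept as reference
constants but never drive computation: 1.96 × 1.71 = 3.35 rounds to 3.4,
not the published 3.3, so they cannot be regenerated self-consistently.

The overall category makes deterioration absorbing: any reliable rise ⇒
*deterioration* (even with reliable falls elsewhere); otherwise any
reliable fall ⇒ *improvement*; otherwise *no change*. Peer problems and
impact never enter classification — they are context/predictors only.
A brute-force three-rule reference classifier (written independently of
the production path) agrees on all 9,261 integer delta triples in
[−10, 10]³.

Sdiff back-derivation note: with the published internal-consistency alphas
(0.66/0.72/0.74), SD·√(2(1−α)) gives ≈1.55/1.63/1.70 — not the published
S_diff values (1.61/1.66/1.71 for emotional/conduct/hyperactivity). The
reliability source behind the published S_diff is not recoverable, so the
defaults here match S_diff itself, and the generator's retest reliabilities
are back-derived from it: r = 1 − S_diff²/(2·SD²) ⇒ 0.727/0.610/0.735.

## Threshold splitting, rates, decomposition

"Above threshold" means baseline conduct ≥ 5, emotional ≥ 6 or
hyperactivity ≥ 7 — the cuts identify membership of the most symptomatic
band, so a score equal to the cut counts as above (configurable). Rate
tables report counts, percentages rounded half-up to 2 decimals, and 95%
binomial CIs; Wilson score intervals by default (any
`statsmodels.proportion_confint` method can be selected). Published
intervals for comparable tables are wider than Wald, Wilson or
Clopper–Pearson reproductions — possibly cluster-adjusted by an unstated
method — so no CI method here claims to reproduce them.

The above-threshold decomposition counts, among overall improvers, cases
whose reliably-improving subscales intersect their baseline-elevated
subscales versus cases improving only on non-elevated subscales (same for
deterioration), and reports percentages both of the category total and of
the whole above-threshold sample, rounded to whole percent as such figures
are conventionally quoted.

## Multinomial model

The 3-category outcome is modelled with "no change" as reference; the two
contrasts are improvement-vs-no-change and deterioration-vs-no-change.
Fitting is direct Newton maximization of the multinomial log-likelihood
with step-halving, convergence at gradient max-norm < 1e-8 (cap 100
iterations), covariance = inverse observed information. Coefficients
diverging past |β| > 30 are reported as separation/empty-cell diagnostics
rather than returned. The fitter agrees with `statsmodels.MNLogit` to
machine precision and with a cold-start Nelder–Mead search to 4 decimals
in log-likelihood on fixtures.

Terms (19, plus intercept, per contrast): three baseline severities;
gender; ethnicity as the binary White vs any-other contrast (5-level
coding exists in the data model but models use the binary contrast that
matches how such tables are reported); FSM; SEN; attainment; school
climate; quality of life; baseline peer problems and impact; problem
duration as four dummies against "none"; three support flags. Continuous
predictors are standardized within the analysis sample being fitted (one
unit = one sample SD); moments are recorded in the fit for reporting.

Stages are nested: null → severity → +demographics (gender, ethnicity,
FSM) → +functioning/context (SEN, attainment, climate, QoL, peer, impact,
duration) → +support. Stage tables report AIC (−2·LL + 2·k with k = free
parameters across both contrasts; the intercept-only model has k = 2 —
this convention reproduces published null AICs exactly), McFadden
R² = 1 − LL/LL_null, and the deviance (LR) of each stage against the full
model. Inference is Wald: OR = exp(β), CI = exp(β ± 1.96·SE). The
significance policy is α = 0.05 for the full sample and a Bonferroni
α = 0.025 for the above/below-threshold samples.

## Conditional-inference trees

Association at a node is the permutation-framework linear statistic
T = Σᵢ g(xᵢ)h(yᵢ)ᵀ with h the outcome-category indicators and g the
identity (numeric and ordinal-rank predictors) or level indicators
(categorical). T is standardized by its exact permutation mean and
covariance (Strasser–Weber closed forms) and referred as a quadratic form
to a chi-square with rank degrees of freedom. The covariance is
structurally rank-deficient (indicator sums are fixed), so the quadratic
form is computed through an eigendecomposition with a relative spectral
cutoff of 1e-8 — this keeps the statistic exactly invariant to categorical
level relabelling. Constant predictors and single-class nodes give p = 1
by convention. A seeded permutation-resampling p-value (9,999 draws) is
available for small nodes (`monte_carlo_below`); the default is asymptotic
everywhere, appropriate at these sample sizes.

Variable selection (smallest Bonferroni-adjusted p ≤ α, default α = 0.05)
is separated from split search: the chosen variable's binary split
maximizes the standardized two-sample statistic between child outcome
distributions, over midpoints between adjacent observed values (numeric;
ties → smallest cutpoint) or binary level partitions (categorical; ties →
lexicographically first). Both children must hold ≥ `min_node` cases
(default 20 — no published stopping size exists; 20 keeps the chi-square
asymptotics serviceable). "Three levels" is read as three levels of splits
below the root (max_depth 3, ≤ 8 leaves). Ordered duration enters as
numeric ranks. Renderings label classes no/det/imp; a JSON export
round-trips node-for-node.

Measured calibration (sizes chosen to make the Monte-Carlo error small at
modest cost): under a global null with 10 noise predictors the root splits
in ~5% of 200 cohorts of n = 1,000; a single strong predictor is the root
split in 100% of 100 seeds.

## Synthetic cohorts

The generator emulates a two-wave secondary-school cohort at the study's
scale (defaults n = 9,074 analysed; 14,296 at T1 when attrition is
switched on; 118 school labels, uniform, with no induced clustering).

**Marginals.** Integer scores are latent Gaussians rounded and clipped to
the scale range. Rounding/clipping biases moments, so the latent location
and scale are solved numerically (Powell-hybrid root find on the exact
discrete moments) to hit the target mean/SD — the discretized population
moments equal the configured targets to solver precision, and skewness of
low-mean subscales emerges from the floor. Targets default to the study
sample's characteristics (e.g. emotional 2.61/2.18, conduct 1.96/1.88,
hyperactivity 3.72/2.35; school climate 9.44/3.09; quality of life
25.38/5.50; attainment 28.29/5.44 kept as an unbounded real score since no
scale range is published). Demographic and duration prevalences default to
the same table; a single latent "distress" factor gives an inter-subscale
correlation of 0.3 (no correlation matrix is published; configurable).

**Retest process.** T2 latents follow an AR(1) in the T1 latent with a
latent correlation solved (1-D Gauss–Hermite over a shared-factor
representation) so the *discrete* T1–T2 correlation equals the configured
reliability; the population change SD then equals S_diff = SD·√(2(1−r))
exactly, confirmed by simulation at n = 50,000 within sampling error.

**Help-seeking.** Support-flag probabilities are
inverse-logit(a + slope·z̄) with z̄ the mean standardized baseline severity
and slope 0.5 by default (a moderate confound standing in for
"deterioration prompts contact with services"); the intercept a is solved
by quadrature so the marginal prevalence stays on target whatever the
slope. Slope 0 decouples flags from severity exactly.

**Planted effects.** When any planted log-odds is nonzero (or the
propensity process is forced), each record's change category is drawn from
a multinomial logit — intercepts (−2.062, −1.957), matching overall
improvement/deterioration rates of ~10.0%/11.1%, plus Σβ·x with
continuous x standardized at the configured moments — and T2 outcome
scores are then realized so classification reproduces the drawn category
(the improving/deteriorating subscale is the one with most headroom,
echoing regression to the mean). Classification therefore remains a
genuine downstream computation while the category follows an exact,
recoverable multinomial law. When a drawn category is arithmetically
infeasible (improvement with all baseline outcome scores < 3: ~17% of
records at default marginals — the floor effect), the category is redrawn
among feasible ones with unchanged relative odds, which preserves the
log-odds-ratios between the remaining categories; measured recovery bias
on a planted log-OR of 0.7 (balanced binary predictor, n = 10,000, 50
seeds) is ≈ −0.02, and 95% Wald CIs cover the truth at ~95%.

This floor has one structural consequence: severity predictors can never
be exactly null for the change category generated through scores, because
low-severity records cannot improve. Global-null calibration of the LR
test therefore draws the outcome iid multinomial over the generated
(correlated) design — the exact null — giving a mean null-vs-full LR of
≈ 39 at df = 38, n = 2,000 over 200 seeds. The propensity-forced generator
null is the right tool for nulls on non-severity predictors.

**Attrition.** Follow-up is blanked with probability
inverse-logit(intercept + Σ log-odds): male +0.25, FSM +0.30, Black/Other
ethnicity +0.35, and +0.10 to +0.15 per SD of each baseline score
(conduct heaviest). The intercept (−0.751) was tuned once, by simulation
at n = 200,000, to a 63% retention target and frozen; at the T1 scale the
retained fraction is 63% ± 2 and retained students score lower at baseline
on every scale, including impact.

**Streams.** Structure (T1, demographics, covariates, support flags),
change noise, and attrition use independent sub-streams of the single
seed, so toggling effects or attrition never perturbs the baseline cohort.

**What the generator does not emulate**, and hence what passing tests do
not show about real data: school-level clustering (labels only — any
cluster-robust question is out of scope), item-level response processes,
measurement non-invariance, informative missingness beyond the modelled
attrition, the real joint distribution between covariates (drawn
independently except where stated), and real effect structure — published
regression coefficients and figure split-points are properties of
unavailable real data and are deliberately not targets; parameter-recovery
properties stand in for them.

## Numerical and I/O decisions

- CSV is the only external tabular format: one row per student, documented
  canonical column order, UTF-8, empty cells for absent T2 (all five T2
  columns empty = lost to follow-up; partial T2 is an error). Reading uses
  round-trip float parsing so write→read is the identity.
- Listwise deletion is the only missing-data policy (`analysable_subset`);
  no imputation. The record schema makes every other key field required,
  mirroring an eligibility rule of complete key variables.
- Prosocial subscale and age are not fields: the one never enters any
  reported model, the other is constant by design in a single school-year
  cohort.
- Percentage rounding is half-up (Decimal), matching how such tables are
  printed; internal computation is full precision.
- The attrition t-comparison uses the Welch (unequal-variance) form; the
  form used for the published comparisons is unstated, so this is a
  documented choice, with a both-groups-constant degenerate case defined
  as t = 0.
- The pipeline derives per-stage sub-seeds from the global seed by hashing,
  so stages can be re-run in isolation; the manifest records a SHA-256 of
  the canonicalized config. Model fitting failures on degenerate
  sub-samples (separation at small n) are written as flagged diagnostics
  rather than aborting the run.

## Known limitations

- Wald CIs undercover slightly for very sparse cells (duration × category
  at small n); profile-likelihood CIs are out of scope.
- Asymptotic chi-square p-values in trees are anti-conservative for nodes
  far below ~20 cases per class; use `monte_carlo_below` there.
- The integer change criterion treats a 3-point change identically on all
  three subscales even though their S_diff values differ slightly; the
  strict mode exists precisely to probe that sensitivity.
- Generated cohorts satisfy the published marginal moments, not any real
  joint distribution; conclusions about real-data effect sizes cannot be
  read off synthetic fits.
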