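# Methods

## Problem setting

Observational treatment-effect estimation with a binary treatment W, binary
outcomes Y (one "benefit", one "detriment"), and unmeasured severity that
affects both treatment choice and outcomes. Identification comes from
local-area practice-style variation: areas differ in how aggressively they
treat for reasons assumed unrelated to the severity mix of their patients.
The package turns that variation into patient-level effect estimates, then
into a small set of discovered patient classes, each scrutinized with
classical instrumental-variable regression.

## The instrument

A logistic choice model P(W=1 | X) is fit by maximum likelihood on
binary-encoded baseline factors (each ordinal level gets its own indicator,
lowest level as reference). The area surgery ratio for area a is

    ASR_a = (# treated in a) / Σ_{i in a} p̂_i .

Because the model has an intercept, the ML score equation makes Σ p̂_i equal
the total treated count, so the predicted-sum-weighted mean ASR is exactly 1
— an identity tested to 1e-8. Patients inherit ASR of their resident area;
quintiles are cut over *patients* (ties assigned to the lower quintile), so
each quintile holds 20% of patients up to tie blocks.

Numerical choices: complete separation in the choice model is a hard error
naming the separating column; a sparse indicator level on which treatment is
constant (quasi-separation, which has no finite ML coefficient but harmless
fitted probabilities) is collapsed into the reference level. An optional
leave-area-out mode refits the choice model without each area before
predicting it, guarding against own-area contamination; the default is the
single full-cohort fit.

## Honest IV causal forest

For each of `num_trees` trees a 25% subsample is drawn without replacement
and split 50/50 into a split half and an honest half. Node-level effects are
Wald ratios τ = Cov(Y,Z)/Cov(W,Z). Split search is exhaustive over `mtry`
(= ⌈√p⌉ by default) randomly drawn covariates and all thresholds ("level ≤ c"
for ordinals, 0-vs-1 for binaries), maximizing the heterogeneity score
(n_L n_R / n²)(τ_L − τ_R)² computed on the split half. A candidate split is
admissible only if both children satisfy the minimum leaf size and the
denominator guard |Cov(W,Z)| > 1e-6·sd(W)·sd(Z) in *both* halves. Leaf
effects are recomputed on the honest half only. Ties break to the lowest
covariate index, then the lowest threshold. A tree whose root denominator
fails the guard is redrawn (10 attempts, then a hard error). Predictions
average leaf effects over all trees; trees are seeded by (master seed, tree
index), so results are independent of execution order.

This is a from-scratch implementation of the exhaustive child-Wald
objective; large-scale libraries use a gradient-based approximation of the
same objective and forest-weighted estimating equations, which differ in
finite samples. No local centering of Y, W, Z is applied by default (an
option flag exists); honesty can be disabled for diagnostics.

Known behavior (tested): with the minimum leaf size forcing stumps, the
forest mean converges to the full-sample Wald ratio; the inter-decile range
of estimates is non-increasing in the minimum leaf size while the mean
moves by < 0.02; percentile summaries at 1,000 vs 3,000 trees differ by
< 0.01 (desk-scale analyses therefore run at a few hundred trees).

## Ex-post reference classes

A depth-limited CART (default depth 3, variance-reduction splits, exhaustive
search, same ordinal split rule and tie-breaks as the forest) is fit to the
patient-level estimates. The minimum node size defaults to the minimum leaf
size of the source forest so every class stays estimable by 2SLS. Nodes are
numbered breadth-first from 1; depth-3 classes carry labels 8–15, and a
branch that stops early keeps its shallower label. No pruning beyond the
depth limit. Partitions are compared by (i) exact matches of canonicalized
predicate intervals, (ii) an adjusted Rand index over patient pairs, and
(iii) Kendall concordance of effect ranks among matched classes.

## Within-class 2SLS

First stage: treatment on instrument + binary-encoded free covariates
(+ optional area-level controls). F is the squared t-ratio of the single
instrument; F > 10 is flagged "non-weak". Second stage: outcome on fitted
treatment + the same controls (linear probability model — the estimand is
an absolute probability effect). Standard errors use the conventional 2SLS
covariance with residuals formed against *original* treatment;
heteroskedasticity-robust and area-clustered options exist (default
homoskedastic). Collinear control columns are dropped by a deterministic
left-to-right scan; covariate levels pinned by the class predicates encode
as constants and drop automatically. With no controls the estimator reduces
algebraically to the Wald ratio (tested to 1e-12) and F equals the squared
first-stage t (tested to 1e-10). Significance stars at p < .1/.05/.01;
cross-tab colors at α = 0.05: green (benefit positive & significant,
detriment not), red (the reverse), yellow (both), orange (neither).

The class-level estimand is a LATE: the average effect among the class
members whose treatment is moved by the instrument. Under essential
heterogeneity it is not an ATE/ATT/ATU, and no such extrapolation is
attempted.

## Synthetic cohort generator

The generator emulates an elderly fracture cohort: 20,000 patients in 100
areas by default, ordinal age group (66–69 / 70–75 / 76–79 / 80–85 / 86+),
CCI and FRI with right-skewed marginals, prior-cost quintiles equally
populated by construction, binary demographic/diagnosis flags, and a mild
positive rank correlation (0.3 Gaussian-copula driver) among CCI, FRI and
prior cost — the joint distribution of those scores is a modeling choice,
not data-derived.

Treatment follows a latent-index threshold (probit-style) rule:

    W = 1{ intercept + β'x + γ_a·style(area) + γ_c·complexity + ε > 0 } ,

with area styles N(0, 0.5), γ_a = 1.2 (a deliberately strong instrument),
γ_c = 0.5 and ε ~ N(0,1). The threshold rule makes complier status exact:
holding each patient's ε fixed, treatment is re-thresholded with the area
style pinned at its 10th and 90th patient-level percentiles; a complier is a
patient who switches on. γ_a ≥ 0 enforces one-sided monotonicity.

Latent complexity (N(0,1), unobservable to all estimation stages) loads on
outcome baselines (−0.12 benefit, +0.12 detriment per sd — classic
confounding) and on the treatment effect itself (+0.05 per sd — essential
heterogeneity / sorting on the gain; set to 0 to disable).

Planted effects are piecewise-constant over eight cells of (CCI = 0 vs > 0,
age < 80 vs 80+, prior cost in top-two quintiles vs not), spanning roughly
−0.3 to +0.6 — the magnitude of class-level effect spreads reported in
area-instrument surgery studies. The hierarchy (CCI strongest, then age,
then cost) gives the class-discovery stage a recoverable target at desk
scale: the 86+ and top-quintile strata alone are too thin to be splittable
at a 200-patient minimum leaf with 20,000 patients, which is why the bands
are 80+ and top-two-quintiles. Potential outcomes are drawn from a shared
uniform per patient (monotone coupling); probabilities are clipped to [0,1]
after the complexity shift, and the stored per-patient effect is the exact
post-clip probability difference, so ground-truth LATEs are exact averages
of stored values.

What the generator does *not* emulate: claims-level outcome construction
(diagnosis codes, cost accounting), geography beyond exchangeable areas,
time trends, measurement error in covariates, and area-level confounding
(styles are independent of patient composition by construction). Passing
tests therefore demonstrate internal validity of the estimation chain under
the stated model, not robustness to instrument invalidity.

## Problem sizes and determinism

Tests and the acceptance script run forests of 200 trees on cohorts of
20,000 patients — forest-size insensitivity above ~1,000 trees is itself
verified once, and the conventional 3,000–5,000-tree grid is available via
configuration. All randomness flows from a master seed through documented
(seed, index) derivations; pipeline artifacts are written with fixed float
formatting and are byte-identical across re-runs with the same seed.

## Known limitations

- Quintile tie-blocks can make quintile sizes uneven when the instrument
  takes few distinct values (few areas).
- The forest provides no per-patient confidence intervals and no variable
  importance; inference happens at the class level via 2SLS.
- Class discovery inherits CART's instability near ties; consistency
  metrics across parameter settings are the intended diagnostic.
- With very weak instruments the denominator guard rejects trees and the
  root-retry budget can exhaust; this surfaces as a hard error rather than
  silently exploding Wald ratios.
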