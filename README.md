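# ivforest

Personalized treatment-effect evidence from observational data, built around
a local-area practice-style instrument. `ivforest` implements the full
chain used in comparative-effectiveness studies of elective surgery where
treatment choice is confounded by unmeasured severity:

1. **Area surgery ratio (ASR) instrument.** For each local area,
   `ASR = (observed treated count) / (Σ model-predicted treatment
   probabilities)`, with the probabilities from a logistic choice model of
   treatment on baseline factors. Each patient inherits their resident
   area's ASR; patients are grouped into patient-count quintiles of it.
2. **Honest instrumental-variable causal forest.** Each tree is grown on a
   random 25% subsample split into a split half and an honest half. Within
   a node the effect is the Wald ratio `τ = Cov(Y,Z)/Cov(W,Z)` (outcome Y,
   treatment W, instrument Z); splits maximize
   `n_L n_R / n² · (τ_L − τ_R)²` subject to a minimum leaf size and a
   denominator guard in both halves. A patient's estimate is the average
   leaf effect over all trees.
3. **Ex-post reference classes.** A depth-3 regression tree (CART,
   variance-reduction splits) fit to the patient-level estimates turns them
   into a small set of interpretable classes defined *after* estimation,
   with breadth-first node labels (depth-3 classes are nodes 8–15) and
   consistency metrics (exact definition matches, adjusted-Rand membership
   agreement) across forest parameter settings.
4. **Within-class 2SLS.** For every class: the local average treatment
   effect (LATE) with standard errors, the first-stage F statistic of the
   instrument (F > 10 = "non-weak"), treatment rates in the bottom/top
   cohort instrument quintiles, and a benefit × detriment cross-tabulation
   whose cells are colored green / red / yellow / orange by the
   significance pattern of the two class fits.

A synthetic cohort generator with planted piecewise-constant effects,
latent "fracture complexity" confounding, and sorting-on-the-gain makes
every stage testable with full ground truth (exact per-patient complier
flags and true effects).

## Worked example

```python
import ivforest as iv

cfg = iv.SimulationConfig(n_patients=20_000, n_areas=100, seed=1)
cohort = iv.simulate_cohort(cfg)
cohort_iv, inst = iv.attach_instrument(cohort)
print(f"treatment rate {cohort['treatment'].mean():.3f}, "
      f"weighted mean ASR {inst.weighted_mean_asr:.6f}")

model = iv.fit_forest(cohort_iv, "benefit",
                      iv.ForestConfig(num_trees=200, min_leaf_size=200, seed=7))
tau = iv.predict_effects(model, cohort_iv)
print(iv.summarize_distribution(tau))

classes = iv.fit_cart(tau, cohort_iv, max_depth=3, min_node=200)
fits = iv.fit_class_table(cohort_iv, classes, "benefit")
print(fits[["class_label", "definition", "n", "first_stage_F", "ive", "se"]])
```

prints (seed 1, abridged to three significant digits):

```
treatment rate 0.306, weighted mean ASR 1.000000
DistributionSummary(mean=0.200, sd=0.113, pct_positive=99.5, min=-0.016,
                    p10=0.051, p25=0.113, p50=0.176, p75=0.325, p90=0.364,
                    max=0.395)
   class_label                                        definition    ive     se
0            8  age_group <= 3 & cci == 0 & prior_cost_quintile…  0.349  0.081
1            9  age_group <= 3 & cci == 0 & prior_cost_quintile…  0.508  0.046
2           10                         age_group == 4 & cci == 0  0.222  0.084
3           11                         age_group == 5 & cci == 0  0.323  0.106
4           12  age_group <= 3 & cci > 0 & prior_cost_quintile…   0.022  0.053
5           13  age_group <= 3 & cci > 0 & prior_cost_quintile…   0.233  0.052
6           14  age_group > 3 & cci > 0 & prior_cost_quintile…   -0.196  0.058
7           15  age_group > 3 & cci > 0 & prior_cost_quintile…    0.124  0.090
```

The distribution says the forest attributes a positive benefit effect to
nearly all patients, with substantial heterogeneity (inter-decile range
≈ 0.31). The class tree recovers exactly the covariates the generator
planted (CCI, age band, prior-cost band), and each class row reports the
class definition, the 2SLS LATE and its standard error (the full table
also carries n, treatment rates and the first-stage F, which sits far
above the weak-instrument threshold of 10 under the default
strong-instrument conditions). On synthetic cohorts the class-level 2SLS
estimates track the planted complier-average effects, while the naive
treated-minus-untreated difference is biased by the planted confounding.

The same pipeline is scriptable end to end:

```sh
ivforest run --seed 1 --out run1       # simulate → instrument → forests →
                                       # classes → consistency → 2SLS
ivforest report --run-dir run1
```

Real cohorts enter as a delimited text table (see
`ivforest.pipeline.RunConfig(cohort_path=...)`); columns with the `truth_`
prefix are reserved for synthetic ground truth and are ignored by every
estimation stage.

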