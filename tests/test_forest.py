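"""Honest IV causal forest: Wald algebra, tree growth, forest behavior."""

import numpy as np
import pandas as pd
import pytest

import ivforest as iv
from ivforest.forest import (
    CausalTree,
    ForestConfig,
    _derive_seed,
    leaf_wald,
    summarize_distribution,
)
from ivforest.schema import COVARIATE_NAMES
from conftest import make_instrumented_cohort


def iv_frame(Y, W, Z, effect_cov=None):
    """Cohort-shaped frame around raw (Y, W, Z) arrays for forest entry."""
    n = len(Y)
    data = {
        "patient_id": np.arange(n),
        "area_id": np.arange(n) % 10,
        "treatment": np.asarray(W),
        "y_benefit": np.asarray(Y),
        "instrument": np.asarray(Z),
    }
    for name in COVARIATE_NAMES:
        lo = 1 if name in ("age_group", "prior_cost_quintile") else 0
        data[name] = np.full(n, lo)
    if effect_cov is not None:
        data["sex"] = np.asarray(effect_cov)
    return pd.DataFrame(data)


def planted_binary_cohort(n, tau1=0.4, tau0=0.0, seed=0):
    """One binary covariate drives the effect; Z is a strong instrument."""
    rng = np.random.default_rng(seed)
    sex = rng.integers(0, 2, n)
    z = rng.normal(0, 1, n)
    w = (0.9 * z + rng.normal(0, 1, n) > 0).astype(int)
    tau = np.where(sex == 1, tau1, tau0)
    p0 = 0.4
    y = (rng.uniform(size=n) < p0 + tau * w).astype(int)
    return iv_frame(y, w, z, effect_cov=sex), sex


class TestLeafWald:
    def test_perfect_compliance_reduces_to_mean_difference(self):
        rng = np.random.default_rng(0)
        w = rng.integers(0, 2, 200).astype(float)
        y = 0.3 * w + rng.normal(0, 1, 200)
        est, _ = leaf_wald(y, w, w)
        assert est == pytest.approx(y[w == 1].mean() - y[w == 0].mean(), abs=1e-12)

    def test_binary_instrument_wald_ratio(self):
        # Z=1: mean Y 0.6, mean W 0.8; Z=0: mean Y 0.4, mean W 0.3 -> 0.4
        z = np.repeat([1.0, 0.0], 10)
        y = np.r_[np.repeat([1.0], 6), np.repeat([0.0], 4),
                  np.repeat([1.0], 4), np.repeat([0.0], 6)]
        w = np.r_[np.repeat([1.0], 8), np.repeat([0.0], 2),
                  np.repeat([1.0], 3), np.repeat([0.0], 7)]
        est, denom = leaf_wald(y, w, z)
        assert est == pytest.approx((0.6 - 0.4) / (0.8 - 0.3), abs=1e-12)
        assert denom == pytest.approx(0.25 * 0.5, abs=1e-12)

    def test_matches_two_stage_regression_oracle(self):
        """Oracle: closed-form 2SLS with intercepts on the same 20 rows."""
        rng = np.random.default_rng(3)
        z = rng.normal(0, 1, 20)
        w = (z + rng.normal(0, 1, 20) > 0).astype(float)
        y = 0.5 * w + rng.normal(0, 1, 20)
        est, _ = leaf_wald(y, w, z)
        # stage 1: project W on [1, Z]; stage 2: regress Y on [1, W_hat]
        A = np.column_stack([np.ones(20), z])
        w_hat = A @ np.linalg.lstsq(A, w, rcond=None)[0]
        B = np.column_stack([np.ones(20), w_hat])
        beta = np.linalg.lstsq(B, y, rcond=None)[0]
        assert est == pytest.approx(beta[1], abs=1e-10)


class TestTreeGrowth:
    def test_two_cell_first_split_recovers_covariate(self):
        """With one planted binary effect modifier and all covariates in the
        candidate set, the root split lands on it in >=95% of seeded trees."""
        df, sex = planted_binary_cohort(4000, seed=1)
        sex_idx = COVARIATE_NAMES.index("sex")
        hits = 0
        n_trees = 60
        model = iv.fit_forest(
            df, "benefit",
            ForestConfig(num_trees=n_trees, min_leaf_size=200, seed=5,
                         mtry=len(COVARIATE_NAMES)),
        )
        for tree in model.trees:
            if tree.feature[0] == sex_idx:
                hits += 1
        assert hits / n_trees >= 0.95

    def test_large_min_leaf_forces_stump(self):
        df, _ = planted_binary_cohort(2000, seed=2)
        # subsample 500 -> halves of 250; min_leaf 200 > 250/2 blocks any split
        model = iv.fit_forest(
            df, "benefit", ForestConfig(num_trees=5, min_leaf_size=200, seed=1)
        )
        for tree in model.trees:
            assert tree.n_nodes == 1 and tree.feature[0] == -1

    def test_homogeneous_effect_near_stump_estimate(self):
        """No heterogeneity to find: forest mean lands on the planted effect."""
        rng = np.random.default_rng(4)
        n = 20_000
        z = rng.normal(0, 1, n)
        w = (z + rng.normal(0, 1, n) > 0).astype(int)
        y = (rng.uniform(size=n) < 0.4 + 0.2 * w).astype(int)
        df = iv_frame(y, w, z)
        model = iv.fit_forest(
            df, "benefit", ForestConfig(num_trees=200, min_leaf_size=400, seed=9)
        )
        tau = iv.predict_effects(model, df)
        assert abs(tau.mean() - 0.2) < 0.02


class TestForest:
    def test_same_seed_identical_models(self):
        df, _ = planted_binary_cohort(3000, seed=3)
        cfg = ForestConfig(num_trees=20, min_leaf_size=100, seed=77)
        t1 = iv.predict_effects(iv.fit_forest(df, "benefit", cfg), df)
        t2 = iv.predict_effects(iv.fit_forest(df, "benefit", cfg), df)
        assert np.array_equal(t1, t2)

    def test_single_tree_predictions_equal_leaf_assignment(self):
        df, _ = planted_binary_cohort(3000, seed=4)
        model = iv.fit_forest(
            df, "benefit", ForestConfig(num_trees=1, min_leaf_size=100, seed=3)
        )
        from ivforest import schema
        X = schema.covariate_matrix(df)
        assert np.array_equal(iv.predict_effects(model, df), model.trees[0].predict(X))

    def test_stump_forest_converges_to_full_sample_wald(self):
        """Stump forest = average of per-subsample Wald ratios, which
        approaches the full-sample Wald ratio as trees accumulate."""
        rng = np.random.default_rng(6)
        n = 4000
        z = rng.normal(0, 1, n)
        w = (z + rng.normal(0, 1, n) > 0).astype(int)
        y = (rng.uniform(size=n) < 0.4 + 0.25 * w).astype(int)
        df = iv_frame(y, w, z)
        model = iv.fit_forest(
            df, "benefit",
            ForestConfig(num_trees=1000, min_leaf_size=n, seed=2, honesty=False),
        )
        tau = iv.predict_effects(model, df)
        full, _ = leaf_wald(y.astype(float), w.astype(float), z)
        assert np.ptp(tau) == 0  # every patient shares the stump-forest mean
        assert abs(tau.mean() - full) < 0.01

    def test_prediction_is_mean_of_tree_leaf_effects(self):
        stump = lambda e: CausalTree(
            feature=np.array([-1]), threshold=np.array([0]),
            left=np.array([-1]), right=np.array([-1]),
            effect=np.array([e]), n_honest=np.array([10]),
            denom=np.array([1.0]),
        )
        model = iv.CausalForestModel(
            trees=[stump(0.1), stump(0.3)],
            config=ForestConfig(num_trees=2),
            feature_names=COVARIATE_NAMES,
        )
        df, _ = planted_binary_cohort(50, seed=5)
        assert np.allclose(iv.predict_effects(model, df), 0.2, atol=1e-15)

    def test_planted_two_cell_group_means(self):
        """Group means of estimates recover the planted 0.4 / 0.0 cells."""
        df, sex = planted_binary_cohort(20_000, seed=7)
        model = iv.fit_forest(
            df, "benefit",
            ForestConfig(num_trees=200, min_leaf_size=200, seed=11,
                         mtry=len(COVARIATE_NAMES)),
        )
        tau = iv.predict_effects(model, df)
        assert abs(tau[sex == 1].mean() - 0.4) < 0.03
        assert abs(tau[sex == 0].mean() - 0.0) < 0.03


class TestDistributionSummary:
    def test_constant(self):
        s = summarize_distribution(np.full(50, 0.2))
        assert s.mean == pytest.approx(0.2, abs=1e-12)
        assert s.sd == pytest.approx(0.0, abs=1e-12)
        assert s.pct_positive == 100
        assert s.min == s.p50 == s.max == 0.2

    def test_three_values(self):
        s = summarize_distribution(np.array([-1.0, 0.0, 1.0]))
        assert s.mean == 0 and s.p50 == 0
        assert s.pct_positive == pytest.approx(100 / 3)

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(8)
        v = rng.normal(0, 1, 1000)
        s = summarize_distribution(v)
        srt = np.sort(v)

        def q(p):  # linear-interpolation percentile from the sorted sample
            h = (len(srt) - 1) * p
            lo = int(np.floor(h))
            return srt[lo] + (h - lo) * (srt[min(lo + 1, len(srt) - 1)] - srt[lo])

        assert s.min == srt[0] and s.max == srt[-1]
        for field, p in (("p10", 0.1), ("p25", 0.25), ("p50", 0.5),
                         ("p75", 0.75), ("p90", 0.9)):
            assert getattr(s, field) == pytest.approx(q(p), abs=1e-12)
        assert s.mean == pytest.approx(v.mean(), abs=1e-12)
        assert s.sd == pytest.approx(v.std(ddof=1), abs=1e-12)
        assert s.pct_positive == pytest.approx((v > 0).mean() * 100, abs=1e-12)

    def test_order_statistics_monotone(self):
        rng = np.random.default_rng(9)
        s = summarize_distribution(rng.normal(0, 1, 137))
        vals = [s.min, s.p10, s.p25, s.p50, s.p75, s.p90, s.max]
        assert all(a <= b for a, b in zip(vals, vals[1:]))


def test_forest_size_insensitivity(seed_sweep):
    """Estimate distributions stabilize in forest size: percentile summaries
    at 1,000 vs 3,000 trees differ by < 0.01 everywhere."""
    df2 = seed_sweep[0]["instrumented"]
    summaries = {}
    for nt in (1000, 3000):
        model = iv.fit_forest(
            df2, "benefit",
            ForestConfig(num_trees=nt, min_leaf_size=200, seed=_derive_seed(55, nt)),
        )
        summaries[nt] = summarize_distribution(iv.predict_effects(model, df2))
    a, b = summaries[1000].as_dict(), summaries[3000].as_dict()
    for key in ("mean", "p10", "p25", "p50", "p75", "p90"):
        assert abs(a[key] - b[key]) < 0.01, key


def test_confounding_resistance():
    """With latent complexity loading on both treatment and baseline outcome
    (level confounding, no effect interaction), the forest mean tracks the
    true mean effect better than the naive treated-minus-untreated
    difference on >= 90% of seeds."""
    wins = 0
    n_seeds = 20
    for seed in range(n_seeds):
        _, df, df2, _ = make_instrumented_cohort(
            seed, complexity_effect_interaction=0.0
        )
        model = iv.fit_forest(
            df2, "benefit",
            ForestConfig(num_trees=200, min_leaf_size=200,
                         seed=_derive_seed(4000, seed)),
        )
        tau_hat = iv.predict_effects(model, df2)
        true_mean = df["truth_tau_benefit"].mean()
        y = df["y_benefit"].to_numpy()
        w = df["treatment"].to_numpy().astype(bool)
        naive = y[w].mean() - y[~w].mean()
        if abs(tau_hat.mean() - true_mean) < abs(naive - true_mean):
            wins += 1
    assert wins / n_seeds >= 0.9
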