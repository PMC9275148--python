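"""Honest, subsampled instrumental-variable causal forest.

Each tree is grown on a random 25% subsample of the cohort, split 50/50 into
a *split half* used to search for partitions and an *honest half* used to
estimate leaf effects, so that the data that choose the partition never
score it.  Within any node the treatment effect is the Wald ratio

    tau = Cov(Y, Z) / Cov(W, Z)

using only the treatment variation associated with the instrument Z.  Splits
greedily maximize the heterogeneity score

    (n_L * n_R / n^2) * (tau_L - tau_R)^2

over candidate covariates and thresholds, subject to a minimum leaf size and
a scale-free guard on the Wald denominator in both halves.  A patient's
final estimate is the unweighted average of their leaf effect across all
trees in the forest.

The exhaustive child-Wald split search is exact at the scale this package
targets; gradient-based approximations used by large-scale implementations
trade that exactness for speed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import schema
from .schema import COVARIATE_NAMES

__all__ = [
    "ForestConfig",
    "CausalTree",
    "CausalForestModel",
    "DistributionSummary",
    "leaf_wald",
    "grow_tree",
    "fit_forest",
    "predict_effects",
    "summarize_distribution",
    "estimate_grid",
    "write_forest",
]


@dataclass
class ForestConfig:
    """Tuning parameters of the forest.

    ``num_trees`` and ``min_leaf_size`` are the two parameters the method is
    most sensitive to; the conventional grid crosses {3000, 4000, 5000}
    trees with minimum leaf sizes {50, 100, 200, 300, 400}, but any positive
    integers are accepted (desk-scale studies run fine at a few hundred
    trees).
    """

    num_trees: int = 4000
    min_leaf_size: int = 200
    subsample_fraction: float = 0.25
    honesty: bool = True
    split_fraction: float = 0.5
    mtry: int | None = None          # default ceil(sqrt(p))
    seed: int = 0
    denom_tol_scale: float = 1e-6    # |Cov(W,Z)| must exceed scale*sd(W)*sd(Z)
    center: bool = False             # residualize Y,W,Z on covariates first
    max_retries: int = 10

    def validate(self) -> None:
        if self.num_trees < 1 or self.min_leaf_size < 1:
            raise ValueError("num_trees and min_leaf_size must be >= 1")
        if not (0 < self.subsample_fraction <= 1):
            raise ValueError("subsample_fraction must be in (0, 1]")
        if not (0 < self.split_fraction < 1):
            raise ValueError("split_fraction must be in (0, 1)")


@dataclass
class CausalTree:
    """Flat arrays over nodes; children always follow their parent."""

    feature: np.ndarray    # int, -1 for leaves
    threshold: np.ndarray  # int split level ("x <= t" goes left)
    left: np.ndarray
    right: np.ndarray
    effect: np.ndarray     # honest Wald estimate (leaves)
    n_honest: np.ndarray
    denom: np.ndarray      # honest Cov(W, Z) (leaves)

    @property
    def n_nodes(self) -> int:
        return len(self.feature)

    def predict(self, X: np.ndarray) -> np.ndarray:
        assign = np.zeros(len(X), dtype=np.int64)
        for i in range(self.n_nodes):
            f = self.feature[i]
            if f < 0:
                continue
            idx = np.nonzero(assign == i)[0]
            if len(idx) == 0:
                continue
            go_left = X[idx, f] <= self.threshold[i]
            assign[idx[go_left]] = self.left[i]
            assign[idx[~go_left]] = self.right[i]
        return self.effect[assign]


@dataclass
class CausalForestModel:
    trees: list[CausalTree]
    config: ForestConfig
    feature_names: tuple[str, ...]
    outcome: str = ""


@dataclass
class DistributionSummary:
    mean: float
    sd: float
    pct_positive: float
    min: float
    p10: float
    p25: float
    p50: float
    p75: float
    p90: float
    max: float

    def as_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


# ---------------------------------------------------------------------------
# Wald machinery

def leaf_wald(Y: np.ndarray, W: np.ndarray, Z: np.ndarray) -> tuple[float, float]:
    """Wald effect Cov(Y,Z)/Cov(W,Z) and the denominator Cov(W,Z).

    With Z = W this reduces to the two-group mean-outcome difference for
    binary W.  Callers must treat a denominator below the tolerance as
    invalid rather than dividing by it.
    """
    n = len(Y)
    if n < 2:
        raise ValueError("need at least 2 observations")
    zm = Z.mean()
    cov_yz = (Y * Z).mean() - Y.mean() * zm
    cov_wz = (W * Z).mean() - W.mean() * zm
    if cov_wz == 0:
        return math.nan, 0.0
    return cov_yz / cov_wz, cov_wz


class _HalfStats:
    """Per-level aggregate machinery for one data half at one node."""

    __slots__ = ("idx", "n", "Y", "W", "Z", "YZ", "WZ", "Z2", "W2")

    def __init__(self, data: "_TreeData", idx: np.ndarray):
        self.idx = idx
        self.n = len(idx)
        self.Y = data.Y[idx]
        self.W = data.W[idx]
        self.Z = data.Z[idx]
        self.YZ = data.YZ[idx]
        self.WZ = data.WZ[idx]
        self.Z2 = data.Z2[idx]
        self.W2 = data.W2[idx]

    def level_sums(self, codes: np.ndarray, minlength: int):
        cnt = np.bincount(codes, minlength=minlength).astype(float)
        out = [cnt]
        for arr in (self.Y, self.W, self.Z, self.YZ, self.WZ, self.Z2, self.W2):
            out.append(np.bincount(codes, weights=arr, minlength=minlength))
        return out

    def cov_wz(self) -> tuple[float, float]:
        """(Cov(W,Z), tolerance) on this half."""
        n = self.n
        mw, mz = self.W.mean(), self.Z.mean()
        cov = self.WZ.mean() - mw * mz
        var_w = self.W2.mean() - mw * mw
        var_z = self.Z2.mean() - mz * mz
        return cov, math.sqrt(max(var_w, 0.0) * max(var_z, 0.0))

    def wald(self) -> tuple[float, float]:
        mz = self.Z.mean()
        cov_yz = self.YZ.mean() - self.Y.mean() * mz
        cov_wz = self.WZ.mean() - self.W.mean() * mz
        return (cov_yz / cov_wz if cov_wz != 0 else math.nan), cov_wz


class _TreeData:
    """Cohort arrays shared by all trees of one forest."""

    def __init__(self, X: np.ndarray, Y: np.ndarray, W: np.ndarray, Z: np.ndarray):
        self.X = X
        self.Y = Y.astype(float)
        self.W = W.astype(float)
        self.Z = Z.astype(float)
        self.YZ = self.Y * self.Z
        self.WZ = self.W * self.Z
        self.Z2 = self.Z * self.Z
        self.W2 = self.W * self.W
        self.minlength = int(X.max()) + 1


def _best_split(
    data: _TreeData,
    S: _HalfStats,
    H: _HalfStats,
    features: np.ndarray,
    min_leaf: int,
    tol_scale: float,
):
    """Exhaustive admissible-split search; returns (score, feature, thr) or None.

    Ties break to the lowest covariate index, then the lowest threshold,
    enforced by iterating features/thresholds in ascending order and
    requiring strict improvement.
    """
    best = None
    ml = data.minlength
    for f in features:
        codes_S = data.X[S.idx, f]
        codes_H = data.X[H.idx, f]
        (cnt_s, y_s, w_s, z_s, yz_s, wz_s, z2_s, w2_s) = S.level_sums(codes_S, ml)
        (cnt_h, _y_h, w_h, z_h, _yz_h, wz_h, z2_h, w2_h) = H.level_sums(codes_H, ml)

        # left-child cumulative sums at threshold t (= levels 0..t)
        def cums(a):
            return np.cumsum(a)[:-1]  # topmost level can never be a left cut

        cl_s = cums(cnt_s)
        cl_h = cums(cnt_h)
        cr_s = S.n - cl_s
        cr_h = H.n - cl_h
        ok_n = (
            (cl_s >= min_leaf) & (cr_s >= min_leaf)
            & (cl_h >= min_leaf) & (cr_h >= min_leaf)
        )
        if not ok_n.any():
            continue

        def side_stats(cnt, y, w, z, yz, wz, z2, w2, left: bool, n_tot):
            if left:
                c = cums(cnt); ys = cums(y); ws = cums(w); zs = cums(z)
                yzs = cums(yz); wzs = cums(wz); z2s = cums(z2); w2s = cums(w2)
            else:
                c = n_tot - cums(cnt)
                ys = y.sum() - cums(y); ws = w.sum() - cums(w)
                zs = z.sum() - cums(z); yzs = yz.sum() - cums(yz)
                wzs = wz.sum() - cums(wz); z2s = z2.sum() - cums(z2)
                w2s = w2.sum() - cums(w2)
            with np.errstate(invalid="ignore", divide="ignore"):
                cov_yz = yzs / c - (ys / c) * (zs / c)
                cov_wz = wzs / c - (ws / c) * (zs / c)
                var_w = w2s / c - (ws / c) ** 2
                var_z = z2s / c - (zs / c) ** 2
            tol = tol_scale * np.sqrt(np.clip(var_w, 0, None) * np.clip(var_z, 0, None))
            return c, cov_yz, cov_wz, tol

        cS_L, cyzS_L, cwzS_L, tolS_L = side_stats(cnt_s, y_s, w_s, z_s, yz_s, wz_s, z2_s, w2_s, True, S.n)
        cS_R, cyzS_R, cwzS_R, tolS_R = side_stats(cnt_s, y_s, w_s, z_s, yz_s, wz_s, z2_s, w2_s, False, S.n)
        _, _, cwzH_L, tolH_L = side_stats(cnt_h, _y_h, w_h, z_h, _yz_h, wz_h, z2_h, w2_h, True, H.n)
        _, _, cwzH_R, tolH_R = side_stats(cnt_h, _y_h, w_h, z_h, _yz_h, wz_h, z2_h, w2_h, False, H.n)

        ok = (
            ok_n
            & (np.abs(cwzS_L) > tolS_L) & (np.abs(cwzS_R) > tolS_R)
            & (np.abs(cwzH_L) > tolH_L) & (np.abs(cwzH_R) > tolH_R)
        )
        if not ok.any():
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            tau_L = cyzS_L / cwzS_L
            tau_R = cyzS_R / cwzS_R
            score = (cS_L * cS_R / float(S.n) ** 2) * (tau_L - tau_R) ** 2
        score = np.where(ok & np.isfinite(score), score, -np.inf)
        t = int(np.argmax(score))  # argmax takes the first (lowest) threshold on ties
        if score[t] > 0 and (best is None or score[t] > best[0]):
            best = (float(score[t]), int(f), t)
    return best


def grow_tree(
    data: _TreeData,
    sub_idx: np.ndarray,
    config: ForestConfig,
    rng: np.random.Generator,
) -> CausalTree | None:
    """Grow one honest IV tree on a subsample; None if the root is invalid."""
    m = len(sub_idx)
    if config.honesty:
        perm = rng.permutation(sub_idx)
        n_split = int(round(config.split_fraction * m))
        idx_S, idx_H = perm[:n_split], perm[n_split:]
    else:
        idx_S = idx_H = sub_idx

    p = data.X.shape[1]
    mtry = config.mtry if config.mtry is not None else math.ceil(math.sqrt(p))
    mtry = min(mtry, p)

    root_S = _HalfStats(data, idx_S)
    root_H = _HalfStats(data, idx_H)
    for half in (root_S, root_H):
        cov, tol = half.cov_wz()
        if abs(cov) <= config.denom_tol_scale * tol or cov == 0:
            return None

    feature: list[int] = []
    threshold: list[int] = []
    left: list[int] = []
    right: list[int] = []
    effect: list[float] = []
    n_honest: list[int] = []
    denom: list[float] = []

    queue: list[tuple[int, _HalfStats, _HalfStats]] = []

    def new_node() -> int:
        feature.append(-1)
        threshold.append(0)
        left.append(-1)
        right.append(-1)
        effect.append(math.nan)
        n_honest.append(0)
        denom.append(math.nan)
        return len(feature) - 1

    root = new_node()
    queue.append((root, root_S, root_H))
    while queue:
        node, S, H = queue.pop(0)
        split = None
        if S.n >= 2 * config.min_leaf_size and H.n >= 2 * config.min_leaf_size:
            feats = np.sort(rng.choice(p, size=mtry, replace=False))
            split = _best_split(data, S, H, feats, config.min_leaf_size,
                                config.denom_tol_scale)
        if split is None:
            tau, cov = H.wald()
            effect[node] = tau
            n_honest[node] = H.n
            denom[node] = cov
            continue
        _, f, t = split
        feature[node] = f
        threshold[node] = t
        mask_S = data.X[S.idx, f] <= t
        mask_H = data.X[H.idx, f] <= t
        l = new_node()
        r = new_node()
        left[node], right[node] = l, r
        queue.append((l, _HalfStats(data, S.idx[mask_S]), _HalfStats(data, H.idx[mask_H])))
        queue.append((r, _HalfStats(data, S.idx[~mask_S]), _HalfStats(data, H.idx[~mask_H])))

    return CausalTree(
        feature=np.array(feature, dtype=np.int64),
        threshold=np.array(threshold, dtype=np.int64),
        left=np.array(left, dtype=np.int64),
        right=np.array(right, dtype=np.int64),
        effect=np.array(effect, dtype=float),
        n_honest=np.array(n_honest, dtype=np.int64),
        denom=np.array(denom, dtype=float),
    )


def _centered(data: _TreeData, df: pd.DataFrame) -> _TreeData:
    """Residualize Y, W, Z on binary-encoded covariates (optional mode)."""
    Xd, _ = schema.encode_design(df)
    D = np.column_stack([np.ones(len(df)), Xd])
    def resid(v):
        beta, *_ = np.linalg.lstsq(D, v, rcond=None)
        return v - D @ beta
    return _TreeData(data.X, resid(data.Y), resid(data.W), resid(data.Z))


def fit_forest(df: pd.DataFrame, outcome: str, config: ForestConfig) -> CausalForestModel:
    """Fit the forest for one outcome on a cohort with the instrument attached.

    Trees are seeded by a counter derived from the master seed, so the model
    is reproducible and invariant to execution order.  A tree whose root
    Wald denominator fails the tolerance is re-drawn (bounded retries).
    """
    config.validate()
    if "instrument" not in df.columns:
        raise ValueError("cohort has no instrument column; run the instrument stage first")
    ycol = outcome if outcome in df.columns else f"y_{outcome}"
    X = schema.covariate_matrix(df)
    data = _TreeData(
        X,
        df[ycol].to_numpy(),
        df["treatment"].to_numpy(),
        df["instrument"].to_numpy(),
    )
    if config.center:
        data = _centered(data, df)
    n = len(df)
    m = max(2, int(round(config.subsample_fraction * n)))
    trees: list[CausalTree] = []
    for t in range(config.num_trees):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, t]))
        tree = None
        for _ in range(config.max_retries):
            sub = rng.choice(n, size=m, replace=False)
            tree = grow_tree(data, sub, config, rng)
            if tree is not None:
                break
        if tree is None:
            raise RuntimeError(
                f"tree {t}: root Wald denominator below tolerance after "
                f"{config.max_retries} subsample draws (weak instrument?)"
            )
        trees.append(tree)
    return CausalForestModel(trees=trees, config=config,
                             feature_names=COVARIATE_NAMES, outcome=outcome)


def predict_effects(model: CausalForestModel, df: pd.DataFrame) -> np.ndarray:
    """Per-patient effect: unweighted mean of leaf effects over all trees."""
    X = schema.covariate_matrix(df)
    total = np.zeros(len(df))
    for tree in model.trees:
        total += tree.predict(X)
    return total / len(model.trees)


def summarize_distribution(estimates: np.ndarray) -> DistributionSummary:
    """Location/spread summary of patient-level estimates.

    Percentiles use linear interpolation; ``pct_positive`` counts strictly
    positive estimates, in percent.
    """
    v = np.asarray(estimates, dtype=float)
    if len(v) == 0:
        raise ValueError("no estimates")
    qs = np.percentile(v, [10, 25, 50, 75, 90])
    return DistributionSummary(
        mean=float(v.mean()),
        sd=float(v.std(ddof=1)) if len(v) > 1 else 0.0,
        pct_positive=float((v > 0).mean() * 100),
        min=float(v.min()),
        p10=float(qs[0]),
        p25=float(qs[1]),
        p50=float(qs[2]),
        p75=float(qs[3]),
        p90=float(qs[4]),
        max=float(v.max()),
    )


def estimate_grid(
    df: pd.DataFrame,
    outcomes: list[str],
    tree_counts: list[int],
    leaf_sizes: list[int],
    base_config: ForestConfig | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit one forest per (outcome, num_trees, min_leaf_size) grid point.

    Returns a long estimate table (patient_id, outcome, num_trees,
    min_leaf_size, tau_hat) and a summary table with one row per grid point.
    """
    base = base_config or ForestConfig()
    est_rows = []
    sum_rows = []
    for oi, outcome in enumerate(outcomes):
        for ti, nt in enumerate(tree_counts):
            for li, ml in enumerate(leaf_sizes):
                cfg = replace(base, num_trees=nt, min_leaf_size=ml,
                              seed=_derive_seed(seed, oi, ti, li))
                model = fit_forest(df, outcome, cfg)
                tau = predict_effects(model, df)
                est_rows.append(pd.DataFrame({
                    "patient_id": df["patient_id"].to_numpy(),
                    "outcome": outcome,
                    "num_trees": nt,
                    "min_leaf_size": ml,
                    "tau_hat": tau,
                }))
                s = summarize_distribution(tau).as_dict()
                s.update(outcome=outcome, num_trees=nt, min_leaf_size=ml)
                sum_rows.append(s)
    est = pd.concat(est_rows, ignore_index=True)
    cols = ["outcome", "num_trees", "min_leaf_size", "mean", "sd", "pct_positive",
            "min", "p10", "p25", "p50", "p75", "p90", "max"]
    summary = pd.DataFrame(sum_rows)[cols]
    return est, summary


def _derive_seed(master: int, *tokens: int) -> int:
    """Stable sub-seed derivation (master seed + index path), < 2^31."""
    ss = np.random.SeedSequence([int(master), *[int(t) for t in tokens]])
    return int(ss.generate_state(1)[0] % (2**31))


def write_forest(model: CausalForestModel, path) -> None:
    """Serialize a forest as one node record per line (structured text)."""
    rows = []
    for ti, tree in enumerate(model.trees):
        for i in range(tree.n_nodes):
            f = int(tree.feature[i])
            rows.append({
                "tree": ti,
                "node": i,
                "split_var": model.feature_names[f] if f >= 0 else "",
                "threshold": int(tree.threshold[i]) if f >= 0 else "",
                "left": int(tree.left[i]),
                "right": int(tree.right[i]),
                "effect": tree.effect[i],
                "n_honest": int(tree.n_honest[i]),
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")
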