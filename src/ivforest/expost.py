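"""Ex-post reference classes: CART on patient-level effect estimates.

The forest yields an effect estimate per patient; a depth-limited regression
tree fit to those estimates on the baseline factors turns them into a small
set of interpretable patient classes defined *after* estimation ("ex-post"),
instead of subgroups specified a priori.  Splits minimize the within-child
sum of squared deviations of the estimates, ordinals split as "level <= c",
and nodes are numbered breadth-first from 1 (root), so the depth-3 classes
carry labels 8-15; a branch that stops early keeps its shallower label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import kendalltau

from . import schema
from .schema import COVARIATE_NAMES

__all__ = [
    "ReferenceClass",
    "ClassPartition",
    "ConsistencyEntry",
    "fit_cart",
    "compare_partitions",
    "tabulate_class_definitions",
    "render_tree",
]


@dataclass(frozen=True)
class ReferenceClass:
    """One leaf of the class tree: an interval predicate per split variable."""

    label: int                       # breadth-first node number (root = 1)
    bounds: tuple[tuple[str, int, int], ...]  # (covariate, lo, hi) inclusive
    mean_effect: float
    n: int

    def predicates(self) -> list[tuple[str, str, int]]:
        """As (covariate, relation, level) conjunctions for class_mask."""
        preds = []
        for name, lo, hi in self.bounds:
            cov = schema.covariate(name)
            if lo == hi:
                preds.append((name, "==", lo))
            else:
                if lo > cov.min_level:
                    preds.append((name, ">", lo - 1))
                if hi < cov.max_level:
                    preds.append((name, "<=", hi))
        return preds

    def describe(self) -> str:
        parts = []
        for name, lo, hi in self.bounds:
            cov = schema.covariate(name)
            if lo == hi:
                parts.append(f"{name} == {lo}")
            elif lo > cov.min_level and hi < cov.max_level:
                parts.append(f"{lo} <= {name} <= {hi}")
            elif lo > cov.min_level:
                parts.append(f"{name} > {lo - 1}")
            else:
                parts.append(f"{name} <= {hi}")
        return " & ".join(parts) if parts else "all patients"


@dataclass
class ClassPartition:
    """Disjoint, exhaustive set of reference classes over one cohort."""

    classes: list[ReferenceClass]
    assignment: np.ndarray          # per patient: class label
    patient_ids: np.ndarray
    max_depth: int
    min_node: int
    nodes: list[dict] = field(default_factory=list, repr=False)

    def class_for(self, label: int) -> ReferenceClass:
        return next(c for c in self.classes if c.label == label)

    def member_mask(self, label: int) -> np.ndarray:
        return self.assignment == label


@dataclass
class ConsistencyEntry:
    exact_matches: int
    membership_agreement: float     # adjusted-Rand-style, in [-1, 1]
    effect_rank_concordance: float  # Kendall tau over matched classes (nan if <2)


def _canonical_bounds(bounds: dict[str, list[int]]) -> tuple[tuple[str, int, int], ...]:
    out = []
    for name in COVARIATE_NAMES:
        if name in bounds:
            lo, hi = bounds[name]
            cov = schema.covariate(name)
            if lo > cov.min_level or hi < cov.max_level:
                out.append((name, lo, hi))
    return tuple(out)


def fit_cart(
    tau_hat: np.ndarray,
    df: pd.DataFrame,
    max_depth: int = 3,
    min_node: int = 1,
) -> ClassPartition:
    """Depth-limited variance-reduction tree on effect estimates.

    Greedy exhaustive search over every (covariate, threshold) pair at each
    node; a split is kept only if it strictly reduces the summed squared
    deviation and both children meet ``min_node``.  Constant estimates yield
    a single-class partition.  Ties break to the lowest covariate index,
    then the lowest threshold.
    """
    tau = np.asarray(tau_hat, dtype=float)
    if not np.all(np.isfinite(tau)):
        raise ValueError("effect estimates must be finite")
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    X = schema.covariate_matrix(df)
    n, p = X.shape
    ml = int(X.max()) + 1

    classes: list[ReferenceClass] = []
    assignment = np.zeros(n, dtype=np.int64)
    nodes: list[dict] = []

    # (node label, row indices, depth, bounds so far)
    init_bounds = {c.name: [c.min_level, c.max_level] for c in schema.COVARIATES}
    stack = [(1, np.arange(n), 0, init_bounds)]
    while stack:
        label, idx, depth, bounds = stack.pop(0)
        t = tau[idx]
        node = {"label": label, "n": len(idx), "mean": float(t.mean()),
                "depth": depth, "split": None}
        nodes.append(node)
        split = None
        if depth < max_depth and len(idx) >= 2 * min_node and t.min() != t.max():
            split = _best_sse_split(X, tau, idx, min_node, ml)
        if split is None:
            classes.append(ReferenceClass(
                label=label,
                bounds=_canonical_bounds(bounds),
                mean_effect=float(t.mean()),
                n=len(idx),
            ))
            assignment[idx] = label
            continue
        f, thr = split
        name = COVARIATE_NAMES[f]
        node["split"] = (name, thr)
        go_left = X[idx, f] <= thr
        bl = {k: list(v) for k, v in bounds.items()}
        br = {k: list(v) for k, v in bounds.items()}
        bl[name][1] = min(bl[name][1], thr)
        br[name][0] = max(br[name][0], thr + 1)
        stack.append((2 * label, idx[go_left], depth + 1, bl))
        stack.append((2 * label + 1, idx[~go_left], depth + 1, br))

    classes.sort(key=lambda c: c.label)
    return ClassPartition(
        classes=classes,
        assignment=assignment,
        patient_ids=df["patient_id"].to_numpy(),
        max_depth=max_depth,
        min_node=min_node,
        nodes=nodes,
    )


def _best_sse_split(X, tau, idx, min_node, ml):
    """Maximize between-child SSE reduction = nL*nR/n * (meanL-meanR)^2."""
    n = len(idx)
    t = tau[idx]
    best = None
    for f in range(X.shape[1]):
        codes = X[idx, f]
        cnt = np.bincount(codes, minlength=ml).astype(float)
        st = np.bincount(codes, weights=t, minlength=ml)
        cl = np.cumsum(cnt)[:-1]
        sl = np.cumsum(st)[:-1]
        cr = n - cl
        sr = t.sum() - sl
        ok = (cl >= min_node) & (cr >= min_node)
        if not ok.any():
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            gain = (cl * cr / n) * (sl / cl - sr / cr) ** 2
        gain = np.where(ok & np.isfinite(gain), gain, -np.inf)
        thr = int(np.argmax(gain))
        if gain[thr] > 0 and (best is None or gain[thr] > best[0]):
            best = (float(gain[thr]), f, thr)
    return None if best is None else (best[1], best[2])


# ---------------------------------------------------------------------------


def _adjusted_rand(a: np.ndarray, b: np.ndarray) -> float:
    """Adjusted Rand index from the pair-count contingency formula."""
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    ka, kb = ai.max() + 1, bi.max() + 1
    ct = np.bincount(ai * kb + bi, minlength=ka * kb).reshape(ka, kb)

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(ct).sum()
    sum_a = comb2(ct.sum(axis=1)).sum()
    sum_b = comb2(ct.sum(axis=0)).sum()
    total = comb2(len(a))
    expected = sum_a * sum_b / total if total > 0 else 0.0
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def compare_partitions(a: ClassPartition, b: ClassPartition) -> ConsistencyEntry:
    """Agreement between two class partitions of the same cohort.

    Exact matches compare canonicalized predicate interval lists; membership
    agreement is an adjusted Rand index over all patient pairs; rank
    concordance is the Kendall tau of mean-effect orderings restricted to
    exact-definition matches (nan when fewer than two match).
    """
    if len(a.patient_ids) != len(b.patient_ids) or not np.array_equal(
        a.patient_ids, b.patient_ids
    ):
        raise ValueError("partitions cover different cohorts")
    defs_a = {c.bounds: c for c in a.classes}
    defs_b = {c.bounds: c for c in b.classes}
    matched = sorted(set(defs_a) & set(defs_b))
    if len(matched) >= 2:
        ra = [defs_a[m].mean_effect for m in matched]
        rb = [defs_b[m].mean_effect for m in matched]
        conc = float(kendalltau(ra, rb).statistic)
    else:
        conc = float("nan")
    return ConsistencyEntry(
        exact_matches=len(matched),
        membership_agreement=_adjusted_rand(a.assignment, b.assignment),
        effect_rank_concordance=conc,
    )


def tabulate_class_definitions(
    partitions: dict[int, ClassPartition],
    ascending: bool = False,
) -> pd.DataFrame:
    """Class-definition table across minimum leaf sizes.

    One row per minimum leaf size, classes as columns ordered by mean effect
    (descending for a benefit outcome, ascending for a detriment outcome),
    cells holding human-readable predicate strings.
    """
    if len(partitions) < 2:
        raise ValueError("need at least 2 partitions to tabulate")
    rows = {}
    width = max(len(p.classes) for p in partitions.values())
    for ml in sorted(partitions):
        cls = sorted(
            partitions[ml].classes,
            key=lambda c: c.mean_effect,
            reverse=not ascending,
        )
        row = [c.describe() for c in cls] + [""] * (width - len(cls))
        rows[ml] = row
    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"class_{i+1}" for i in range(width)]
    )
    out.index.name = "min_leaf_size"
    return out


def render_tree(partition: ClassPartition) -> str:
    """Plain-text rendering: node number, n, mean effect, split label."""
    lines = []
    for node in partition.nodes:
        indent = "  " * node["depth"]
        split = node["split"]
        tag = f" | split: {split[0]} <= {split[1]}" if split else " [class]"
        lines.append(
            f"{indent}node {node['label']}: n={node['n']} "
            f"mean_effect={node['mean']:+.4f}{tag}"
        )
    return "\n".join(lines)
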