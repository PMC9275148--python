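"""Within-class two-stage least squares (2SLS) scrutiny of reference classes.

For each ex-post reference class the first stage regresses treatment on the
instrument plus binary-encoded free baseline factors; the second stage
regresses the outcome on fitted treatment plus the same controls.  The
coefficient on fitted treatment (IVE) estimates the local average treatment
effect (LATE) for the class members whose treatment choice is moved by the
instrument.  Standard errors use the conventional 2SLS covariance with
residuals formed against *original* treatment; the first-stage F statistic
is the squared t-ratio of the single instrument, with F > 10 the usual
"non-weak" convention.  The benefit x detriment cross-tabulation colors each
cell from the two class-level fits: green (significant benefit only), red
(significant detriment only), yellow (both), orange (neither).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import schema
from .expost import ClassPartition

__all__ = [
    "TSLSFit",
    "IdentificationError",
    "fit_2sls",
    "class_descriptives",
    "fit_class_table",
    "build_crosstab",
    "nonweak_instrument",
    "significance_stars",
]


class IdentificationError(RuntimeError):
    pass


@dataclass
class TSLSFit:
    ive: float                 # 2SLS absolute effect of treatment on outcome
    se: float
    p_value: float
    first_stage_F: float
    n: int
    treat_rate: float
    rate_q1: float = math.nan  # treatment rate in cohort instrument quintile 1
    rate_q5: float = math.nan  # ... and quintile 5 (nan = class empty there)
    df_resid: int = 0

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)

    def positive_significant(self, alpha: float = 0.05) -> bool:
        return self.ive > 0 and self.p_value < alpha


def significance_stars(p: float) -> str:
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.1:
        return "*"
    return ""


def nonweak_instrument(fit: TSLSFit) -> bool:
    """True iff the first-stage F statistic exceeds the conventional 10."""
    return fit.first_stage_F > 10


def _prune_collinear(M: np.ndarray, tol: float = 1e-8) -> list[int]:
    """Indices of columns to keep: deterministic left-to-right scan."""
    keep: list[int] = []
    basis = np.empty((M.shape[0], 0))
    for j in range(M.shape[1]):
        v = M[:, j]
        norm = np.linalg.norm(v)
        if norm == 0:
            continue
        if basis.shape[1]:
            coef, *_ = np.linalg.lstsq(basis, v, rcond=None)
            resid = v - basis @ coef
        else:
            resid = v
        if np.linalg.norm(resid) > tol * max(norm, 1.0):
            keep.append(j)
            q = resid / np.linalg.norm(resid)
            basis = np.column_stack([basis, q])
    return keep


def fit_2sls(
    outcome: np.ndarray,
    treatment: np.ndarray,
    instrument: np.ndarray,
    controls: np.ndarray | None = None,
    robust: bool = False,
    clusters: np.ndarray | None = None,
) -> TSLSFit:
    """2SLS with a single instrument and a linear-probability second stage.

    With no controls this reduces algebraically to the Wald estimator.
    Collinear control columns are dropped by a deterministic left-to-right
    scan.  ``robust`` switches to heteroskedasticity-robust (HC0) standard
    errors; ``clusters`` additionally aggregates scores within clusters.
    """
    Y = np.asarray(outcome, dtype=float)
    W = np.asarray(treatment, dtype=float)
    Z = np.asarray(instrument, dtype=float)
    n = len(Y)
    if n == 0:
        raise IdentificationError("empty class")
    if np.ptp(Z) == 0:
        raise IdentificationError("no identifying variation: instrument constant within class")

    C = np.column_stack([np.ones(n)] + ([controls] if controls is not None and controls.size else []))
    keep = _prune_collinear(C)
    C = C[:, keep]
    k = C.shape[1] + 1  # + treatment column
    if n <= k:
        raise IdentificationError(f"class too small: n={n} <= {k} model columns")

    # first stage: W on [Z, C]
    ZC = np.column_stack([Z, C])
    g, *_ = np.linalg.lstsq(ZC, W, rcond=None)
    w_hat = ZC @ g
    u = W - w_hat
    df1 = n - ZC.shape[1]
    s2_1 = (u @ u) / df1
    XtX1_inv = np.linalg.pinv(ZC.T @ ZC)
    se_g = math.sqrt(s2_1 * XtX1_inv[0, 0])
    F = (g[0] / se_g) ** 2 if se_g > 0 else math.inf

    # second stage: Y on [W_hat, C]; residuals against original W
    Xhat = np.column_stack([w_hat, C])
    beta, *_ = np.linalg.lstsq(Xhat, Y, rcond=None)
    X = np.column_stack([W, C])
    e = Y - X @ beta
    df2 = n - Xhat.shape[1]
    XtX_inv = np.linalg.pinv(Xhat.T @ Xhat)
    if clusters is not None:
        Xe = Xhat * e[:, None]
        _, inv = np.unique(np.asarray(clusters), return_inverse=True)
        G = np.zeros((inv.max() + 1, Xhat.shape[1]))
        np.add.at(G, inv, Xe)
        meat = G.T @ G
        cov = XtX_inv @ meat @ XtX_inv
    elif robust:
        meat = (Xhat * (e ** 2)[:, None]).T @ Xhat
        cov = XtX_inv @ meat @ XtX_inv
    else:
        cov = ((e @ e) / df2) * XtX_inv
    se = math.sqrt(max(cov[0, 0], 0.0))
    tstat = beta[0] / se if se > 0 else math.inf
    p = 2 * stats.t.sf(abs(tstat), df2)
    return TSLSFit(
        ive=float(beta[0]),
        se=float(se),
        p_value=float(p),
        first_stage_F=float(F),
        n=n,
        treat_rate=float(W.mean()),
        df_resid=df2,
    )


def class_descriptives(
    treatment: np.ndarray, quintiles: np.ndarray
) -> tuple[float, float, float, int]:
    """(treat_rate, rate_q1, rate_q5, n) for one class.

    Quintiles must be the cohort-wide instrument quintile labels, re-used
    inside the class, not re-cut.  A class with no members in a tail
    quintile reports nan for that rate.
    """
    W = np.asarray(treatment, dtype=float)
    q = np.asarray(quintiles)
    n = len(W)
    r1 = float(W[q == 1].mean()) if (q == 1).any() else math.nan
    r5 = float(W[q == 5].mean()) if (q == 5).any() else math.nan
    return float(W.mean()), r1, r5, n


def _free_controls(df_class: pd.DataFrame) -> np.ndarray:
    """Binary-encoded baseline factors free to vary within the class.

    Levels pinned by the class predicates encode as constant columns and are
    dropped, which is exactly the exclusion the predicates imply.
    """
    X, _ = schema.encode_design(df_class)
    return X


def fit_class_table(
    df: pd.DataFrame,
    partition: ClassPartition,
    outcome: str,
    alpha: float = 0.05,
    robust: bool = False,
    cluster_by_area: bool = False,
    area_controls: list[str] | None = None,
) -> pd.DataFrame:
    """Per-class 2SLS fits plus descriptives for one outcome.

    ``area_controls`` names optional area-level columns passed through to
    both stages.
    """
    ycol = outcome if outcome in df.columns else f"y_{outcome}"
    rows = []
    for cls in partition.classes:
        mask = partition.member_mask(cls.label)
        sub = df.loc[mask]
        controls = _free_controls(sub)
        if area_controls:
            controls = np.column_stack([controls, sub[area_controls].to_numpy(float)])
        fit = fit_2sls(
            sub[ycol].to_numpy(),
            sub["treatment"].to_numpy(),
            sub["instrument"].to_numpy(),
            controls=controls,
            robust=robust,
            clusters=sub["area_id"].to_numpy() if cluster_by_area else None,
        )
        rate, r1, r5, n = class_descriptives(
            sub["treatment"].to_numpy(), sub["instrument_q"].to_numpy()
        )
        rows.append({
            "class_label": cls.label,
            "definition": cls.describe(),
            "n": n,
            "treat_rate": rate,
            "rate_q1": r1,
            "rate_q5": r5,
            "first_stage_F": fit.first_stage_F,
            "nonweak": nonweak_instrument(fit),
            "ive": fit.ive,
            "se": fit.se,
            "p_value": fit.p_value,
            "stars": fit.stars,
            "positive_significant": fit.positive_significant(alpha),
            "forest_mean_effect": cls.mean_effect,
        })
    return pd.DataFrame(rows)


def _cell_color(benefit_pos_sig: bool, detriment_pos_sig: bool) -> str:
    if benefit_pos_sig and not detriment_pos_sig:
        return "green"
    if not benefit_pos_sig and detriment_pos_sig:
        return "red"
    if benefit_pos_sig and detriment_pos_sig:
        return "yellow"
    return "orange"


@dataclass
class CrossTab:
    cells: pd.DataFrame            # one row per benefit x detriment cell
    benefit_fits: pd.DataFrame     # rows, sorted by ive descending
    detriment_fits: pd.DataFrame   # columns, sorted by ive ascending
    population_benefit: TSLSFit    # corner cell: whole-population fits
    population_detriment: TSLSFit

    def layout(self) -> pd.DataFrame:
        """Cell colors arranged rows x columns as in the report table."""
        return self.cells.pivot(
            index="benefit_class", columns="detriment_class", values="color"
        )


def build_crosstab(
    df: pd.DataFrame,
    benefit_partition: ClassPartition,
    detriment_partition: ClassPartition,
    alpha: float = 0.05,
    robust: bool = False,
    cluster_by_area: bool = False,
    area_controls: list[str] | None = None,
) -> CrossTab:
    """Benefit x detriment class cross-tabulation with significance colors.

    Rows (benefit classes) are ordered by estimated effect descending,
    columns (detriment classes) ascending; each cell carries the patient
    count, treatment rate and tail-quintile rates of the intersection, plus
    a color derived from the two class fits at level ``alpha``.  The
    whole-population 2SLS fits for both outcomes occupy the corner.
    """
    kw = dict(alpha=alpha, robust=robust, cluster_by_area=cluster_by_area,
              area_controls=area_controls)
    bfits = fit_class_table(df, benefit_partition, "benefit", **kw)
    dfits = fit_class_table(df, detriment_partition, "detriment", **kw)
    bfits = bfits.sort_values("ive", ascending=False, kind="stable").reset_index(drop=True)
    dfits = dfits.sort_values("ive", ascending=True, kind="stable").reset_index(drop=True)

    bsig = dict(zip(bfits["class_label"], bfits["positive_significant"]))
    dsig = dict(zip(dfits["class_label"], dfits["positive_significant"]))

    W = df["treatment"].to_numpy()
    q = df["instrument_q"].to_numpy()
    rows = []
    for bl in bfits["class_label"]:
        bm = benefit_partition.member_mask(bl)
        for dl in dfits["class_label"]:
            mask = bm & detriment_partition.member_mask(dl)
            n = int(mask.sum())
            if n:
                rate, r1, r5, _ = class_descriptives(W[mask], q[mask])
            else:
                rate = r1 = r5 = math.nan
            rows.append({
                "benefit_class": bl,
                "detriment_class": dl,
                "n": n,
                "treat_rate": rate,
                "rate_q1": r1,
                "rate_q5": r5,
                "color": _cell_color(bool(bsig[bl]), bool(dsig[dl])),
            })
    cells = pd.DataFrame(rows)

    controls = _free_controls(df)
    if area_controls:
        controls = np.column_stack([controls, df[area_controls].to_numpy(float)])
    pop = {}
    for label in ("benefit", "detriment"):
        ycol = f"y_{label}"
        pop[label] = fit_2sls(
            df[ycol].to_numpy(), W, df["instrument"].to_numpy(),
            controls=controls, robust=robust,
            clusters=df["area_id"].to_numpy() if cluster_by_area else None,
        )
    return CrossTab(
        cells=cells,
        benefit_fits=bfits,
        detriment_fits=dfits,
        population_benefit=pop["benefit"],
        population_detriment=pop["detriment"],
    )
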