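"""Risk-adjusted area surgery ratio (ASR) instrument.

The instrument exploits local-area "practice signatures": the ratio, per
area, of the observed number of treated patients to the sum of
model-predicted treatment probabilities for the patients living there.  A
ratio above one marks an area that treats more aggressively than its patient
mix predicts.  Each patient inherits their resident area's ratio as an
instrumental variable, then patients are grouped into patient-count
quintiles of the instrument.

Because the choice model includes an intercept, the maximum-likelihood score
equation forces fitted probabilities to sum to the treated count, so the
predicted-sum-weighted mean ASR is exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import schema

__all__ = [
    "ChoiceModelError",
    "AreaInstrument",
    "fit_choice_model",
    "compute_asr",
    "assign_quintiles",
    "attach_instrument",
]


class ChoiceModelError(RuntimeError):
    pass


def _separating_columns(W: np.ndarray, X: np.ndarray, names: list[str]) -> list[str]:
    """Binary-encoded columns that perfectly predict treatment on one side."""
    out = []
    for j, name in enumerate(names):
        col = X[:, j]
        if set(np.unique(col)) <= {0.0, 1.0}:
            for side in (col == 1, col == 0):
                if side.any() and side.sum() < len(W):
                    w = W[side]
                    if w.min() == w.max():
                        out.append(name)
                        break
    return out


def fit_choice_model(df: pd.DataFrame) -> np.ndarray:
    """ML logistic fit of treatment on binary-encoded baseline factors.

    Returns fitted probabilities in (0,1).  With the intercept present the
    fitted probabilities sum to the number of treated patients.  Complete
    separation (a column pure on both sides) raises
    :class:`ChoiceModelError` naming the offending covariate column(s).
    A sparse indicator level that merely quasi-separates (treatment constant
    among the handful of patients at that level) has no finite ML
    coefficient; such columns are collapsed into the reference level, the
    standard sparse-cell remedy.
    """
    if len(df) == 0:
        raise ValueError("empty cohort")
    W = df["treatment"].to_numpy(dtype=float)
    if W.min() == W.max():
        raise ChoiceModelError("treatment is constant: choice model undefined")
    X, names = schema.encode_design(df)

    complete, quasi = [], []
    for j, name in enumerate(names):
        col = X[:, j]
        on, off = col == 1, col == 0
        pure_on = on.any() and W[on].min() == W[on].max()
        pure_off = off.any() and W[off].min() == W[off].max()
        if pure_on and pure_off and W[on].mean() != W[off].mean():
            complete.append(name)
        elif pure_on:
            quasi.append(j)
    if complete:
        raise ChoiceModelError(
            f"perfect separation in choice model (separating covariate: {', '.join(complete)})"
        )
    if quasi:
        keep = [j for j in range(X.shape[1]) if j not in set(quasi)]
        X = X[:, keep]
        names = [names[j] for j in keep]
    design = sm.add_constant(X, has_constant="add")
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(W, design).fit(disp=0, maxiter=200)
        params = res.params
        converged = bool(res.mle_retvals.get("converged", True))
    except Exception as exc:  # statsmodels raises on hard separation
        sep = _separating_columns(W, X, names)
        raise ChoiceModelError(
            "perfect separation in choice model"
            + (f" (separating covariate: {', '.join(sep)})" if sep else "")
        ) from exc
    if not converged or not np.all(np.isfinite(params)):
        sep = _separating_columns(W, X, names)
        if sep:
            raise ChoiceModelError(
                f"perfect separation in choice model (separating covariate: {', '.join(sep)})"
            )
        raise ChoiceModelError("choice model failed to converge")
    p = res.predict(design)
    return np.clip(p, 1e-12, 1 - 1e-12)


@dataclass
class AreaInstrument:
    """Per-area instrument table plus patient-level assignment."""

    area_table: pd.DataFrame      # area_id, n, observed, predicted_sum, asr
    instrument: np.ndarray        # per patient: resident area's ASR
    quintile: np.ndarray          # per patient: 1..5

    @property
    def weighted_mean_asr(self) -> float:
        t = self.area_table
        return float((t["asr"] * t["predicted_sum"]).sum() / t["predicted_sum"].sum())


def assign_quintiles(values: np.ndarray) -> np.ndarray:
    """Patient-count quintiles 1..5 with ties assigned to the lower quintile.

    All patients sharing a value receive the quintile implied by the count of
    patients with strictly smaller values, so a tie block never straddles a
    cut.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if len(np.unique(values)) < 5:
        raise ValueError("need at least 5 distinct instrument values for quintiles")
    sorted_vals = np.sort(values)
    below = np.searchsorted(sorted_vals, values, side="left")
    return np.minimum(below * 5 // n, 4).astype(np.int64) + 1


def compute_asr(
    df: pd.DataFrame, probabilities: np.ndarray, quintiles: bool = True
) -> AreaInstrument:
    """Area surgery ratios and patient-level instrument assignment.

    ASR(area) = observed treated count / sum of predicted probabilities over
    the area's patients.  Quintiles are cut over patients, not areas;
    ``quintiles=False`` skips them (toy inputs with <5 distinct values).
    """
    p = np.asarray(probabilities, dtype=float)
    if len(p) != len(df):
        raise ValueError("probabilities not aligned with cohort rows")
    area = df["area_id"].to_numpy()
    W = df["treatment"].to_numpy(dtype=float)
    areas, inv = np.unique(area, return_inverse=True)
    n_a = np.bincount(inv)
    obs = np.bincount(inv, weights=W)
    pred = np.bincount(inv, weights=p)
    if np.any(pred <= 0):
        bad = areas[pred <= 0][0]
        raise ValueError(f"area {bad} has non-positive predicted sum")
    asr = obs / pred
    table = pd.DataFrame(
        {"area_id": areas, "n": n_a, "observed": obs.astype(int),
         "predicted_sum": pred, "asr": asr}
    )
    instrument = asr[inv]
    quintile = (
        assign_quintiles(instrument)
        if quintiles
        else np.zeros(len(instrument), dtype=np.int64)
    )
    return AreaInstrument(area_table=table, instrument=instrument, quintile=quintile)


def attach_instrument(df: pd.DataFrame, leave_area_out: bool = False) -> tuple[pd.DataFrame, AreaInstrument]:
    """Fit the choice model, build the ASR, and append instrument columns.

    ``leave_area_out`` refits the choice model excluding each area before
    predicting that area's patients, guarding against own-area contamination;
    the default keeps the single full-cohort fit.
    """
    base = df[[c for c in df.columns if not c.startswith(schema.TRUTH_PREFIX)]]
    if leave_area_out:
        X, _ = schema.encode_design(base, drop_constant=False)
        design_all = sm.add_constant(X, has_constant="add")
        p = np.empty(len(df))
        for area in base["area_id"].unique():
            mask = (base["area_id"] == area).to_numpy()
            rest = base.loc[~mask]
            Xr, _ = schema.encode_design(rest, drop_constant=False)
            design_r = sm.add_constant(Xr, has_constant="add")
            res = sm.Logit(rest["treatment"].to_numpy(dtype=float), design_r).fit(disp=0)
            p[mask] = res.predict(design_all[mask])
    else:
        p = fit_choice_model(base)
    inst = compute_asr(base, p)
    out = df.copy()
    out["instrument"] = inst.instrument
    out["instrument_q"] = inst.quintile
    return out, inst
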