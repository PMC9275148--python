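"""Cohort covariate schema and encoding rules.

The patient-level table carries a fixed set of ordinal and binary baseline
factors typical of elderly orthopaedic claims cohorts: an ordinal age group
(five levels: 66-69, 70-75, 76-79, 80-85, 86+), the Charlson Comorbidity
Index (CCI), a Frailty Risk Index (FRI), quintiles of prior-year healthcare
spending, and binary demographic / diagnosis flags.  Ordinal factors are
split as "level <= c" by the tree learners and expanded to one indicator per
level (first level dropped) for regression stages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Covariate",
    "COVARIATES",
    "COVARIATE_NAMES",
    "TRUTH_PREFIX",
    "encode_design",
    "validate_cohort",
]

TRUTH_PREFIX = "truth_"


@dataclass(frozen=True)
class Covariate:
    """A baseline factor: its name, kind and closed set of integer levels."""

    name: str
    kind: str  # "ordinal" or "binary"
    levels: tuple[int, ...]

    @property
    def min_level(self) -> int:
        return self.levels[0]

    @property
    def max_level(self) -> int:
        return self.levels[-1]


COVARIATES: tuple[Covariate, ...] = (
    Covariate("age_group", "ordinal", tuple(range(1, 6))),
    Covariate("sex", "binary", (0, 1)),
    Covariate("race_white", "binary", (0, 1)),
    Covariate("dual_eligible", "binary", (0, 1)),
    Covariate("dx_oa", "binary", (0, 1)),
    Covariate("dx_ra", "binary", (0, 1)),
    Covariate("dx_cuff", "binary", (0, 1)),
    Covariate("dx_avn", "binary", (0, 1)),
    Covariate("cci", "ordinal", tuple(range(0, 13))),
    Covariate("fri", "ordinal", tuple(range(0, 11))),
    Covariate("prior_cost_quintile", "ordinal", tuple(range(1, 6))),
)

COVARIATE_NAMES: tuple[str, ...] = tuple(c.name for c in COVARIATES)

_BY_NAME = {c.name: c for c in COVARIATES}


def covariate(name: str) -> Covariate:
    return _BY_NAME[name]


def covariate_matrix(df: pd.DataFrame) -> np.ndarray:
    """Baseline factors as an (n, p) integer matrix in schema order."""
    return df[list(COVARIATE_NAMES)].to_numpy(dtype=np.int64)


def encode_design(
    df: pd.DataFrame,
    columns: tuple[str, ...] = COVARIATE_NAMES,
    drop_constant: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Binary-encode baseline factors for regression stages.

    Each ordinal factor contributes one indicator per level above its lowest
    observed-schema level; binary factors enter as-is.  Columns constant in
    ``df`` are dropped (they carry no within-sample information), keeping the
    left-to-right column order deterministic.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    for name in columns:
        cov = _BY_NAME[name]
        x = df[name].to_numpy()
        if cov.kind == "binary":
            cols.append(x.astype(float))
            names.append(name)
        else:
            for lev in cov.levels[1:]:
                cols.append((x == lev).astype(float))
                names.append(f"{name}=={lev}")
    if not cols:
        return np.empty((len(df), 0)), []
    X = np.column_stack(cols)
    if drop_constant:
        keep = [j for j in range(X.shape[1]) if X[:, j].min() != X[:, j].max()]
        X = X[:, keep]
        names = [names[j] for j in keep]
    return X, names


def validate_cohort(df: pd.DataFrame, require_outcomes: bool = True) -> list[str]:
    """Schema-check a cohort table, returning an exhaustive error list.

    Checks: required columns, binary coding of treatment and outcomes,
    declared levels for every baseline factor, no missing values, and a
    minimum of two patients per area.
    """
    errors: list[str] = []
    required = ["patient_id", "area_id", "treatment"]
    if require_outcomes:
        required += ["y_benefit", "y_detriment"]
    required += list(COVARIATE_NAMES)
    for col in required:
        if col not in df.columns:
            errors.append(f"missing column: {col}")
    if errors:
        return errors

    if df["patient_id"].duplicated().any():
        errors.append("duplicate patient_id values")
    for col in required:
        if df[col].isna().any():
            row = int(df.index[df[col].isna()][0])
            errors.append(f"missing value in column {col} (first at row {row})")

    binary_cols = ["treatment"] + (["y_benefit", "y_detriment"] if require_outcomes else [])
    for col in binary_cols:
        bad = ~df[col].isin([0, 1])
        if bad.any():
            row = int(df.index[bad][0])
            errors.append(f"column {col} not 0/1 (first offending row {row})")

    for cov in COVARIATES:
        bad = ~df[cov.name].isin(cov.levels)
        if bad.any():
            row = int(df.index[bad][0])
            errors.append(
                f"column {cov.name} outside declared levels "
                f"{cov.min_level}..{cov.max_level} (first offending row {row})"
            )

    sizes = df.groupby("area_id").size()
    small = sizes[sizes < 2]
    for area in small.index.tolist():
        errors.append(f"area {area} has fewer than 2 patients")
    return errors
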