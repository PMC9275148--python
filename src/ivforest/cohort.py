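"""Synthetic observational cohorts with planted treatment-effect heterogeneity.

The generator emulates the statistical structure that area-instrument studies
of elective surgery rely on:

* local areas with heterogeneous latent practice styles, so that the area a
  patient lives in shifts their probability of treatment for reasons
  unrelated to their own unmeasured severity (the instrument's source of
  identifying variation);
* a latent "fracture complexity" factor that is invisible to every
  estimation stage but may load on treatment choice, on baseline outcome
  probabilities (classic confounding), and on the treatment effect itself
  (essential heterogeneity / sorting on the gain);
* piecewise-constant treatment effects over cells of (CCI band, age band,
  prior-cost band), so the ex-post class-discovery stage has a recoverable
  target.

Treatment is generated by a latent-index threshold (probit-style) rule.
Holding each patient's idiosyncratic noise draw fixed while moving the area
practice style between its 10th and 90th population percentiles gives an
exact, non-randomized complier flag: the patient is a complier iff treatment
switches on under the high-style counterfactual.  All latent quantities are
exported with a ``truth_`` column prefix and stripped automatically by the
estimation stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from . import schema
from .schema import COVARIATE_NAMES, TRUTH_PREFIX

__all__ = [
    "SimulationConfig",
    "simulate_cohort",
    "true_class_late",
    "class_mask",
    "cell_labels",
    "write_cohort",
    "read_cohort",
]

# Probability-cell keys: three band digits, in order
#   (cci above band cut)(age above band cut)(cost above band cut),
# e.g. "010" = CCI in low band, age in high band, prior cost in low band.
CELL_KEYS = tuple(f"{a}{b}{c}" for a in "01" for b in "01" for c in "01")


def _cell_map(base: float, d_cci: float, d_age: float, d_cost: float) -> dict[str, float]:
    return {
        k: round(base + d_cci * int(k[0]) + d_age * int(k[1]) + d_cost * int(k[2]), 10)
        for k in CELL_KEYS
    }


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic cohort.

    Defaults describe a cohort of 20,000 elderly fracture patients across
    100 areas with a strong practice-style instrument, mild confounding in
    outcome levels through latent complexity, and modest sorting on the gain.
    """

    n_patients: int = 20_000
    n_areas: int = 100
    seed: int = 0

    # --- area practice style (instrument source) ---
    area_style_sd: float = 0.5

    # --- treatment choice model: latent index + threshold at 0 ---
    treat_intercept: float = -0.55
    area_style_loading: float = 1.2  # must be >= 0 (one-sided monotonicity)
    complexity_loading: float = 0.5
    treat_noise_sd: float = 1.0
    covariate_loadings: dict[str, float] = field(
        default_factory=lambda: {
            "age_group": -0.05,
            "sex": 0.10,
            "race_white": 0.05,
            "dual_eligible": -0.10,
            "dx_oa": 0.05,
            "dx_ra": 0.05,
            "dx_cuff": 0.15,
            "dx_avn": 0.10,
            "cci": -0.05,
            "fri": -0.04,
            "prior_cost_quintile": 0.04,
        }
    )

    # --- effect-cell bands over (cci, age_group, prior_cost_quintile) ---
    cci_band_max: int = 0    # low band: cci <= 0
    age_band_max: int = 3    # low band: age_group <= 3 (i.e. under 80)
    cost_band_max: int = 3   # low band: quintile <= 3 (not top two)

    # --- baseline outcome probabilities per cell ---
    baseline_benefit: dict[str, float] = field(
        default_factory=lambda: _cell_map(0.40, -0.10, -0.10, -0.05)
    )
    baseline_detriment: dict[str, float] = field(
        default_factory=lambda: _cell_map(0.10, 0.12, 0.08, 0.04)
    )

    # --- planted additive treatment effects per cell ---
    # Cell-level effects span roughly -0.3 .. +0.6, the magnitude of
    # class-level effect spreads reported in area-instrument surgery studies:
    # healthier (CCI 0), younger, high-utilization patients gain most from
    # higher treatment rates; older, sicker patients gain least / are harmed.
    tau_benefit: dict[str, float] = field(
        default_factory=lambda: _cell_map(0.40, -0.35, -0.25, 0.20)
    )
    tau_detriment: dict[str, float] = field(
        default_factory=lambda: _cell_map(0.05, 0.30, 0.20, -0.15)
    )

    # --- latent complexity loadings on outcome levels (confounding) ---
    complexity_baseline_benefit: float = -0.12
    complexity_baseline_detriment: float = 0.12

    # --- complexity x effect interaction (0 disables sorting on the gain) ---
    complexity_effect_interaction: float = 0.05

    # --- complier definition: area-style shift between these percentiles ---
    complier_percentiles: tuple[float, float] = (10.0, 90.0)

    def validate(self) -> None:
        if self.n_patients < 2 * self.n_areas:
            raise ValueError("need at least 2 patients per area: raise n_patients")
        if self.area_style_loading < 0:
            raise ValueError("area_style_loading must be >= 0 (monotone instrument)")
        if self.area_style_sd < 0 or self.treat_noise_sd <= 0:
            raise ValueError("area_style_sd must be >= 0 and treat_noise_sd > 0")
        for label, base_map, tau_map in (
            ("benefit", self.baseline_benefit, self.tau_benefit),
            ("detriment", self.baseline_detriment, self.tau_detriment),
        ):
            for key in CELL_KEYS:
                if key not in base_map or key not in tau_map:
                    raise ValueError(f"{label} maps missing cell '{key}'")
                p0 = base_map[key]
                p1 = p0 + tau_map[key]
                if not (0.0 <= p0 <= 1.0):
                    raise ValueError(
                        f"{label} baseline probability {p0} outside [0,1] in cell '{key}'"
                    )
                if not (0.0 <= p1 <= 1.0):
                    raise ValueError(
                        f"{label} treated probability {p1} outside [0,1] in cell '{key}'"
                    )

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["complier_percentiles"] = list(self.complier_percentiles)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "complier_percentiles" in d:
            d["complier_percentiles"] = tuple(d["complier_percentiles"])
        return cls(**d)


# ---------------------------------------------------------------------------
# covariate generation internals

# Marginal pmfs chosen to resemble an elderly fracture cohort: most patients
# female, CCI/FRI right-skewed with a large mass at zero.
_AGE_PROBS = np.array([0.22, 0.27, 0.20, 0.19, 0.12])
_BINARY_PROBS = {
    "sex": 0.72,
    "race_white": 0.92,
    "dual_eligible": 0.15,
    "dx_oa": 0.25,
    "dx_ra": 0.05,
    "dx_cuff": 0.10,
    "dx_avn": 0.02,
}
_LATENT_CORR = 0.3  # rank correlation driver among cci, fri, prior cost


def _skewed_pmf(p0: float, decay: float, n_levels: int) -> np.ndarray:
    w = np.concatenate([[p0], (1 - p0) * (1 - decay) * decay ** np.arange(n_levels - 1)])
    return w / w.sum()


_CCI_PMF = _skewed_pmf(0.40, 0.62, 13)
_FRI_PMF = _skewed_pmf(0.30, 0.60, 11)


def _quantile_map(u: np.ndarray, pmf: np.ndarray, offset: int) -> np.ndarray:
    cdf = np.cumsum(pmf)
    return offset + np.searchsorted(cdf, u, side="left").astype(np.int64)


def _rank_quintile(score: np.ndarray) -> np.ndarray:
    """Equally-populated quintiles of a continuous score (ties to lower)."""
    order = np.argsort(score, kind="stable")
    n = len(score)
    q = np.empty(n, dtype=np.int64)
    q[order] = np.minimum(np.arange(n) * 5 // n, 4) + 1
    return q


def _cell_key(cfg: SimulationConfig, cci, age, cost) -> np.ndarray:
    """Integer cell index 0..7 with bit order (cci, age, cost)."""
    return (
        (cci > cfg.cci_band_max).astype(np.int64) * 4
        + (age > cfg.age_band_max).astype(np.int64) * 2
        + (cost > cfg.cost_band_max).astype(np.int64)
    )


def cell_labels(cfg: SimulationConfig, df: pd.DataFrame) -> np.ndarray:
    """Cell key strings ('000'..'111') for each patient row."""
    idx = _cell_key(
        cfg,
        df["cci"].to_numpy(),
        df["age_group"].to_numpy(),
        df["prior_cost_quintile"].to_numpy(),
    )
    return np.array(CELL_KEYS)[idx]


def _map_to_array(m: dict[str, float]) -> np.ndarray:
    return np.array([m[k] for k in CELL_KEYS])


# ---------------------------------------------------------------------------


def simulate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Draw a synthetic cohort with full ground truth.

    Returns a patient-level table with id, area id, baseline factors,
    treatment, the two binary outcomes, and ``truth_``-prefixed latent
    columns (complexity, area style, individual effects, potential-outcome
    draws, complier flag).  Deterministic given the config seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, n_areas = config.n_patients, config.n_areas

    # Areas: style ~ N(0, sd); every area seeded with 2 patients, the
    # remainder assigned uniformly at random.
    style = rng.normal(0.0, config.area_style_sd, n_areas)
    area_id = np.concatenate(
        [np.repeat(np.arange(n_areas), 2), rng.integers(0, n_areas, n - 2 * n_areas)]
    )
    area_id = rng.permutation(area_id)

    # Correlated latents for cci / fri / prior cost (mild positive rank
    # correlation), age group and binary flags independent.
    L = np.full((3, 3), _LATENT_CORR) + (1 - _LATENT_CORR) * np.eye(3)
    h = rng.multivariate_normal(np.zeros(3), L, size=n)
    u = norm.cdf(h)
    cci = _quantile_map(u[:, 0], _CCI_PMF, 0)
    fri = _quantile_map(u[:, 1], _FRI_PMF, 0)
    cost_q = _rank_quintile(h[:, 2])
    age = 1 + _quantile_map(rng.uniform(size=n), _AGE_PROBS, 0)

    cov = {
        "age_group": age,
        "cci": cci,
        "fri": fri,
        "prior_cost_quintile": cost_q,
    }
    for name, p in _BINARY_PROBS.items():
        cov[name] = (rng.uniform(size=n) < p).astype(np.int64)

    complexity = rng.normal(0.0, 1.0, n)

    # Treatment: latent index crosses zero.
    lin = np.zeros(n)
    for name, coef in config.covariate_loadings.items():
        lin += coef * cov[name]
    style_i = style[area_id]
    noise = rng.normal(0.0, config.treat_noise_sd, n)
    base_index = (
        config.treat_intercept
        + lin
        + config.complexity_loading * complexity
        + noise
    )
    treatment = (base_index + config.area_style_loading * style_i > 0).astype(np.int64)

    # Complier flag: re-threshold the same index with area style pinned at
    # its 10th / 90th patient-level percentiles (same noise draw).
    lo_p, hi_p = config.complier_percentiles
    s_lo, s_hi = np.percentile(style_i, [lo_p, hi_p])
    w_lo = base_index + config.area_style_loading * s_lo > 0
    w_hi = base_index + config.area_style_loading * s_hi > 0
    complier = (w_hi & ~w_lo).astype(np.int64)

    cell = _cell_key(config, cci, age, cost_q)
    out = {
        "patient_id": np.arange(n, dtype=np.int64),
        "area_id": area_id,
        "treatment": treatment,
    }
    truth = {
        "area_style": style_i,
        "complexity": complexity,
        "complier": complier,
        "cell": np.array(CELL_KEYS)[cell],
    }

    s = config.complexity_effect_interaction
    for label, base_map, tau_map, c_base in (
        ("benefit", config.baseline_benefit, config.tau_benefit,
         config.complexity_baseline_benefit),
        ("detriment", config.baseline_detriment, config.tau_detriment,
         config.complexity_baseline_detriment),
    ):
        p0 = np.clip(_map_to_array(base_map)[cell] + c_base * complexity, 0.01, 0.99)
        p1 = np.clip(p0 + _map_to_array(tau_map)[cell] + s * complexity, 0.0, 1.0)
        tau = p1 - p0
        udraw = rng.uniform(size=n)
        y0 = (udraw < p0).astype(np.int64)
        y1 = (udraw < p1).astype(np.int64)
        out[f"y_{label}"] = np.where(treatment == 1, y1, y0)
        truth[f"tau_{label}"] = tau
        truth[f"y0_{label}"] = y0
        truth[f"y1_{label}"] = y1

    for name in COVARIATE_NAMES:
        out[name] = cov[name]
    for name, val in truth.items():
        out[TRUTH_PREFIX + name] = val
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------


def class_mask(df: pd.DataFrame, predicates: Sequence[tuple[str, str, int]]) -> np.ndarray:
    """Boolean row mask for a conjunction of (covariate, relation, level).

    Relations: "<=", ">", "==".
    """
    mask = np.ones(len(df), dtype=bool)
    for name, rel, level in predicates:
        x = df[name].to_numpy()
        if rel == "<=":
            mask &= x <= level
        elif rel == ">":
            mask &= x > level
        elif rel == "==":
            mask &= x == level
        else:
            raise ValueError(f"unknown relation {rel!r}")
    return mask


def true_class_late(
    df: pd.DataFrame,
    predicates: Sequence[tuple[str, str, int]],
    outcome: str = "benefit",
) -> float:
    """Ground-truth complier-average effect within a covariate class.

    The benchmark every within-class IV fit is trying to recover: the mean
    planted individual effect among the class members whose treatment status
    switches between the low and high instrument counterfactuals.
    """
    col = f"{TRUTH_PREFIX}tau_{outcome}"
    if col not in df.columns or f"{TRUTH_PREFIX}complier" not in df.columns:
        raise ValueError("cohort has no ground truth columns")
    mask = class_mask(df, predicates)
    if not mask.any():
        raise ValueError("class predicates select no patients")
    compl = df[f"{TRUTH_PREFIX}complier"].to_numpy().astype(bool) & mask
    if not compl.any():
        raise ValueError("undefined LATE: class contains no compliers")
    return float(df.loc[compl, col].mean())


# ---------------------------------------------------------------------------
# flat-file round trip (fixed formatting so identical cohorts are
# byte-identical on disk)

_FLOAT_FMT = "%.10g"


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def strip_truth(df: pd.DataFrame) -> pd.DataFrame:
    """Drop every ``truth_`` column (estimation stages must not see them)."""
    return df[[c for c in df.columns if not c.startswith(TRUTH_PREFIX)]]
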