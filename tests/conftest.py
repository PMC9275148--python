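"""Shared fixtures.

The expensive session fixture ``seed_sweep`` runs the full estimation chain
(simulate -> instrument -> forest -> CART -> per-cell 2SLS) over 20
independent cohort seeds at the default study conditions; several
statistical checks consume different slices of it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import ivforest as iv
from ivforest.cohort import cell_labels, CELL_KEYS
from ivforest.forest import _derive_seed
from ivforest.tsls import _free_controls


N_SWEEP_SEEDS = 20


def make_instrumented_cohort(seed: int, n: int = 20_000, **overrides):
    cfg = iv.SimulationConfig(n_patients=n, seed=seed, **overrides)
    df = iv.simulate_cohort(cfg)
    df2, inst = iv.attach_instrument(df)
    return cfg, df, df2, inst


@pytest.fixture(scope="session")
def small_cohort():
    """A modest instrumented cohort for fast structural tests."""
    cfg, df, df2, inst = make_instrumented_cohort(seed=11, n=4000, n_areas=40)
    return cfg, df, df2, inst


@pytest.fixture(scope="session")
def seed_sweep():
    """Per-seed artifacts of the full chain at the default study conditions.

    For each seed: the cohort (with truth), the instrumented cohort, benefit
    forest estimates (200 trees, minimum leaf 200), the depth-3 class
    partition, and per planted-cell 2SLS and naive difference-in-means
    results against the ground-truth complier-average effect.
    """
    out = []
    for seed in range(N_SWEEP_SEEDS):
        cfg, df, df2, _ = make_instrumented_cohort(seed)
        partitions_by_ml = {}
        tau_hat = None
        for ml in (100, 200, 400):
            model = iv.fit_forest(
                df2, "benefit",
                iv.ForestConfig(num_trees=200, min_leaf_size=ml,
                                seed=_derive_seed(1000, seed, ml)),
            )
            tau = iv.predict_effects(model, df2)
            partitions_by_ml[ml] = iv.fit_cart(tau, df2, max_depth=3, min_node=ml)
            if ml == 200:
                tau_hat = tau
        partition = partitions_by_ml[200]

        cells = cell_labels(cfg, df2)
        cell_results = []
        for key in np.unique(cells):
            mask = cells == key
            sub = df2.loc[mask]
            truth = df.loc[mask]
            compliers = truth["truth_complier"].to_numpy().astype(bool)
            late = float(truth.loc[compliers, "truth_tau_benefit"].mean())
            fit = iv.fit_2sls(
                sub["y_benefit"].to_numpy(),
                sub["treatment"].to_numpy(),
                sub["instrument"].to_numpy(),
                controls=_free_controls(sub),
            )
            y = sub["y_benefit"].to_numpy()
            w = sub["treatment"].to_numpy().astype(bool)
            naive = float(y[w].mean() - y[~w].mean())
            naive_se = float(np.sqrt(
                y[w].var(ddof=1) / w.sum() + y[~w].var(ddof=1) / (~w).sum()
            ))
            cell_results.append({
                "cell": key, "late": late, "ive": fit.ive, "se": fit.se,
                "F": fit.first_stage_F, "naive": naive, "naive_se": naive_se,
            })
        out.append({
            "seed": seed,
            "config": cfg,
            "cohort": df,
            "instrumented": df2,
            "tau_hat": tau_hat,
            "partition": partition,
            "partitions_by_ml": partitions_by_ml,
            "cells": pd.DataFrame(cell_results),
        })
    return out
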