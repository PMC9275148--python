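"""End-to-end orchestration: cohort -> instrument -> forest grid -> classes
-> consistency -> within-class 2SLS -> report.

Every artifact is delimited or structured text written with fixed float
formatting, so a re-run with the same configuration and master seed is
byte-identical for all deterministic outputs.  The manifest records the
configuration echo, a content digest per file, and per-stage wall-clock.
"""

from __future__ import annotations

import hashlib
import itertools
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import cohort as cohort_mod
from . import expost, forest, instrument, schema, tsls

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "validate_cohort"]


@dataclass
class RunConfig:
    """Configuration of a full study run.

    ``cohort_path`` ingests an existing patient table; when absent a
    synthetic cohort is simulated from ``simulation`` (a mapping of
    SimulationConfig overrides).  The default grid is a desk-scale 1 x 3
    (200 trees, three leaf sizes); the conventional full grid crosses
    {3000, 4000, 5000} trees with {50, 100, 200, 300, 400} leaf sizes.
    """

    out_dir: str = "ivforest_run"
    seed: int = 0
    cohort_path: str | None = None
    simulation: dict = field(default_factory=dict)
    outcomes: list[str] = field(default_factory=lambda: ["benefit", "detriment"])
    tree_counts: list[int] = field(default_factory=lambda: [200])
    leaf_sizes: list[int] = field(default_factory=lambda: [100, 200, 400])
    cart_max_depth: int = 3
    cart_min_node: int | None = None  # default: the source forest's leaf size
    tsls_alpha: float = 0.05
    tsls_robust: bool = False
    tsls_cluster_by_area: bool = False
    area_controls: list[str] = field(default_factory=list)
    # representative grid point for the 2SLS stage (num_trees, min_leaf_size);
    # default: first tree count with the middle leaf size
    report_grid_point: list[int] | None = None

    def validate(self) -> None:
        if not self.outcomes:
            raise ValueError("outcomes must be nonempty")
        if not self.tree_counts or not self.leaf_sizes:
            raise ValueError("forest grid must be nonempty")
        bad = set(self.outcomes) - {"benefit", "detriment"}
        if bad:
            raise ValueError(f"unknown outcomes: {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


@dataclass
class RunManifest:
    config: dict
    versions: dict
    files: dict[str, str]          # relative path -> sha256
    stage_seconds: dict[str, float]

    def write(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def validate_cohort(path) -> pd.DataFrame:
    """Read and schema-check a cohort file; raises with every error listed."""
    df = cohort_mod.read_cohort(path)
    errors = schema.validate_cohort(df)
    if errors:
        raise ValueError("cohort validation failed:\n" + "\n".join(f"- {e}" for e in errors))
    return df


class _StageClock:
    def __init__(self):
        self.times: dict[str, float] = {}

    def __call__(self, name):
        clock = self

        class _Ctx:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, *exc):
                clock.times[name] = round(time.perf_counter() - self.t0, 3)

        return _Ctx()


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute every stage in order and return the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    clock = _StageClock()

    def emit(name: str, writer) -> Path:
        path = out / name
        writer(path)
        files[name] = _digest(path)
        return path

    # ---- stage 1: cohort -------------------------------------------------
    with clock("cohort"):
        if config.cohort_path:
            df = validate_cohort(config.cohort_path)
        else:
            sim = dict(config.simulation)
            sim.setdefault("seed", forest._derive_seed(config.seed, 1))
            sim_cfg = cohort_mod.SimulationConfig(**sim)
            df = cohort_mod.simulate_cohort(sim_cfg)
            emit("simulation_config.yaml", sim_cfg.to_yaml)
        emit("cohort.tsv", lambda p: cohort_mod.write_cohort(df, p))

    # ---- stage 2: instrument --------------------------------------------
    with clock("instrument"):
        est_df = cohort_mod.strip_truth(df)
        df2, inst = instrument.attach_instrument(est_df)
        emit("instrument_areas.tsv",
             lambda p: inst.area_table.to_csv(p, sep="\t", index=False, float_format="%.10g"))
        emit("cohort_with_instrument.tsv", lambda p: cohort_mod.write_cohort(df2, p))

    # ---- stage 3: forest grid -------------------------------------------
    with clock("forest"):
        estimates, summary = forest.estimate_grid(
            df2, config.outcomes, config.tree_counts, config.leaf_sizes,
            seed=forest._derive_seed(config.seed, 3),
        )
        emit("effect_estimates.tsv",
             lambda p: estimates.to_csv(p, sep="\t", index=False, float_format="%.10g"))
        emit("effect_summaries.tsv",
             lambda p: summary.to_csv(p, sep="\t", index=False, float_format="%.6g"))

    # ---- stage 4: ex-post classes ---------------------------------------
    with clock("classes"):
        partitions: dict[tuple[str, int, int], expost.ClassPartition] = {}
        render_lines = []
        for outcome, nt, ml in itertools.product(
            config.outcomes, config.tree_counts, config.leaf_sizes
        ):
            sel = estimates[
                (estimates["outcome"] == outcome)
                & (estimates["num_trees"] == nt)
                & (estimates["min_leaf_size"] == ml)
            ]
            tau = sel.set_index("patient_id").loc[df2["patient_id"], "tau_hat"].to_numpy()
            part = expost.fit_cart(
                tau, df2, max_depth=config.cart_max_depth,
                min_node=config.cart_min_node or ml,
            )
            partitions[(outcome, nt, ml)] = part
            render_lines.append(
                f"== outcome={outcome} num_trees={nt} min_leaf_size={ml} ==\n"
                + expost.render_tree(part)
            )
        for outcome in config.outcomes:
            for nt in config.tree_counts:
                by_ml = {ml: partitions[(outcome, nt, ml)] for ml in config.leaf_sizes}
                if len(by_ml) >= 2:
                    table = expost.tabulate_class_definitions(
                        by_ml, ascending=(outcome == "detriment")
                    )
                    emit(f"class_definitions_{outcome}_t{nt}.tsv",
                         lambda p, t=table: t.to_csv(p, sep="\t"))
        emit("class_trees.txt",
             lambda p: p.write_text("\n\n".join(render_lines) + "\n"))

    # ---- stage 5: cross-parameter consistency ---------------------------
    with clock("consistency"):
        rows = []
        for outcome in config.outcomes:
            keys = [k for k in partitions if k[0] == outcome]
            for ka, kb in itertools.combinations(sorted(keys), 2):
                entry = expost.compare_partitions(partitions[ka], partitions[kb])
                rows.append({
                    "outcome": outcome,
                    "config_a": f"t{ka[1]}_l{ka[2]}",
                    "config_b": f"t{kb[1]}_l{kb[2]}",
                    "exact_matches": entry.exact_matches,
                    "membership_agreement": entry.membership_agreement,
                    "effect_rank_concordance": entry.effect_rank_concordance,
                })
        cons = pd.DataFrame(rows)
        emit("consistency.tsv",
             lambda p: cons.to_csv(p, sep="\t", index=False, float_format="%.6g"))

    # ---- stage 6: within-class 2SLS + cross-tab -------------------------
    with clock("tsls"):
        gp = config.report_grid_point or [
            config.tree_counts[0],
            sorted(config.leaf_sizes)[len(config.leaf_sizes) // 2],
        ]
        nt, ml = int(gp[0]), int(gp[1])
        kw = dict(alpha=config.tsls_alpha, robust=config.tsls_robust,
                  cluster_by_area=config.tsls_cluster_by_area,
                  area_controls=config.area_controls or None)
        for outcome in config.outcomes:
            part = partitions[(outcome, nt, ml)]
            fits = tsls.fit_class_table(df2, part, outcome, **kw)
            emit(f"class_fits_{outcome}.tsv",
                 lambda p, f=fits: f.to_csv(p, sep="\t", index=False, float_format="%.6g"))
        if set(config.outcomes) >= {"benefit", "detriment"}:
            xt = tsls.build_crosstab(
                df2, partitions[("benefit", nt, ml)],
                partitions[("detriment", nt, ml)], **kw,
            )
            emit("crosstab_cells.tsv",
                 lambda p: xt.cells.to_csv(p, sep="\t", index=False, float_format="%.6g"))
            pop = pd.DataFrame([
                {"outcome": "benefit", **xt.population_benefit.__dict__},
                {"outcome": "detriment", **xt.population_detriment.__dict__},
            ])
            emit("population_fits.tsv",
                 lambda p: pop.to_csv(p, sep="\t", index=False, float_format="%.6g"))

    manifest = RunManifest(
        config=asdict(config),
        versions={"ivforest": __version__,
                  "numpy": np.__version__, "pandas": pd.__version__},
        files=files,
        stage_seconds=clock.times,
    )
    manifest.write(out / "manifest.yaml")
    return manifest
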