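"""End-to-end orchestration: generate/load -> build -> fit -> evaluate -> DCA -> ops.

A :class:`RunConfig` fully determines a run; all randomness fans out from its
single top-level seed, and re-running an identical config reproduces every
deterministic artifact byte for byte. Each stage writes plain-text artifacts
(CSV/JSON/YAML) into the output directory so any stage can later be re-run in
isolation from the serialized output of the previous one.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, daybuild, dca, models, ops, plots
from .cohort import CohortSpec, generate_cohort
from .errors import ConfigurationError, StageDependencyError
from .evaluation import reliability_bins, summarize
from .ops import OpsParams

__all__ = ["RunConfig", "run_pipeline", "load_table", "save_table"]

log = logging.getLogger(__name__)

DCA_OUTCOMES = ("any_exit", "floor_only")


@dataclass
class RunConfig:
    """Everything needed to reproduce one analysis run."""

    outdir: str = "runs/default"
    input_path: str | None = None  # user-supplied patient-day table; None -> synthesize
    n_admissions: int = 2000
    exit_prevalence: float = 0.76
    floor_fraction: float = 0.77
    seed: int = 7
    split_fractions: tuple[float, float, float] = (0.81, 0.09, 0.10)
    n_folds: int = 10
    max_stay_days: int = 60
    families: tuple[str, ...] = ("l2_logistic", "random_forest", "gradient_boosting")
    primary_family: str = "random_forest"
    eval_partition: str = "test"
    dca_outcome: str = "any_exit"  # or "floor_only"
    ops: OpsParams = field(default_factory=OpsParams)

    def validate(self) -> None:
        for fam in self.families:
            if fam not in models.FAMILIES:
                raise ConfigurationError(f"unknown model family {fam!r}")
        if self.primary_family not in self.families:
            raise ConfigurationError("primary_family must be among families")
        if self.dca_outcome not in DCA_OUTCOMES:
            raise ConfigurationError(f"dca_outcome must be one of {DCA_OUTCOMES}")
        if self.eval_partition not in ("test", "holdout"):
            raise ConfigurationError("eval_partition must be 'test' or 'holdout'")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ConfigurationError("split_fractions must sum to 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "ops" in raw and raw["ops"] is not None:
            raw["ops"] = OpsParams(**raw["ops"])
        if "split_fractions" in raw:
            raw["split_fractions"] = tuple(raw["split_fractions"])
        if "families" in raw:
            raw["families"] = tuple(raw["families"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["split_fractions"] = list(self.split_fractions)
        d["families"] = list(self.families)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def save_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a patient-day table (or any stage table) as CSV."""
    table.to_csv(path, index=False)


def load_table(path: str | Path) -> pd.DataFrame:
    """Read a patient-day table, preserving the column-naming contract."""
    path = Path(path)
    if not path.exists():
        raise StageDependencyError(f"missing upstream artifact: {path}")
    if path.suffix == ".parquet":
        return pd.read_parquet(path)
    return pd.read_csv(path)


_STAGE_OFFSETS = {"cohort": 1, "split": 2, "fit": 3}


def _derive_seed(seed: int, stage: str) -> int:
    # simple, stable fan-out (hash() is salted per-process, so not used)
    return (seed * 1000003 + _STAGE_OFFSETS[stage]) % (2**31)


def _dca_labels(table: pd.DataFrame, preds: pd.DataFrame, outcome: str) -> np.ndarray:
    if outcome == "any_exit":
        return preds["y"].to_numpy(dtype=int)
    dest = (
        table.set_index(["admission_id", "day_index"])["label_exit_destination"]
        .reindex(pd.MultiIndex.from_frame(preds[["admission_id", "day_index"]]))
        .to_numpy()
    )
    return ((preds["y"].to_numpy(dtype=int) == 1) & (dest == "floor")).astype(int)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order; return (and write) the run manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}}

    def timed(stage):
        t0 = time.perf_counter()

        def done():
            manifest["stages"][stage] = round(time.perf_counter() - t0, 3)
            log.info("stage %s finished in %.2fs", stage, manifest["stages"][stage])

        return done

    # --- cohort ------------------------------------------------------------
    end = timed("cohort")
    if config.input_path:
        raw = load_table(config.input_path)
    else:
        spec = CohortSpec(
            n_admissions=config.n_admissions,
            exit_prevalence=config.exit_prevalence,
            floor_fraction=config.floor_fraction,
            seed=_derive_seed(config.seed, "cohort"),
        )
        raw = generate_cohort(spec)
    save_table(raw, outdir / "cohort.csv")
    end()

    # --- daybuild ----------------------------------------------------------
    end = timed("daybuild")
    aligned = daybuild.align_labels(raw, max_days=config.max_stay_days)
    filled = daybuild.forward_fill(aligned)
    assignment = daybuild.split_admissions(
        filled,
        fractions=config.split_fractions,
        seed=_derive_seed(config.seed, "split"),
        n_folds=config.n_folds,
    )
    assignment.to_csv(outdir / "splits.csv", index=False)
    part_of = assignment.set_index("admission_id")["partition"]
    partition = filled["admission_id"].map(part_of)
    train_raw = filled[partition == "train"].reset_index(drop=True)
    imputer = daybuild.fit_imputer(train_raw)
    parts = {
        name: daybuild.apply_imputer(imputer, filled[partition == name].reset_index(drop=True))
        for name in daybuild.PARTITIONS
    }
    folds = daybuild.cv_fold_indices(parts["train"], assignment)
    end()

    # --- fit + predict -----------------------------------------------------
    end = timed("fit")
    fit_seed = _derive_seed(config.seed, "fit")
    pred_sets: dict[str, pd.DataFrame] = {}
    fitted: dict[str, models.FittedModel] = {}
    for family in config.families:
        m = models.fit(family, parts["train"], folds, seed=fit_seed)
        fitted[family] = m
        pred_sets[family] = models.predict(m, parts[config.eval_partition], config.eval_partition)
        models.importance(m).to_csv(outdir / f"importance_{family}.csv", index=False)
    all_preds = pd.concat(pred_sets.values(), ignore_index=True)
    all_preds.to_csv(outdir / "predictions.csv", index=False)
    end()

    # --- evaluation ---------------------------------------------------------
    end = timed("evaluate")
    metrics = {}
    for family, preds in pred_sets.items():
        rep = summarize(preds["y"], preds["p"])
        metrics[family] = json.loads(rep.to_json())
        reliability_bins(preds["y"], preds["p"]).to_csv(
            outdir / f"reliability_{family}.csv", index=False
        )
    (outdir / "metrics.json").write_text(json.dumps(metrics, indent=2))
    plots.evaluation_figure(pred_sets, outdir / "evaluation.png")
    end()

    # --- decision curves ----------------------------------------------------
    end = timed("dca")
    eval_table = parts[config.eval_partition]
    # the heuristic screens raw daily observations (missing -> not flagged),
    # so it is computed on the pre-fill aligned rows of the eval partition
    eval_raw = aligned[(partition == config.eval_partition).to_numpy()].reset_index(drop=True)
    save_table(eval_raw, outdir / "eval_raw.csv")
    h_cols = {"heart_rate_mean", "resp_rate_mean", "vasopressor_flag"}
    h = dca.heuristic_flags(eval_raw) if h_cols <= set(eval_raw.columns) else None
    curves: dict[str, pd.DataFrame] = {}
    for family, preds in pred_sets.items():
        y_dca = _dca_labels(eval_table, preds, config.dca_outcome)
        curve = dca.decision_curve(y_dca, preds["p"].to_numpy(), heuristic=h)
        curves[family] = curve
        curve.to_csv(outdir / f"decision_curve_{family}.csv", index=False)
    plots.dca_figure(curves[config.primary_family], outdir / "decision_curve.png")
    end()

    # --- ops ---------------------------------------------------------------
    end = timed("ops")
    curve = curves[config.primary_family]
    ops_df = ops.ops_table(curve, config.ops)
    ops_df.to_csv(outdir / "ops_results.csv", index=False)
    best = ops.optimize_threshold(curve, config.ops)
    if best is None:
        opt = {"feasible": False}
        t_star = None
    else:
        t_star, row = best
        opt = {"feasible": True, "threshold": t_star}
        opt.update({k: (None if isinstance(v, float) and np.isnan(v) else v)
                    for k, v in row.drop("threshold").items()})
        opt = json.loads(pd.Series(opt).to_json())
    (outdir / "optimal_threshold.json").write_text(json.dumps(opt, indent=2))
    plots.ops_figure(ops_df, config.ops.daily_budget, t_star, outdir / "ops.png")
    end()

    manifest["metrics"] = metrics
    manifest["optimal"] = opt
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
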