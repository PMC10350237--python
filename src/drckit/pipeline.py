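"""End-to-end workflow: simulate -> fit -> select -> classify -> report.

Each stage is a pure function of (inputs, config, stage seed); the global
seed deterministically derives a seed per stage from the stage's name, so
adding a stage never perturbs the randomness of earlier ones.  Every run
writes a manifest with the full configuration echo, the derived seeds and
a checksum per artifact — the manifest alone reproduces the run.

Stages can consume existing CSVs (a measured cohort) in place of the
synthetic generator: supply ``donors_csv``/``signals_csv`` and the rest
of the pipeline runs unchanged.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .cohort import (
    CohortConfig,
    frame_to_donors,
    generate_cohort,
    validate_signals,
    write_cohort,
)
from .classify import CaseControlForest, ForestConfig, compare_models
from .kinetics import fit_cohort
from .selection import boruta_select, build_feature_table, split_features, stable_seed

logger = logging.getLogger("drckit")

STAGES = ("simulate", "fit", "select", "classify")


@dataclass
class RunConfig:
    """Everything a pipeline run depends on, in one serializable object."""

    outdir: str = "drckit_run"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    donors_csv: str | None = None  # consume measured data instead of simulating
    signals_csv: str | None = None
    include_age: bool = True
    boruta_n_iter: int = 100
    boruta_alpha: float = 0.05
    boruta_n_trees: int = 100
    forest: ForestConfig = field(default_factory=ForestConfig)
    n_bootstrap: int = 10_000
    ci_level: float = 0.95
    seed: int = 0
    log_level: str = "INFO"

    def stage_seed(self, stage: str) -> int:
        return stable_seed(self.seed, "stage", stage)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            cohort = dict(d["cohort"])
            for key in ("subtypes", "times", "control_times", "age_range"):
                if key in cohort and isinstance(cohort[key], list):
                    cohort[key] = tuple(cohort[key])
            if "baselines" in cohort:
                cohort["baselines"] = {
                    k: tuple(v) for k, v in cohort["baselines"].items()
                }
            d["cohort"] = CohortConfig(**cohort)
        if "forest" in d and isinstance(d["forest"], dict):
            d["forest"] = ForestConfig(**d["forest"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", "utf-8")


class StageError(RuntimeError):
    """A pipeline stage failed; earlier artifacts are preserved on disk."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


def _setup_logging(outdir: Path, level: str) -> None:
    logger.setLevel(level.upper())
    logger.handlers = [
        h
        for h in logger.handlers
        if not isinstance(h, logging.FileHandler)
    ]
    if not any(isinstance(h, logging.StreamHandler) for h in logger.handlers):
        sh = logging.StreamHandler()
        sh.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logger.addHandler(sh)
    fh = logging.FileHandler(outdir / "run.log", mode="w", encoding="utf-8")
    fh.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(fh)


def stage_simulate(config: RunConfig, outdir: Path) -> tuple[list, pd.DataFrame]:
    """Generate the synthetic cohort, or load the configured CSVs instead."""
    if config.signals_csv or config.donors_csv:
        if not (config.signals_csv and config.donors_csv):
            raise StageError(
                "simulate", "both donors_csv and signals_csv must be given"
            )
        for p in (config.donors_csv, config.signals_csv):
            if not Path(p).exists():
                raise StageError("simulate", f"input file not found: {p}")
        donors = frame_to_donors(pd.read_csv(config.donors_csv))
        points = validate_signals(pd.read_csv(config.signals_csv))
        logger.info("loaded %d donors from %s", len(donors), config.donors_csv)
    else:
        cohort_cfg = dataclasses.replace(
            config.cohort, seed=config.stage_seed("simulate")
        )
        donors, points = generate_cohort(cohort_cfg)
        logger.info(
            "simulated %d donors (%d pairs)", len(donors), cohort_cfg.n_pairs
        )
    write_cohort(donors, points, outdir)
    return donors, points


def stage_fit(
    config: RunConfig, outdir: Path, donors: list, points: pd.DataFrame
) -> pd.DataFrame:
    params, skipped = fit_cohort(donors, points, dose=config.cohort.dose)
    params.to_csv(outdir / "repair_params.csv", index=False)
    _write_json({"skipped": skipped}, outdir / "fit_skips.json")
    logger.info("fitted %d series, skipped %d", len(params), len(skipped))
    if params.empty:
        raise StageError("fit", "no series could be fitted")
    return params


def stage_features(
    config: RunConfig, outdir: Path, params: pd.DataFrame, donors: list
) -> pd.DataFrame:
    table, excluded = build_feature_table(
        params, donors, include_age=config.include_age
    )
    table.to_csv(outdir / "feature_table.csv")
    if excluded:
        logger.warning("excluded donors with incomplete fits: %s", excluded)
    if table.empty:
        raise StageError("select", "feature table is empty")
    return table


def stage_select(config: RunConfig, outdir: Path, table: pd.DataFrame):
    X, y = split_features(table)
    kinetic = X.drop(columns=["age_at_draw"], errors="ignore")
    report = boruta_select(
        kinetic,
        y,
        n_iter=config.boruta_n_iter,
        alpha=config.boruta_alpha,
        seed=config.stage_seed("select"),
        n_trees=config.boruta_n_trees,
    )
    _write_json(report.to_dict(), outdir / "selection_report.json")
    logger.info("confirmed features: %s", report.confirmed)
    return report


def stage_classify(config: RunConfig, outdir: Path, table: pd.DataFrame, report):
    X, y = split_features(table)
    seed = config.stage_seed("classify")
    forest_cfg = config.forest.with_(seed=seed)
    out: dict = {"models": {}}

    model_features: dict[str, list[str]] = {}
    if report.confirmed:
        model_features["selected"] = report.confirmed
    if config.include_age and "age_at_draw" in X.columns:
        model_features["age"] = ["age_at_draw"]
        if report.confirmed:
            model_features["selected+age"] = report.confirmed + ["age_at_draw"]
    if not model_features:
        raise StageError(
            "classify", "no confirmed features and age not included; nothing to fit"
        )

    roc_frames = []
    for name, feats in model_features.items():
        res = CaseControlForest(X[feats], y, forest_cfg).fit()
        out["models"][name] = res.to_dict(n_boot=config.n_bootstrap, seed=seed)
        roc = res.roc()
        roc.insert(0, "model", name)
        roc_frames.append(roc)
        logger.info("model %-12s AUC %.3f accuracy %.3f", name, res.auc, res.acc)
    pd.concat(roc_frames, ignore_index=True).to_csv(
        outdir / "roc_points.csv", index=False
    )
    _write_json(out, outdir / "classifier_report.json")

    if "selected+age" in model_features and "age" in model_features:
        cmp = compare_models(
            X[model_features["selected+age"]],
            X[model_features["age"]],
            y,
            forest_cfg,
            label_a="selected+age",
            label_b="age",
        )
        _write_json(cmp.to_dict(), outdir / "comparison_report.json")
        logger.info("comparison: %s", cmp.summary().replace("\n", " | "))
        out["comparison"] = cmp.to_dict()
    return out


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage and write a manifest; returns the run directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir, config.log_level)

    donors, points = stage_simulate(config, outdir)
    params = stage_fit(config, outdir, donors, points)
    table = stage_features(config, outdir, params, donors)
    report = stage_select(config, outdir, table)
    stage_classify(config, outdir, table, report)

    artifacts = sorted(
        p.name
        for p in outdir.iterdir()
        if p.suffix in {".csv", ".json"} and p.name != "manifest.json"
    )
    from . import __version__ as package_version

    manifest = {
        "package_version": package_version,
        "config": config.to_dict(),
        "stage_seeds": {s: config.stage_seed(s) for s in STAGES},
        "checksums": {name: _sha256(outdir / name) for name in artifacts},
    }
    _write_json(manifest, outdir / "manifest.json")
    logger.info("run complete: %s", outdir)
    return outdir
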