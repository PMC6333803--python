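"""End-to-end orchestration of the aging-clock study on a synthetic cohort.

Stages: simulate -> arbitrage feature selection -> reconstruction ->
age clock on nonsmokers -> prediction + log2 aging-ratio analysis ->
age clock with smoking as a feature -> smoking classifier ->
permutation importance / partial dependence. Every stage writes its
artifact under the run directory and records seeds, sizes and content
hashes in ``manifest.json``; excluded samples, skipped spaces and
unfillable cells are counted there rather than dropped silently.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aging import (
    assign_risk_groups,
    attach_ratios,
    group_aging_summary,
    marker_age_bicor,
    risk_group_aging_summary,
)
from .arbitrage import (
    DEFAULT_N_SPACES,
    DEFAULT_N_TREES,
    MIN_ELIGIBLE,
    arbitrage_fi,
    enumerate_feature_spaces,
    fit_arbitrage_ensemble,
    select_feature_sets,
)
from .clock import (
    ALL_WITH_SMOKING,
    DEFAULT_EPSILON,
    SplitSpec,
    predict_age,
    regression_metrics,
    split_train_test,
    train_age_model,
)
from .cohort import GeneratorConfig, generate_cohort, marker_names, write_cohort_csv
from .errors import ConfigError
from .importance import partial_dependence, permutation_importance
from .reconstruction import expand_feature_space
from .smoking import classification_metrics, confusion_by_age_group, train_smoking_model

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of a full run; every stochastic stage has a seed."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    n_spaces: int = DEFAULT_N_SPACES
    n_trees: int = DEFAULT_N_TREES
    n_sets: int = 3
    min_eligible: int = MIN_ELIGIBLE
    split: SplitSpec = field(default_factory=SplitSpec)
    epsilon: float = DEFAULT_EPSILON
    estimator: str = "mlp"
    pfi_repeats: int = 10
    seed: int | None = 0

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigError("pipeline seed must be set before any stage runs")
        self.generator.validate()
        self.split.validate()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        generator = GeneratorConfig(**raw.pop("generator", {}))
        split = SplitSpec(**raw.pop("split", {}))
        return cls(generator=generator, split=split, **raw)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def _write_tsv(frame: pd.DataFrame, path: Path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index, lineterminator="\n")


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Execute every stage; returns the run directory.

    Reruns with the same config reproduce all deterministic artifacts
    bit for bit; metric reports of refitted models match to 1e-6.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}}
    seed = int(config.seed)

    def record(stage: str, **info) -> None:
        files = info.pop("files", [])
        manifest["stages"][stage] = {
            **info,
            "files": {f.name: _sha256(f) for f in files},
        }
        logger.info("stage %s done: %s", stage, info)

    # 1. simulate
    cohort = generate_cohort(config.generator)
    cohort_path = outdir / "cohort.csv"
    write_cohort_csv(cohort, cohort_path)
    record(
        "simulate",
        n_subjects=len(cohort),
        n_markers=len(marker_names(cohort)),
        n_smokers=int(cohort["smoking"].sum()),
        median_age=float(cohort["age"].median()),
        files=[cohort_path],
    )

    # 2. arbitrage feature selection
    spaces = enumerate_feature_spaces(
        cohort, n_spaces=config.n_spaces, min_eligible=config.min_eligible, seed=seed
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        records = fit_arbitrage_ensemble(
            cohort, spaces, n_trees=config.n_trees, seed=seed,
            min_eligible=config.min_eligible,
        )
    scores = arbitrage_fi(records)
    sets = select_feature_sets(scores, cohort, n_sets=config.n_sets)
    ranking_path = outdir / "arbitrage_ranking.tsv"
    _write_tsv(scores, ranking_path)
    sets_path = outdir / "feature_sets.json"
    sets_path.write_text(
        json.dumps(
            [{"markers": list(s.markers), "eligible_n": s.eligible_n} for s in sets],
            indent=2,
        ),
        encoding="utf-8",
    )
    record(
        "select_features",
        n_spaces=len(spaces),
        n_models=len(records),
        n_skipped_spaces=len(spaces) - len(records),
        n_trees=config.n_trees,
        set_sizes=[len(s.markers) for s in sets],
        files=[ranking_path, sets_path],
    )

    # 3. reconstruction on the largest selected feature set
    largest = sets[-1]
    reco_cohort, expanded, reco = expand_feature_space(cohort, largest)
    reco_path = outdir / "cohort_reconstructed.csv"
    write_cohort_csv(reco_cohort, reco_path)
    record(
        "reconstruct",
        eligible_n=expanded.eligible_n,
        markers_before=len(largest.markers),
        markers_after=len(expanded.markers),
        unfilled_cells=reco.unfilled,
        files=[reco_path],
    )

    # 4. age clock trained on nonsmokers, applied to the held-out set
    features = [m for m in expanded.markers]
    complete = reco_cohort.dropna(subset=features)
    train, test = split_train_test(complete, config.split)
    excluded_incomplete = len(reco_cohort) - len(complete)
    age_model = train_age_model(
        train[train["smoking"] == 0], features, config.split, estimator=config.estimator
    )
    predictions = predict_age(age_model, test)
    metrics = regression_metrics(predictions, epsilon=config.epsilon)
    pred_path = outdir / "predictions.csv"
    predictions.to_csv(pred_path, index=False, lineterminator="\n")
    metrics_path = outdir / "age_metrics.json"
    metrics_path.write_text(json.dumps(metrics.to_dict(), indent=2), encoding="utf-8")
    record(
        "train_age_nonsmokers",
        n_train_nonsmokers=int((train["smoking"] == 0).sum()),
        n_test=len(test),
        n_excluded_incomplete=excluded_incomplete,
        estimator=config.estimator,
        cv_folds=config.split.cv_folds,
        metrics=metrics.to_dict(),
        files=[pred_path, metrics_path],
    )

    # 5. aging-ratio analysis (+ risk quadrants and marker-age bicor)
    ratios, n_excluded = attach_ratios(predictions)
    summary = group_aging_summary(ratios)
    summary_path = outdir / "aging_ratio_table.tsv"
    _write_tsv(summary, summary_path)
    stage_files = [summary_path]
    risk_cols = {"total_cholesterol", "hdl_cholesterol", "fasting_glucose"}
    n_unassigned = None
    if risk_cols <= set(test.columns):
        risk_labels, n_unassigned = assign_risk_groups(test)
        risk_table = risk_group_aging_summary(ratios, risk_labels)
        risk_path = outdir / "risk_group_table.tsv"
        _write_tsv(risk_table, risk_path)
        stage_files.append(risk_path)
    bicor_path = outdir / "marker_age_bicor.tsv"
    _write_tsv(marker_age_bicor(reco_cohort, features), bicor_path)
    stage_files.append(bicor_path)
    record(
        "aging_ratio",
        n_excluded_nonpositive=n_excluded,
        n_risk_unassigned=n_unassigned,
        files=stage_files,
    )

    # 6. age clock with smoking status as an input feature
    smoking_spec = SplitSpec(
        train_fraction=config.split.train_fraction,
        cv_folds=config.split.cv_folds,
        seed=config.split.seed,
        train_population=ALL_WITH_SMOKING,
    )
    aug_model = train_age_model(
        train, features + ["smoking", "sex"], smoking_spec, estimator=config.estimator
    )
    aug_pred = predict_age(aug_model, test)
    aug_metrics = regression_metrics(aug_pred, epsilon=config.epsilon)
    aug_path = outdir / "age_metrics_with_smoking.json"
    aug_path.write_text(json.dumps(aug_metrics.to_dict(), indent=2), encoding="utf-8")
    record(
        "train_age_with_smoking",
        metrics=aug_metrics.to_dict(),
        files=[aug_path],
    )

    # 7. smoking classifier
    smoker_model = train_smoking_model(
        train, features + ["sex"], smoking_spec, estimator=config.estimator
    )
    smoke_pred = smoker_model.predict(test)
    smoke_report = classification_metrics(test["smoking"], smoke_pred)
    confusion = confusion_by_age_group(test["smoking"], smoke_pred, test["age"])
    smoke_json = outdir / "smoking_report.json"
    smoke_json.write_text(json.dumps(smoke_report.to_dict(), indent=2), encoding="utf-8")
    confusion_path = outdir / "smoking_confusion_by_age.tsv"
    _write_tsv(confusion.table, confusion_path, index=True)
    record(
        "train_smoking",
        report=smoke_report.to_dict(),
        files=[smoke_json, confusion_path],
    )

    # 8. importance analysis of the with-smoking age model
    pfi = permutation_importance(
        aug_model, test[aug_model.features], test["age"].to_numpy(dtype=float),
        metric="mae", n_repeats=config.pfi_repeats, seed=seed,
    )
    pfi_path = outdir / "permutation_importance.tsv"
    _write_tsv(pfi, pfi_path)
    pd_curve = partial_dependence(aug_model, "smoking", test[aug_model.features])
    pd_path = outdir / "partial_dependence_smoking.tsv"
    _write_tsv(pd_curve.as_frame(), pd_path)
    record(
        "importance",
        smoking_importance=float(
            pfi.loc[pfi["feature"] == "smoking", "importance_mean"].iloc[0]
        ),
        pd_smoking=dict(zip(pd_curve.grid.tolist(), pd_curve.values.tolist())),
        files=[pfi_path, pd_path],
    )

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str), encoding="utf-8")
    _write_report(outdir, manifest)
    return outdir


def _write_report(outdir: Path, manifest: dict) -> None:
    lines = [
        "# hemoclock run report",
        "",
        f"package version {manifest['version']}, seed {manifest['seed']}",
        "",
    ]
    for stage, info in manifest["stages"].items():
        lines.append(f"## {stage}")
        for key, value in info.items():
            if key != "files":
                lines.append(f"- {key}: {value}")
        lines.append("")
    (outdir / "report.md").write_text("\n".join(lines), encoding="utf-8")
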