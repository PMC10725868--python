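"""End-to-end grouped cross-validation experiments.

`run_cv_experiment` wires the whole method together: build the labeled,
reversal-augmented dataset; assign grouped five-fold splits for the chosen
leave-out scheme; optionally pretrain the DDI classifier once; then, per
fold, fit every featurization statistic on the training rows, train the
two-headed network, and evaluate on the held-out fold. Fold metrics are
aggregated as mean ± SD with a Student-t 95 % confidence interval.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import data_pipeline as dp
from . import feature_prep as fp
from .config import ModelConfig
from .ddi_pretrain import DDIReport, train_ddi
from .metrics import (MetricReport, classification_metrics, fold_aggregate_ci,
                      regression_metrics)
from .pipeline import FeaturePipeline
from .synergy_model import assemble, predict, train

__all__ = ["ExperimentConfig", "CVResult", "prepare_records", "run_cv_experiment"]


class ExperimentConfig(BaseModel):
    """Validated experiment description (unknown keys are rejected)."""

    model_config = ConfigDict(extra="forbid")

    synergy_csv: Optional[str] = None
    drugs_csv: Optional[str] = None
    descriptors_csv: Optional[str] = None
    expression_csv: Optional[str] = None
    gene_panel: Optional[str] = None
    ddi_csv: Optional[str] = None
    scheme: str = "pair"
    seed: int = 0
    folds: Optional[list[int]] = None  # None → all five
    ddi_epochs: int = 30
    tanh_c: float = 1.0
    out_dir: Optional[str] = None
    model: ModelConfig = ModelConfig()

    def validated(self) -> "ExperimentConfig":
        if self.scheme not in dp.SCHEMES:
            raise ValueError(f"scheme must be one of {dp.SCHEMES}")
        self.model.validated()
        return self


@dataclass
class FoldResult:
    fold: int
    regression: dict[str, float]
    classification: dict[str, float]
    n_train: int
    n_test: int
    train_log_tail: dict = field(default_factory=dict)


@dataclass
class CVResult:
    """Per-fold metrics plus across-fold aggregate reports."""

    scheme: str
    seed: int
    folds: list[FoldResult]
    reports: dict[str, MetricReport]
    ddi_report: Optional[DDIReport] = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"metric": name, "mean": r.mean, "sd": r.sd,
             "ci_low": r.ci_low, "ci_high": r.ci_high, "n_folds": r.n_folds}
            for name, r in self.reports.items()
        ]
        return pd.DataFrame(rows)


def prepare_records(synergy: pd.DataFrame) -> pd.DataFrame:
    """Replicate-average, label and reversal-augment the raw synergy table."""
    records = dp.aggregate_replicates(synergy)
    records = dp.assign_class_labels(records)
    return dp.augment_reversed_pairs(records)


def run_cv_experiment(
    synergy: pd.DataFrame,
    drugs: pd.DataFrame,
    descriptors: pd.DataFrame,
    expression: pd.DataFrame,
    gene_panel: list[str],
    ddi: pd.DataFrame | None = None,
    config: ExperimentConfig | None = None,
    graph_dims: dict[str, int] | None = None,
) -> CVResult:
    """Run the grouped five-fold experiment on in-memory tables."""
    config = (config or ExperimentConfig()).validated()
    mcfg = config.model
    records = prepare_records(synergy)
    split = dp.split_folds(records, config.scheme, config.seed)

    ddi_model = None
    ddi_desc = None
    ddi_report = None
    if mcfg.interaction_attention:
        if ddi is None:
            raise ValueError("interaction attention requires a DDI table")
        cleaned = fp.clean_descriptors(descriptors)
        ddi_desc = fp.apply_normalizer(
            cleaned, fp.fit_normalizer(cleaned, c=config.tanh_c))
        ddi_model, ddi_report = train_ddi(
            ddi, ddi_desc, mcfg, seed=config.seed, epochs=config.ddi_epochs)

    folds = config.folds if config.folds is not None else list(range(split.n_folds))
    fold_results: list[FoldResult] = []
    for fold in folds:
        tr = records.iloc[split.train_indices(fold)]
        te = records.iloc[split.test_indices(fold)]
        pipe = FeaturePipeline(mcfg, graph_dims=graph_dims, c=config.tanh_c)
        pipe.fit(tr, drugs, descriptors, expression, gene_panel,
                 ddi_model=ddi_model, ddi_descriptors=ddi_desc)
        model = assemble(mcfg, pipe.feature_dims(), seed=config.seed + fold)
        log = train(model, pipe.transform(tr), mcfg, seed=config.seed + fold)
        pred = predict(model, pipe.transform(te))
        reg = regression_metrics(te["score"].to_numpy(), pred.scores)
        cls = classification_metrics(te["label"].to_numpy(), pred.probs)
        fold_results.append(FoldResult(
            fold=fold, regression=reg, classification=cls,
            n_train=len(tr), n_test=len(te),
            train_log_tail=log.epochs[-1] if log.epochs else {},
        ))

    reports: dict[str, MetricReport] = {}
    if len(fold_results) >= 2:
        for name in ("mse", "rmse", "pearson"):
            vals = [f.regression[name] for f in fold_results]
            if np.all(np.isfinite(vals)):
                reports[name] = fold_aggregate_ci(vals, name)
        for name in ("roc_auc", "pr_auc", "accuracy", "precision", "kappa"):
            vals = [f.classification[name] for f in fold_results]
            if np.all(np.isfinite(vals)):
                reports[name] = fold_aggregate_ci(vals, name)

    result = CVResult(config.scheme, config.seed, fold_results, reports, ddi_report)
    if config.out_dir:
        _write_artifacts(result, split, config)
    return result


def _write_artifacts(result: CVResult, split: dp.FoldSplit,
                     config: ExperimentConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.model_dump_json(indent=2))
    split.to_frame().to_csv(out / "fold_assignment.csv", index=False)
    result.to_frame().to_csv(out / "aggregate_report.csv", index=False)
    payload = {
        "scheme": result.scheme,
        "seed": result.seed,
        "folds": [
            {"fold": f.fold, "regression": f.regression,
             "classification": f.classification,
             "n_train": f.n_train, "n_test": f.n_test}
            for f in result.folds
        ],
    }
    (out / "fold_metrics.json").write_text(json.dumps(payload, indent=2))
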