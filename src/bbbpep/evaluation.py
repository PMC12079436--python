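"""Confusion-based metrics, ROC/AUC, and the three evaluation protocols.

Metrics follow the standard confusion-matrix definitions:

    ACC = (TP + TN) / (TP + TN + FP + FN)
    SEN = TP / (TP + FN)
    SPE = TN / (TN + FP)
    MCC = (TN*TP - FN*FP) / sqrt((FP+TP)(FN+TP)(FP+TN)(FN+TN))

with MCC defined as 0 whenever a denominator factor vanishes, and an
undefined sensitivity/specificity (empty class) reported as 0. AUC is the
trapezoidal area under the ROC, equal to the Mann-Whitney probability that
a random positive outscores a random negative, ties counted half.

Protocols:

* self-consistency: train and evaluate on the identical full dataset
  (a memorization/capacity check, not a generalization estimate);
* independent test: one stratified 77/23 split, scaler and model fitted on
  the training partition only;
* five-fold CV: stratified folds, each sample tested exactly once, metrics
  averaged over folds (a pooled-confusion mode is available).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from bbbpep.classifiers import TrainConfig, predict_labels, predict_proba, train
from bbbpep.features import DEFAULT_CONFIG, FeatureConfig, featurize_dataset, fit_apply_scaling
from bbbpep.sequences import LabeledDataset
from bbbpep.synthetic import SplitSpec, stratified_split_indices


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return cls(
            TP=int(((y_true == 1) & (y_pred == 1)).sum()),
            TN=int(((y_true == 0) & (y_pred == 0)).sum()),
            FP=int(((y_true == 0) & (y_pred == 1)).sum()),
            FN=int(((y_true == 1) & (y_pred == 0)).sum()),
        )


def metrics(c: ConfusionCounts) -> dict:
    """Accuracy, sensitivity, specificity, MCC from confusion counts."""
    if c.total == 0:
        raise ValueError("cannot compute metrics from all-zero confusion counts")
    accuracy = (c.TP + c.TN) / c.total
    sensitivity = c.TP / (c.TP + c.FN) if (c.TP + c.FN) > 0 else 0.0
    specificity = c.TN / (c.TN + c.FP) if (c.TN + c.FP) > 0 else 0.0
    denom = (c.FP + c.TP) * (c.FN + c.TP) * (c.FP + c.TN) * (c.FN + c.TN)
    if denom == 0:
        mcc = 0.0
    else:
        mcc = (c.TN * c.TP - c.FN * c.FP) / math.sqrt(denom)
    return {"accuracy": accuracy, "sensitivity": sensitivity, "specificity": specificity, "mcc": mcc}


def roc_auc(labels, positive_scores) -> tuple:
    """ROC points (fpr, tpr, thresholds) and trapezoidal AUC.

    Requires both classes present; AUC equals the Mann-Whitney estimate of
    P(score_pos > score_neg) with ties counted half.
    """
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires both classes to be present")
    fpr, tpr, thresholds = roc_curve(labels, np.asarray(positive_scores, dtype=float))
    return (fpr, tpr, thresholds), float(_trapezoid_auc(fpr, tpr))


@dataclass
class EvalReport:
    """Metrics for one evaluation protocol, serializable to JSON/Markdown."""

    protocol: str
    counts: ConfusionCounts
    accuracy: float
    sensitivity: float
    specificity: float
    mcc: float
    auc: float
    roc_points: Optional[tuple] = None
    folds: list = field(default_factory=list)
    classifier: str = ""

    def to_dict(self) -> dict:
        out = {
            "protocol": self.protocol,
            "classifier": self.classifier,
            "counts": {"TP": self.counts.TP, "TN": self.counts.TN, "FP": self.counts.FP, "FN": self.counts.FN},
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "mcc": self.mcc,
            "auc": self.auc,
        }
        if self.folds:
            out["folds"] = self.folds
        return out

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def to_markdown(self) -> str:
        header = "| Classifier | Accuracy | Sensitivity | Specificity | MCC |\n|---|---|---|---|---|\n"
        row = (
            f"| {self.classifier or self.protocol} | {self.accuracy:.3f} | "
            f"{self.sensitivity:.3f} | {self.specificity:.3f} | {self.mcc:.3f} |\n"
        )
        return header + row

    def write_roc_tsv(self, path) -> None:
        if self.roc_points is None:
            raise ValueError("report carries no ROC points")
        fpr, tpr, thr = self.roc_points
        with open(path, "w") as fh:
            fh.write("fpr\ttpr\tthreshold\n")
            for a, b, t in zip(fpr, tpr, thr):
                fh.write(f"{a:.6g}\t{b:.6g}\t{t:.6g}\n")


def _evaluate_predictions(y_true, y_pred, scores) -> tuple:
    counts = ConfusionCounts.from_predictions(y_true, y_pred)
    m = metrics(counts)
    roc, area = roc_auc(y_true, scores)
    return counts, m, roc, area


def self_consistency(
    spec,
    dataset: LabeledDataset,
    cfg: TrainConfig = TrainConfig(),
    feature_config: FeatureConfig = DEFAULT_CONFIG,
) -> EvalReport:
    """Train and evaluate on the identical full dataset."""
    table = featurize_dataset(dataset, feature_config)
    scaled, _ = fit_apply_scaling(table)
    model = train(spec, scaled, cfg)
    scores = predict_proba(model, scaled)[:, 1]
    y_pred = predict_labels(model, scaled)
    counts, m, roc, area = _evaluate_predictions(scaled.labels, y_pred, scores)
    return EvalReport("self_consistency", counts, m["accuracy"], m["sensitivity"], m["specificity"], m["mcc"], area, roc, classifier=spec.name)


def independent_test(
    spec,
    dataset: LabeledDataset,
    split_spec: SplitSpec = SplitSpec(),
    cfg: TrainConfig = TrainConfig(),
    feature_config: FeatureConfig = DEFAULT_CONFIG,
) -> EvalReport:
    """Stratified hold-out evaluation; scaler and model see training rows only."""
    table = featurize_dataset(dataset, feature_config)
    train_idx, test_idx = stratified_split_indices(table.labels, split_spec)
    train_table = table.subset(train_idx)
    test_table = table.subset(test_idx)
    train_scaled, test_scaled, _ = fit_apply_scaling(train_table, test_table)
    model = train(spec, train_scaled, cfg)
    scores = predict_proba(model, test_scaled)[:, 1]
    y_pred = predict_labels(model, test_scaled)
    counts, m, roc, area = _evaluate_predictions(test_scaled.labels, y_pred, scores)
    return EvalReport("independent", counts, m["accuracy"], m["sensitivity"], m["specificity"], m["mcc"], area, roc, classifier=spec.name)


def five_fold_cv(
    spec,
    dataset: LabeledDataset,
    seed: int = 0,
    cfg: TrainConfig = TrainConfig(),
    feature_config: FeatureConfig = DEFAULT_CONFIG,
    n_folds: int = 5,
    aggregate: str = "mean",
) -> EvalReport:
    """Stratified k-fold cross-validation; every sample is tested exactly once.

    ``aggregate="mean"`` (default) averages each metric over folds;
    ``"pooled"`` computes the metrics once from the pooled confusion counts.
    The ROC attached to the report is built from the pooled out-of-fold
    scores either way.
    """
    if aggregate not in ("mean", "pooled"):
        raise ValueError(f"aggregate must be 'mean' or 'pooled', got {aggregate!r}")
    table = featurize_dataset(dataset, feature_config)
    labels = table.labels
    if labels is None:
        raise ValueError("cross-validation requires labels")
    pos, neg = int((labels == 1).sum()), int((labels == 0).sum())
    if min(pos, neg) < n_folds:
        raise ValueError(f"need at least {n_folds} samples per class, got {pos}+/{neg}-")

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_reports = []
    pooled = {"TP": 0, "TN": 0, "FP": 0, "FN": 0}
    all_scores = np.zeros(len(table))
    tested = np.zeros(len(table), dtype=bool)
    for fold_id, (tr, te) in enumerate(skf.split(table.X, labels)):
        train_scaled, test_scaled, _ = fit_apply_scaling(table.subset(tr), table.subset(te))
        model = train(spec, train_scaled, cfg)
        scores = predict_proba(model, test_scaled)[:, 1]
        y_pred = predict_labels(model, test_scaled)
        counts, m, _, area = _evaluate_predictions(test_scaled.labels, y_pred, scores)
        fold_reports.append({"fold": fold_id, "n_test": len(te), **m, "auc": area})
        for key, val in (("TP", counts.TP), ("TN", counts.TN), ("FP", counts.FP), ("FN", counts.FN)):
            pooled[key] += val
        all_scores[te] = scores
        tested[te] = True
    assert tested.all(), "every sample must be tested exactly once"

    pooled_counts = ConfusionCounts(**pooled)
    roc, pooled_auc = roc_auc(labels, all_scores)
    if aggregate == "mean":
        agg = {
            key: float(np.mean([f[key] for f in fold_reports]))
            for key in ("accuracy", "sensitivity", "specificity", "mcc", "auc")
        }
    else:
        agg = {**metrics(pooled_counts), "auc": pooled_auc}
    return EvalReport(
        "five_fold_cv",
        pooled_counts,
        agg["accuracy"],
        agg["sensitivity"],
        agg["specificity"],
        agg["mcc"],
        agg["auc"],
        roc,
        folds=fold_reports,
        classifier=spec.name,
    )
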