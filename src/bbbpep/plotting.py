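"""Plotting utilities: ROC overlays and violin plots of fold accuracies.

These are presentation helpers only; they read finished
:class:`~bbbpep.evaluation.EvalReport` objects and never alter the numbers.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt


def plot_roc(reports, ax=None):
    """Overlay the ROC curves of one or more evaluation reports."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    for report in reports:
        if report.roc_points is None:
            raise ValueError(f"report for {report.classifier!r} carries no ROC points")
        fpr, tpr, _ = report.roc_points
        label = f"{report.classifier or report.protocol} (AUC = {report.auc:.3f})"
        ax.plot(fpr, tpr, label=label)
    ax.plot([0, 1], [0, 1], linestyle="--", color="grey", linewidth=1)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.set_title("ROC")
    ax.legend(loc="lower right", fontsize=8)
    return ax


def plot_fold_accuracies(reports, metric: str = "accuracy", ax=None):
    """Violin plot of per-fold metric distributions of cross-validated reports."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    data, names = [], []
    for report in reports:
        if not report.folds:
            raise ValueError(f"report for {report.classifier!r} has no per-fold values")
        data.append([f[metric] for f in report.folds])
        names.append(report.classifier or report.protocol)
    ax.violinplot(data, showmeans=True)
    ax.set_xticks(range(1, len(names) + 1), names, rotation=30)
    ax.set_ylabel(metric)
    ax.set_title(f"Per-fold {metric}")
    return ax
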