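"""Classification metrics: AUC, AP, threshold metrics, fold aggregation.

AUC is the trapezoidal area under the ROC (ties get half credit,
equivalent to the Mann–Whitney pair-counting estimator); AP is the
step-interpolated area under the precision–recall curve.  Threshold
metrics use probability ≥ threshold → positive, with HGSOC (label 1)
as the positive class.  Fold results aggregate to mean ± standard
deviation; both the population (÷n) and sample (÷(n−1)) conventions
are reported.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.metrics import (average_precision_score, roc_auc_score, roc_curve)

__all__ = ["ScoredCohort", "MetricsReport", "AggregateReport", "roc_auc",
           "average_precision", "threshold_metrics", "aggregate", "export_roc"]

METRIC_NAMES = ("auc", "ap", "f1", "acc", "sen", "spec")


@dataclass
class ScoredCohort:
    """Per-patient predicted probabilities and true labels for one branch."""
    scores: np.ndarray
    labels: np.ndarray
    branch: str = "fused"

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float).ravel()
        self.labels = np.asarray(self.labels).ravel().astype(int)
        if self.scores.shape != self.labels.shape:
            raise ValueError("scores and labels differ in length")
        if self.scores.size == 0:
            raise ValueError("empty cohort")
        if np.any((self.scores < 0) | (self.scores > 1)):
            raise ValueError("probabilities must lie in [0, 1]")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be 0/1")


def roc_auc(cohort: ScoredCohort) -> float:
    """Area under the ROC curve (trapezoidal; ties half-credit)."""
    if len(np.unique(cohort.labels)) < 2:
        raise ValueError("AUC undefined: only one class present")
    return float(roc_auc_score(cohort.labels, cohort.scores))


def average_precision(cohort: ScoredCohort) -> float:
    """Step-interpolated average precision, Σ (R_k − R_{k−1})·P_k."""
    if cohort.labels.sum() == 0:
        raise ValueError("AP undefined: no positive samples")
    return float(average_precision_score(cohort.labels, cohort.scores))


@dataclass
class MetricsReport:
    auc: float
    ap: float
    f1: float
    acc: float
    sen: float
    spec: float
    threshold: float = 0.5
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRIC_NAMES}


def threshold_metrics(cohort: ScoredCohort, threshold: float = 0.5
                      ) -> MetricsReport:
    """Confusion-matrix metrics at a decision threshold.

    Positive prediction when probability ≥ threshold.  Sensitivity and
    specificity require at least one positive and one negative label.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    y, s = cohort.labels, cohort.scores
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0:
        raise ValueError("sensitivity undefined: no positive samples")
    if n_neg == 0:
        raise ValueError("specificity undefined: no negative samples")
    pred = (s >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    acc = (tp + tn) / y.size
    sen = tp / (tp + fn)
    spec = tn / (tn + fp)
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    f1 = (2 * precision * sen / (precision + sen)
          if precision + sen > 0 else 0.0)
    return MetricsReport(auc=roc_auc(cohort), ap=average_precision(cohort),
                         f1=f1, acc=acc, sen=sen, spec=spec,
                         threshold=threshold, tp=tp, fp=fp, tn=tn, fn=fn)


@dataclass
class AggregateReport:
    """Per-metric mean and standard deviation over cross-validation folds."""
    mean: dict[str, float]
    std_population: dict[str, float]
    std_sample: dict[str, float]
    n_folds: int = 0

    def summary(self) -> str:
        lines = []
        for m in METRIC_NAMES:
            lines.append(f"{m.upper():5s} {self.mean[m]:.4f} "
                         f"± {self.std_sample[m]:.4f}")
        return "\n".join(lines)


def aggregate(reports: list[MetricsReport]) -> AggregateReport:
    """Mean and std of each metric over ≥2 fold reports."""
    if len(reports) < 2:
        raise ValueError("aggregation needs at least two fold reports")
    out_mean, out_pop, out_samp = {}, {}, {}
    for m in METRIC_NAMES:
        vals = np.array([getattr(r, m) for r in reports], dtype=float)
        out_mean[m] = float(vals.mean())
        out_pop[m] = float(vals.std(ddof=0))
        out_samp[m] = float(vals.std(ddof=1))
    return AggregateReport(mean=out_mean, std_population=out_pop,
                           std_sample=out_samp, n_folds=len(reports))


def export_roc(cohort: ScoredCohort, path: str | Path,
               render_png: bool = True) -> None:
    """Write (FPR, TPR, threshold) triples as CSV, plus a rendered curve."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fpr, tpr, thr = roc_curve(cohort.labels, cohort.scores)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["fpr", "tpr", "threshold"])
        for f, t, h in zip(fpr, tpr, thr):
            w.writerow([f"{f:.10g}", f"{t:.10g}", f"{h:.10g}"])
    if render_png:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        auc = roc_auc(cohort)
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.plot(fpr, tpr, label=f"{cohort.branch} (AUC = {auc:.4f})")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("False positive rate")
        ax.set_ylabel("True positive rate")
        ax.legend(loc="lower right")
        fig.tight_layout()
        fig.savefig(path.with_suffix(".png"), dpi=120)
        plt.close(fig)
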