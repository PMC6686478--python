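"""Evaluation protocol: ROC/AUC, prevalence-cutoff classification,
per-class and averaged precision/recall/F1, bootstrap mean±std, and
AUC-comparison t-tests.

Classification uses a fixed score cutoff equal to the positive-pair rate
of the whole dataset (scores strictly above the cutoff are positive); a
quantile variant (label the top fraction positive) is available because
cosine-style scores are not probabilities. Averaged metrics are reported
under two schemes: support-weighted (each class weighted by its true
count, so weighted recall equals accuracy) and unweighted macro (plain
mean of the two classes).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import UndefinedMetricError

__all__ = [
    "ScoredPair",
    "MetricsReport",
    "BootstrapConfig",
    "roc_auc",
    "classify_at_cutoff",
    "metrics",
    "bootstrap_metrics",
    "compare_auc_ttest",
    "roc_points",
    "write_roc",
]

DEFAULT_CUTOFF = 0.148  # positive-pair rate of the reference corpus


@dataclass(frozen=True)
class ScoredPair:
    pair_id: str
    score: float
    label: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.score):
            raise ValueError(f"score must be finite, got {self.score}")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0/1, got {self.label}")


def _as_arrays(scored: Sequence[ScoredPair]) -> tuple[np.ndarray, np.ndarray]:
    scores = np.array([s.score for s in scored], dtype=np.float64)
    labels = np.array([s.label for s in scored], dtype=np.int64)
    return scores, labels


@dataclass
class MetricsReport:
    cutoff: float = float("nan")
    auc: float = float("nan")
    precision_pos: float = float("nan")
    recall_pos: float = float("nan")
    f1_pos: float = float("nan")
    precision_neg: float = float("nan")
    recall_neg: float = float("nan")
    f1_neg: float = float("nan")
    precision_weighted: float = float("nan")
    recall_weighted: float = float("nan")
    f1_weighted: float = float("nan")
    precision_macro: float = float("nan")
    recall_macro: float = float("nan")
    f1_macro: float = float("nan")
    std: dict[str, float] = field(default_factory=dict)

    _METRIC_FIELDS = (
        "auc",
        "precision_pos",
        "recall_pos",
        "f1_pos",
        "precision_neg",
        "recall_neg",
        "f1_neg",
        "precision_weighted",
        "recall_weighted",
        "f1_weighted",
        "precision_macro",
        "recall_macro",
        "f1_macro",
    )

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(asdict(self), indent=1, allow_nan=True)
        if path is not None:
            Path(path).write_text(payload, encoding="utf-8")
        return payload


def roc_auc(scored: Sequence[ScoredPair]) -> float:
    """AUROC as the Mann-Whitney concordance probability.

    Equals (#{positive outscores negative} + 0.5 * #ties) / (N+ * N-),
    computed via midranks so ties get half credit.
    """
    scores, labels = _as_arrays(scored)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC is undefined when only one class is present")
    ranks = stats.rankdata(scores)  # midranks
    rank_sum_pos = ranks[labels == 1].sum()
    return float((rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def classify_at_cutoff(
    scored: Sequence[ScoredPair], cutoff: float = DEFAULT_CUTOFF, quantile: bool = False
) -> np.ndarray:
    """Predicted labels: 1 iff score strictly above the cutoff.

    With ``quantile=True`` the cutoff is instead read as a positive
    fraction r and the numeric threshold becomes the (1-r) score quantile.
    """
    scores, _ = _as_arrays(scored)
    if quantile:
        if not 0.0 <= cutoff <= 1.0:
            raise ValueError("quantile cutoff must be in [0,1]")
        threshold = float(np.quantile(scores, 1.0 - cutoff)) if len(scores) else 0.0
    else:
        threshold = cutoff
    if not np.isfinite(threshold) and threshold == -np.inf:
        return np.ones(len(scores), dtype=np.int64)
    return (scores > threshold).astype(np.int64)


def _prf(predicted: np.ndarray, true: np.ndarray, positive: int) -> tuple[float, float, float]:
    tp = int(np.sum((predicted == positive) & (true == positive)))
    fp = int(np.sum((predicted == positive) & (true != positive)))
    fn = int(np.sum((predicted != positive) & (true == positive)))
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    return precision, recall, f1


def metrics(
    predicted: Sequence[int] | np.ndarray,
    true: Sequence[int] | np.ndarray,
    cutoff: float = float("nan"),
) -> MetricsReport:
    """Per-class and averaged precision/recall/F1 (0/0 counted as 0)."""
    predicted = np.asarray(predicted, dtype=np.int64)
    true = np.asarray(true, dtype=np.int64)
    if predicted.shape != true.shape:
        raise ValueError(f"length mismatch: {predicted.shape} vs {true.shape}")
    if len(set(true.tolist())) < 2:
        raise ValueError("true labels must contain both classes")
    p_pos, r_pos, f_pos = _prf(predicted, true, 1)
    p_neg, r_neg, f_neg = _prf(predicted, true, 0)
    n_pos = int(true.sum())
    n_neg = len(true) - n_pos
    w_pos, w_neg = n_pos / len(true), n_neg / len(true)
    return MetricsReport(
        cutoff=cutoff,
        precision_pos=p_pos,
        recall_pos=r_pos,
        f1_pos=f_pos,
        precision_neg=p_neg,
        recall_neg=r_neg,
        f1_neg=f_neg,
        precision_weighted=w_pos * p_pos + w_neg * p_neg,
        recall_weighted=w_pos * r_pos + w_neg * r_neg,
        f1_weighted=w_pos * f_pos + w_neg * f_neg,
        precision_macro=(p_pos + p_neg) / 2,
        recall_macro=(r_pos + r_neg) / 2,
        f1_macro=(f_pos + f_neg) / 2,
    )


@dataclass(frozen=True)
class BootstrapConfig:
    n_resamples: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")


def bootstrap_metrics(
    scored: Sequence[ScoredPair],
    cutoff: float = DEFAULT_CUTOFF,
    config: BootstrapConfig = BootstrapConfig(),
    quantile: bool = False,
) -> MetricsReport:
    """Mean ± std of every metric over size-preserving resamples.

    Resamples the scored test set with replacement (the fitted model is
    not retrained); a resample missing one of the classes is redrawn.
    """
    scores, labels = _as_arrays(scored)
    if len(set(labels.tolist())) < 2:
        raise UndefinedMetricError("bootstrap requires both classes present")
    rng = np.random.default_rng(config.seed)
    n = len(scored)
    per_metric: dict[str, list[float]] = {k: [] for k in MetricsReport._METRIC_FIELDS}
    for _ in range(config.n_resamples):
        for _attempt in range(1000):
            idx = rng.integers(n, size=n)
            if len(set(labels[idx].tolist())) == 2:
                break
        sample = [scored[i] for i in idx]
        rep = metrics(classify_at_cutoff(sample, cutoff, quantile), labels[idx], cutoff)
        rep.auc = roc_auc(sample)
        for k in per_metric:
            per_metric[k].append(getattr(rep, k))
    out = MetricsReport(cutoff=cutoff)
    for k, vals in per_metric.items():
        arr = np.asarray(vals)
        setattr(out, k, float(arr.mean()))
        out.std[k] = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return out


def compare_auc_ttest(aucs_a: Sequence[float], aucs_b: Sequence[float]) -> float:
    """Two-sided Welch t-test p-value between two AUC samples.

    The samples are meant to come from independent training runs (e.g. 50
    seeds per initialization strategy). Two degenerate equal-mean
    zero-variance samples give p = 1 by convention.
    """
    a = np.asarray(aucs_a, dtype=np.float64)
    b = np.asarray(aucs_b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each AUC list needs at least 2 values")
    if a.std() == 0.0 and b.std() == 0.0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def roc_points(scored: Sequence[ScoredPair]) -> list[tuple[float, float, float]]:
    """(threshold, FPR, TPR) staircase over sorted unique thresholds.

    Starts at (+inf, 0, 0) and ends at (min score, 1, 1); the trapezoidal
    integral of the curve equals :func:`roc_auc`.
    """
    scores, labels = _as_arrays(scored)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("ROC is undefined when only one class is present")
    order = np.argsort(-scores, kind="mergesort")
    scores, labels = scores[order], labels[order]
    points: list[tuple[float, float, float]] = [(float("inf"), 0.0, 0.0)]
    tp = fp = 0
    for i in range(len(scores)):
        if labels[i] == 1:
            tp += 1
        else:
            fp += 1
        if i == len(scores) - 1 or scores[i + 1] != scores[i]:
            points.append((float(scores[i]), fp / n_neg, tp / n_pos))
    return points


def write_roc(points: Sequence[tuple[float, float, float]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["threshold", "fpr", "tpr"])
        for thr, fpr, tpr in points:
            writer.writerow([thr, fpr, tpr])
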