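"""Confusion metrics, AUROC, AUPR, and the three aggregation protocols.

Multi-drug / multi-disease predictions can be evaluated three ways:

* **global** — pool the scores of every (drug, disease) pair into one vector
  and compute each metric once;
* **drug-centric** — compute each metric per drug, then average (unweighted)
  over drugs;
* **disease-centric** — compute each metric per disease, then average over
  diseases.

Per-entity metrics that are undefined (an entity whose labels are all one
class) are skipped and counted, never silently imputed.  Entity averages are
reported as mean +/- population sd (divisor n).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from cpirank.io import IndicationLabels

if TYPE_CHECKING:  # pragma: no cover
    from cpirank.classifier import PredictionSet

__all__ = [
    "ConfusionMetrics",
    "MetricSummary",
    "MetricReport",
    "confusion_metrics",
    "auroc",
    "aupr",
    "aggregate",
]


@dataclass(frozen=True)
class ConfusionMetrics:
    """Threshold metrics; undefined entries are NaN and listed in ``undefined``."""

    accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    undefined: frozenset[str] = frozenset()

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


@dataclass(frozen=True)
class MetricSummary:
    mean: float
    sd: float | None = None


@dataclass
class MetricReport:
    """Metrics under one aggregation mode.

    For entity-averaged (centric) or repeated modes each entry carries a mean
    and sd; single-shot global metrics have ``sd=None``.
    """

    mode: str
    metrics: dict[str, MetricSummary] = field(default_factory=dict)
    n_entities_evaluated: int = 0
    n_entities_skipped: int = 0

    def __getitem__(self, name: str) -> MetricSummary:
        return self.metrics[name]


def confusion_metrics(
    scores: np.ndarray,
    y: np.ndarray,
    threshold: float | None,
    predictions: np.ndarray | None = None,
) -> ConfusionMetrics:
    """Accuracy, precision, sensitivity, specificity at a threshold.

    Positive prediction iff ``score >= threshold`` (inclusive).  A
    precomputed boolean ``predictions`` vector may be given instead of a
    threshold.  Undefined metrics (no positives -> sensitivity; no predicted
    positives -> precision; no negatives -> specificity) come back as NaN,
    flagged in ``undefined``.
    """
    y = np.asarray(y, dtype=int)
    if predictions is None:
        if threshold is None:
            raise ValueError("either threshold or predictions must be given")
        scores = np.asarray(scores, dtype=float)
        if scores.shape != y.shape:
            raise ValueError("scores and y must have the same length")
        predictions = scores >= threshold
    else:
        predictions = np.asarray(predictions, dtype=bool)
        if predictions.shape != y.shape:
            raise ValueError("predictions and y must have the same length")

    tp = int(np.sum(predictions & (y == 1)))
    fp = int(np.sum(predictions & (y == 0)))
    fn = int(np.sum(~predictions & (y == 1)))
    tn = int(np.sum(~predictions & (y == 0)))

    undefined: set[str] = set()
    accuracy = (tp + tn) / y.size
    if tp + fp == 0:
        precision = float("nan")
        undefined.add("precision")
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        sensitivity = float("nan")
        undefined.add("sensitivity")
    else:
        sensitivity = tp / (tp + fn)
    if tn + fp == 0:
        specificity = float("nan")
        undefined.add("specificity")
    else:
        specificity = tn / (tn + fp)
    return ConfusionMetrics(accuracy, precision, sensitivity, specificity, frozenset(undefined))


def auroc(scores: np.ndarray, y: np.ndarray) -> float:
    """Area under the ROC curve.

    Equals the Mann-Whitney pairwise statistic
    ``P(score_pos > score_neg) + 0.5 * P(tie)``.  Raises ``ValueError`` on a
    single-class label vector.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    mask = np.isfinite(scores)
    scores, y = scores[mask], y[mask]
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("AUROC undefined for single-class labels")
    return float(roc_auc_score(y, scores))


def aupr(scores: np.ndarray, y: np.ndarray) -> float:
    """Area under the precision-recall curve, average-precision form.

    Step-wise sum of precision x recall increments (no linear interpolation,
    which is optimistically biased).  Raises ``ValueError`` with no positives.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    mask = np.isfinite(scores)
    scores, y = scores[mask], y[mask]
    if y.sum() == 0:
        raise ValueError("AUPR undefined with no positive labels")
    return float(average_precision_score(y, scores))


_METRIC_FNS = {"auroc": auroc, "aupr": aupr}


def _entity_metrics(
    s: np.ndarray, yv: np.ndarray, threshold: float
) -> dict[str, float] | None:
    """All metrics for one entity, or None when ranking metrics are undefined."""
    if yv.sum() == 0 or yv.sum() == yv.size:
        return None
    out = {"auroc": auroc(s, yv), "aupr": aupr(s, yv)}
    cm = confusion_metrics(s, yv, threshold)
    out.update(cm.as_dict())
    return out


def aggregate(
    preds: "PredictionSet",
    labels: IndicationLabels,
    mode: str = "global",
    threshold: float | str = "max_f",
) -> MetricReport:
    """Evaluate a prediction matrix under one aggregation protocol.

    ``threshold`` is either a number or ``"max_f"``, in which case the max-F
    threshold is selected once on the pooled scores and applied everywhere
    (the operating point is a global property of the score scale).  Entities
    whose labels are single-class are skipped and counted in
    ``n_entities_skipped``.  Raises ``ValueError`` when nothing is evaluable.
    """
    from cpirank.classifier import select_threshold  # local to avoid cycle

    if mode not in ("global", "drug_centric", "disease_centric"):
        raise ValueError(f"unknown aggregation mode {mode!r}")
    S = preds.scores
    Y = np.column_stack(
        [labels.label_vector(preds.drug_ids, labels.positives_for(c)) for c in preds.endpoint_codes]
    )
    pooled_s, pooled_y = S.ravel(), Y.ravel()
    finite = np.isfinite(pooled_s)
    if threshold == "max_f":
        threshold = select_threshold(pooled_s[finite], pooled_y[finite])
    threshold = float(threshold)

    if mode == "global":
        m = _entity_metrics(pooled_s[finite], pooled_y[finite], threshold)
        if m is None:
            raise ValueError("pooled labels are single-class; nothing to evaluate")
        return MetricReport(
            mode=mode,
            metrics={k: MetricSummary(mean=v) for k, v in m.items()},
            n_entities_evaluated=1,
            n_entities_skipped=0,
        )

    axis_entities = range(S.shape[0]) if mode == "drug_centric" else range(S.shape[1])
    collected: dict[str, list[float]] = {}
    skipped = 0
    for i in axis_entities:
        s = S[i, :] if mode == "drug_centric" else S[:, i]
        yv = Y[i, :] if mode == "drug_centric" else Y[:, i]
        ok = np.isfinite(s)
        m = _entity_metrics(s[ok], yv[ok], threshold)
        if m is None:
            skipped += 1
            continue
        for k, v in m.items():
            collected.setdefault(k, []).append(v)
    n_eval = len(next(iter(collected.values()), []))
    if n_eval == 0:
        raise ValueError(
            f"every entity is single-class under {mode}; skipped {skipped}"
        )
    metrics = {
        k: MetricSummary(mean=float(np.nanmean(v)), sd=float(np.nanstd(v)))
        for k, v in collected.items()
    }
    return MetricReport(
        mode=mode,
        metrics=metrics,
        n_entities_evaluated=n_eval,
        n_entities_skipped=skipped,
    )
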