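"""Per-endpoint regularized logistic classifiers on CPI features.

One binary classifier is trained per endpoint (disease code or disease
family) on the drug x target docking-score matrix, with L2 regularization to
keep the 600-odd-feature models from overfitting the small positive classes.
Features are z-scored per target on each training split: docking scores share
units (kcal/mol) but their location differs per target pocket, and penalized
models need comparable scales.

Evaluation follows repeated k-fold cross-validation: per repeat, one random
drug-level partition shared by every endpoint (required for the merged
"global" metrics to be well defined), each endpoint model trained on k-1
folds and scored on the held-out fold.  The operating threshold is the one
maximizing the F-score on the pooled out-of-fold scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression

from cpirank.evaluation import MetricReport, MetricSummary, aupr, auroc, confusion_metrics
from cpirank.icd9 import EndpointSet
from cpirank.io import CPIMatrix, IndicationLabels

__all__ = [
    "EndpointModel",
    "PredictionSet",
    "fit_endpoint_model",
    "predict_scores",
    "cross_validate",
    "select_threshold",
]

logger = logging.getLogger(__name__)

OPTIMIZER_TOL = 1e-8
OPTIMIZER_MAX_ITER = 1000


@dataclass
class EndpointModel:
    """A fitted linear probabilistic classifier for one endpoint.

    ``weights`` align with the target panel the model was trained on;
    ``feature_means``/``feature_sds`` hold the training-split z-scoring
    parameters (zero-variance targets get sd sentinel 1 and weight 0).
    A constant (prevalence) model is encoded as all-zero weights with
    ``intercept = logit(prevalence)``.
    """

    endpoint_code: str
    weights: np.ndarray
    intercept: float
    feature_means: np.ndarray
    feature_sds: np.ndarray
    reg_strength: float
    threshold: float | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.feature_means = np.asarray(self.feature_means, dtype=float)
        self.feature_sds = np.asarray(self.feature_sds, dtype=float)
        n = self.weights.shape[0]
        if self.feature_means.shape != (n,) or self.feature_sds.shape != (n,):
            raise ValueError("standardization parameter length does not match weights")
        if np.any(self.feature_sds <= 0):
            raise ValueError("feature_sds must be positive (sentinel 1 for zero variance)")

    @property
    def n_features(self) -> int:
        return self.weights.shape[0]


@dataclass
class PredictionSet:
    """A drug x endpoint matrix of probabilistic scores in [0, 1].

    ``NaN`` cells are explicitly unscored (e.g. a drug outside every fold's
    test set).  ``provenance`` records where the scores came from, e.g.
    ``{"cv_repeat_index": 3, "fold_map": {...}}`` or ``{"holdout": True}``.
    """

    drug_ids: list[str]
    endpoint_codes: list[str]
    scores: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.drug_ids), len(self.endpoint_codes)):
            raise ValueError("score matrix shape does not match id lists")
        finite = self.scores[np.isfinite(self.scores)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("scores must lie in [0, 1]")


def _standardize_params(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    sds = np.where(sds > 0, sds, 1.0)  # zero-variance sentinel
    return means, sds


def fit_endpoint_model(
    X: np.ndarray,
    y: np.ndarray,
    reg_strength: float = 1.0,
    endpoint_code: str = "",
) -> EndpointModel:
    """Fit an L2-regularized logistic model for one endpoint.

    ``reg_strength`` is the inverse penalty (scikit-learn's ``C``).  The fit
    is deterministic given identical input.  Raises ``ValueError`` when ``y``
    is single-class or a feature is non-finite.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X rows must align with y")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature value in X")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("y contains a single class; cannot fit a classifier")
    if reg_strength <= 0:
        raise ValueError("reg_strength must be positive")

    means, sds = _standardize_params(X)
    Z = (X - means) / sds
    clf = LogisticRegression(
        C=reg_strength,  # L2 penalty (the estimator's default)
        solver="lbfgs",
        tol=OPTIMIZER_TOL,
        max_iter=OPTIMIZER_MAX_ITER,
    )
    clf.fit(Z, y)
    return EndpointModel(
        endpoint_code=endpoint_code,
        weights=clf.coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        feature_means=means,
        feature_sds=sds,
        reg_strength=reg_strength,
    )


def _constant_model(prevalence: float, n_features: int, endpoint_code: str, reg_strength: float) -> EndpointModel:
    p = min(max(prevalence, 1e-9), 1 - 1e-9)
    return EndpointModel(
        endpoint_code=endpoint_code,
        weights=np.zeros(n_features),
        intercept=float(np.log(p / (1 - p))),
        feature_means=np.zeros(n_features),
        feature_sds=np.ones(n_features),
        reg_strength=reg_strength,
    )


def predict_scores(model: EndpointModel, X: np.ndarray) -> np.ndarray:
    """Logistic link applied to the stored standardization and weights."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature count {X.shape[1]} does not match model ({model.n_features})"
        )
    Z = (X - model.feature_means) / model.feature_sds
    eta = Z @ model.weights + model.intercept
    return 1.0 / (1.0 + np.exp(-eta))


def select_threshold(scores: np.ndarray, y: np.ndarray) -> float:
    """Smallest candidate threshold attaining the maximal F-score.

    Candidates are the midpoints between consecutive sorted unique scores plus
    a sentinel below the minimum (predict everything positive) and one above
    the maximum (predict nothing).  Prediction is positive iff
    ``score >= threshold``; F ties break toward the smaller threshold (higher
    sensitivity).  Raises ``ValueError`` when ``y`` has no positives.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    if scores.shape != y.shape:
        raise ValueError("scores and y must have the same length")
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("no positive labels; F-score undefined")

    u = np.unique(scores)
    low = u[0] - 0.5 * (u[-1] - u[0]) if u.size > 1 else u[0] - 0.5
    high = u[-1] + 0.5 * (u[-1] - u[0]) if u.size > 1 else u[-1] + 0.5
    candidates = np.concatenate(([low], (u[:-1] + u[1:]) / 2.0, [high]))

    best_t = candidates[0]
    best_f = -1.0
    for t in candidates:
        pred = scores >= t
        tp = int(np.sum(pred & (y == 1)))
        fp = int(np.sum(pred & (y == 0)))
        fn = n_pos - tp
        # single-ratio form keeps exact ties exact in floating point
        f = 0.0 if tp == 0 else 2 * tp / (2 * tp + fp + fn)
        if f > best_f:  # strict: earlier (smaller) candidate wins ties
            best_f = f
            best_t = t
    return float(best_t)


def _partition(n: int, k: int, rng: np.random.Generator, strata: np.ndarray | None = None) -> np.ndarray:
    """Assign each of n items a fold in 0..k-1, sizes differing by <= 1.

    With ``strata`` given (binary), each class is spread round-robin over a
    random fold order so positives land as evenly as possible.
    """
    fold = np.empty(n, dtype=int)
    if strata is None:
        perm = rng.permutation(n)
        for pos, idx in enumerate(perm):
            fold[idx] = pos % k
    else:
        for cls in np.unique(strata):
            members = np.flatnonzero(strata == cls)
            members = members[rng.permutation(members.size)]
            offset = int(rng.integers(k))
            for pos, idx in enumerate(members):
                fold[idx] = (pos + offset) % k
    return fold


def cross_validate(
    cpi: CPIMatrix,
    labels: IndicationLabels,
    endpoints: EndpointSet,
    k: int = 10,
    repeats: int = 100,
    reg_strength: float = 1.0,
    seed: int = 0,
    stratify_code: str | None = None,
    threshold_mode: str = "global",
) -> tuple[list[PredictionSet], MetricReport]:
    """Repeated k-fold cross-validation of all endpoint models.

    Per repeat, a single drug-level partition (sizes differing by at most 1)
    is shared across endpoints; each endpoint's model is trained on k-1 folds
    and scored on the held-out fold, yielding one out-of-fold score matrix per
    repeat.  Global AUROC/AUPR and the max-F confusion metrics are computed on
    the pooled scores of each repeat and summarized as mean +/- sd (population
    sd) over repeats.

    A training split with fewer than 2 positives or 2 negatives for some
    endpoint degrades to a constant model predicting the training prevalence
    (logged); with 5-positive endpoints under 10-fold CV this is unavoidable.

    ``threshold_mode="global"`` selects one max-F threshold on the pooled
    scores per repeat; ``"per_endpoint"`` selects one per endpoint column.
    All randomness derives from ``seed`` via per-repeat child seeds.
    """
    n = cpi.n_drugs
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of drugs ({n})")
    if threshold_mode not in ("global", "per_endpoint"):
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")
    codes = endpoints.codes
    if not codes:
        raise ValueError("empty endpoint set")

    # label matrix, drugs x endpoints
    Y = np.column_stack(
        [labels.label_vector(cpi.drug_ids, endpoints.endpoints[c]) for c in codes]
    )
    strata = Y[:, codes.index(stratify_code)] if stratify_code is not None else None

    prediction_sets: list[PredictionSet] = []
    per_repeat: dict[str, list[float]] = {
        m: [] for m in ("auroc", "aupr", "accuracy", "precision", "sensitivity", "specificity", "threshold")
    }

    for rep in range(repeats):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), rep]))
        fold = _partition(n, k, rng, strata)
        oof = np.full((n, len(codes)), np.nan)

        for f in range(k):
            test = fold == f
            train = ~test
            Xtr, Xte = cpi.scores[train], cpi.scores[test]
            means, sds = _standardize_params(Xtr)
            Ztr = (Xtr - means) / sds
            Zte = (Xte - means) / sds
            for j, code in enumerate(codes):
                ytr = Y[train, j]
                n_pos = int(ytr.sum())
                n_neg = ytr.size - n_pos
                if n_pos < 2 or n_neg < 2:
                    prev = min(max(n_pos / ytr.size, 1e-9), 1 - 1e-9)
                    logger.info(
                        "repeat %d fold %d endpoint %s: %d positives in training "
                        "split; using constant prevalence model", rep, f, code, n_pos
                    )
                    oof[test, j] = prev
                    continue
                clf = LogisticRegression(
                    C=reg_strength,
                    solver="lbfgs",
                    tol=OPTIMIZER_TOL,
                    max_iter=OPTIMIZER_MAX_ITER,
                )
                clf.fit(Ztr, ytr)
                oof[test, j] = clf.predict_proba(Zte)[:, 1]

        prediction_sets.append(
            PredictionSet(
                drug_ids=list(cpi.drug_ids),
                endpoint_codes=list(codes),
                scores=oof,
                provenance={
                    "cv_repeat_index": rep,
                    "fold_map": {d: int(fold[i]) for i, d in enumerate(cpi.drug_ids)},
                },
            )
        )

        pooled_s = oof.ravel()
        pooled_y = Y.ravel()
        per_repeat["auroc"].append(auroc(pooled_s, pooled_y))
        per_repeat["aupr"].append(aupr(pooled_s, pooled_y))
        if threshold_mode == "global":
            t = select_threshold(pooled_s, pooled_y)
            pred = pooled_s >= t
        else:
            thresholds = np.array(
                [select_threshold(oof[:, j], Y[:, j]) if Y[:, j].any() else np.inf for j in range(len(codes))]
            )
            pred = (oof >= thresholds).ravel()
            t = float(np.mean(thresholds[np.isfinite(thresholds)]))
        cm = confusion_metrics(pooled_s, pooled_y, threshold=None, predictions=pred)
        per_repeat["threshold"].append(t)
        per_repeat["accuracy"].append(cm.accuracy)
        per_repeat["precision"].append(cm.precision)
        per_repeat["sensitivity"].append(cm.sensitivity)
        per_repeat["specificity"].append(cm.specificity)

    summaries = {
        name: MetricSummary(mean=float(np.mean(vals)), sd=float(np.std(vals)))
        for name, vals in per_repeat.items()
    }
    report = MetricReport(
        mode="global",
        metrics=summaries,
        n_entities_evaluated=1,
        n_entities_skipped=0,
    )
    return prediction_sets, report
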