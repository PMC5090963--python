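"""Empirical-Bayes normalization of per-endpoint prediction scores.

Raw per-endpoint classifier scores for one drug are not comparable across
endpoints: each endpoint model has its own prevalence and score scale.  To
rank indications within a drug, partition the training diseases into Group 1
(treated by the drug) and Group 0 (not treated), and report the posterior
probability that a disease with raw score ``y`` belongs to Group 1:

    P(G1 | y) = P(y | G1) P(G1) / (P(y | G1) P(G1) + P(y | G0) P(G0))

The priors are the empirical group proportions and the likelihoods are
density estimates of each group's raw scores.  Densities default to Gaussian
KDE with Silverman bandwidth; a group with fewer than 5 samples falls back to
a single Gaussian at the group mean with a bandwidth pooled over both groups
(per-drug Group-1 samples are often tiny, so a hard small-sample policy is
mandatory).  Distributions may be fitted per training drug or pooled over all
training (drug, disease) pairs; pooled is the default for drugs never seen in
training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Callable

import numpy as np
from scipy import stats

from cpirank.io import IndicationLabels

if TYPE_CHECKING:  # pragma: no cover
    from cpirank.classifier import PredictionSet

__all__ = ["EBDistributions", "fit_eb", "fit_eb_from_predictions", "normalize", "normalize_profile"]

DENSITY_FLOOR = 1e-12
KDE_MIN_SAMPLES = 5
_SILVERMAN = (4.0 / 3.0) ** 0.2


@dataclass
class EBDistributions:
    """Priors and score-density estimators for the two groups.

    ``density_g1``/``density_g0`` are callables evaluable at any point of
    [0, 1] (and beyond: KDE tails are used directly, never clipped).
    """

    prior_g1: float
    density_g1: Callable[[np.ndarray], np.ndarray]
    density_g0: Callable[[np.ndarray], np.ndarray]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.prior_g1 <= 1.0:
            raise ValueError("prior_g1 must lie in [0, 1]")

    @property
    def prior_g0(self) -> float:
        return 1.0 - self.prior_g1


def _pooled_bandwidth(all_scores: np.ndarray) -> float:
    n = all_scores.size
    sd = float(np.std(all_scores, ddof=1)) if n > 1 else 0.0
    h = _SILVERMAN * sd * n ** (-0.2) if sd > 0 else 0.0
    return max(h, 1e-3)


def _density_estimator(samples: np.ndarray, pooled_h: float) -> Callable[[np.ndarray], np.ndarray]:
    samples = np.asarray(samples, dtype=float)
    if samples.size >= KDE_MIN_SAMPLES and np.std(samples) > 0:
        kde = stats.gaussian_kde(samples, bw_method="silverman")
        return lambda y: np.asarray(kde(np.atleast_1d(y)))
    # small-sample / degenerate fallback: one Gaussian at the group mean
    mu = float(samples.mean())
    return lambda y: stats.norm.pdf(np.atleast_1d(y), loc=mu, scale=pooled_h)


def fit_eb(
    scores_g1: np.ndarray,
    scores_g0: np.ndarray,
    prior_g1: float,
    provenance: dict | None = None,
) -> EBDistributions:
    """Fit group priors and score densities from empirical score samples.

    Raises ``ValueError`` on an empty group (no fallback can be anchored) or
    a prior outside (0, 1).
    """
    scores_g1 = np.asarray(scores_g1, dtype=float).ravel()
    scores_g0 = np.asarray(scores_g0, dtype=float).ravel()
    if scores_g1.size == 0:
        raise ValueError("empty Group-1 score sample; cannot fit a density")
    if scores_g0.size == 0:
        raise ValueError("empty Group-0 score sample; cannot fit a density")
    if not 0.0 < prior_g1 < 1.0:
        raise ValueError(f"prior_g1 must lie in (0, 1), got {prior_g1}")
    pooled_h = _pooled_bandwidth(np.concatenate([scores_g1, scores_g0]))
    return EBDistributions(
        prior_g1=float(prior_g1),
        density_g1=_density_estimator(scores_g1, pooled_h),
        density_g0=_density_estimator(scores_g0, pooled_h),
        provenance=provenance or {},
    )


def fit_eb_from_predictions(
    preds: "PredictionSet",
    labels: IndicationLabels,
    drug_id: str | None = None,
) -> EBDistributions:
    """Fit EB distributions from a training score matrix and its labels.

    ``drug_id=None`` pools all finite (drug, disease) score cells split by
    label, priors = pooled label prevalence; giving a training ``drug_id``
    restricts to that drug's row (its endpoints split by its own labels).
    """
    S = preds.scores
    Y = np.column_stack(
        [labels.label_vector(preds.drug_ids, labels.positives_for(c)) for c in preds.endpoint_codes]
    )
    if drug_id is not None:
        try:
            i = preds.drug_ids.index(drug_id)
        except ValueError:
            raise KeyError(f"drug {drug_id!r} not in the prediction set") from None
        S, Y = S[i : i + 1], Y[i : i + 1]
    s, yv = S.ravel(), Y.ravel()
    ok = np.isfinite(s)
    s, yv = s[ok], yv[ok]
    g1, g0 = s[yv == 1], s[yv == 0]
    if g1.size == 0 or g0.size == 0:
        who = "Group 1" if g1.size == 0 else "Group 0"
        raise ValueError(
            f"{who} is empty for {'drug ' + drug_id if drug_id else 'the pooled set'}; "
            "cannot fit per-drug distributions (use pooled mode)"
        )
    prior = g1.size / s.size
    return fit_eb(
        g1, g0, prior,
        provenance={"per_drug": drug_id} if drug_id else {"pooled": True},
    )


def normalize(eb: EBDistributions, y_j: float) -> float:
    """Posterior confidence P(G1 | y_j) via Bayes' rule.

    Both densities are floored at 1e-12 before forming the ratio; when both
    land on the floor the posterior collapses to the prior (warned).
    """
    d1 = float(np.asarray(eb.density_g1(y_j)).ravel()[0])
    d0 = float(np.asarray(eb.density_g0(y_j)).ravel()[0])
    if d1 <= DENSITY_FLOOR and d0 <= DENSITY_FLOOR:
        warnings.warn(
            f"both group densities at the floor for y={y_j}; returning the prior"
        )
        return eb.prior_g1
    d1 = max(d1, DENSITY_FLOOR)
    d0 = max(d0, DENSITY_FLOOR)
    num = d1 * eb.prior_g1
    return num / (num + d0 * eb.prior_g0)


def normalize_profile(raw_scores: np.ndarray, eb: EBDistributions) -> np.ndarray:
    """Element-wise posterior confidences, preserving endpoint order."""
    raw = np.asarray(raw_scores, dtype=float).ravel()
    return np.array([normalize(eb, float(y)) for y in raw])
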