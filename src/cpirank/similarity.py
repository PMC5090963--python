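"""Tanimoto similarity on binary fingerprints and the train/validation leakage filter.

A validation drug structurally near-identical to a training drug inflates
apparent generalization; the filter removes any validation drug whose maximum
Tanimoto similarity to the training set strictly exceeds the cutoff
(default 0.7).  The filter is fingerprint-agnostic: which fingerprint family
(ECFP, MACCS, ...) the bitsets come from is the caller's choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from cpirank.io import FingerprintSet

__all__ = ["tanimoto", "filter_leakage", "LeakageRecord"]

DEFAULT_CUTOFF = 0.7


def tanimoto(a: frozenset[int] | set[int], b: frozenset[int] | set[int]) -> float:
    """|A n B| / |A u B| on on-bit index sets; both-empty -> 0.0 (warned)."""
    union = len(a | b)
    if union == 0:
        warnings.warn("Tanimoto of two empty fingerprints is 0/0; returning 0.0")
        return 0.0
    return len(a & b) / union


@dataclass(frozen=True)
class LeakageRecord:
    """A removed validation drug with its nearest training neighbour."""

    drug_id: str
    max_similarity: float
    nearest_training_drug: str


def filter_leakage(
    validation_ids: set[str] | list[str],
    training_ids: set[str] | list[str],
    fps: FingerprintSet,
    cutoff: float = DEFAULT_CUTOFF,
) -> tuple[list[str], list[LeakageRecord]]:
    """Remove validation drugs too similar to any training drug.

    A validation drug is removed iff its maximum Tanimoto similarity over the
    training set is strictly greater than ``cutoff`` (a drug at exactly the
    cutoff is retained).  An empty training set removes nothing.  Returns
    (sorted retained ids, removal records sorted by drug id).  Raises
    ``KeyError`` for any listed drug without a fingerprint.
    """
    validation = sorted(set(validation_ids))
    training = sorted(set(training_ids))
    for d in validation + training:
        if d not in fps:
            raise KeyError(f"no fingerprint for drug {d!r}")

    retained: list[str] = []
    removed: list[LeakageRecord] = []
    for v in validation:
        best_sim, best_train = -1.0, None
        for t in training:
            s = tanimoto(fps[v], fps[t])
            if s > best_sim or (s == best_sim and best_train is not None and t < best_train):
                best_sim, best_train = s, t
        if best_train is not None and best_sim > cutoff:
            removed.append(LeakageRecord(v, best_sim, best_train))
        else:
            retained.append(v)
    return retained, removed
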