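"""Scoring new drugs with two-tier models and hierarchical ranked reports.

Predictions run at two independent tiers: individual ICD-9 disease models and
3-digit disease-family models.  A family's confidence comes from the
family-level model, never from aggregating its members -- the two tiers can
legitimately disagree (a family model may score higher than every member),
and the report carries both without reconciliation.  The report groups member
diseases under their families, ranks families by family-tier confidence
(descending; ties by ascending code) and orders members the same way.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from cpirank.classifier import EndpointModel, predict_scores
from cpirank.ebnorm import EBDistributions, normalize_profile
from cpirank.icd9 import parse_icd9

__all__ = ["FamilyEntry", "RankedReport", "predict_indications", "build_ranked_report"]

DEFAULT_CONFIDENCE_FLOOR = 0.5


@dataclass
class FamilyEntry:
    """One family row of the report with its ranked member diseases.

    ``confidence`` is ``None`` for a family that has member predictions but
    no family-tier model (flagged, listed after scored families).
    """

    rank: int
    code: str
    confidence: float | None
    members: list[tuple[str, float]] = field(default_factory=list)

    @property
    def flagged(self) -> bool:
        return self.confidence is None


@dataclass
class RankedReport:
    families: list[FamilyEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.families)


def _code_sort_key(code: str) -> tuple[int, float, str]:
    parsed = parse_icd9(code)
    nf = parsed.numeric_family if parsed.numeric_family is not None else float("inf")
    return (0 if parsed.numeric_family is not None else 1, nf, code)


def predict_indications(
    models_disease: Mapping[str, EndpointModel],
    models_family: Mapping[str, EndpointModel],
    profile: np.ndarray | Mapping[str, float],
    eb: EBDistributions | Mapping[str, EBDistributions] | None = None,
    target_panel: Sequence[str] | None = None,
) -> tuple[dict[str, float], dict[str, float]]:
    """Score one drug's CPI profile with both model tiers.

    ``profile`` is a docking-score vector aligned to the models' target panel,
    or a {target_id: score} mapping resolved against ``target_panel`` (any
    missing target is an error listing the gaps).  Raw logistic scores from
    each tier are normalized with ``eb`` -- a single fitted
    :class:`EBDistributions` applied to both tiers, a mapping with keys
    ``"disease"``/``"family"``, or ``None`` to return raw scores.

    Returns ``(disease_confidences, family_confidences)`` keyed by code.
    """
    if isinstance(profile, Mapping):
        if target_panel is None:
            raise ValueError("target_panel is required when profile is a mapping")
        missing = [t for t in target_panel if t not in profile]
        if missing:
            raise ValueError(f"profile is missing targets: {', '.join(missing)}")
        x = np.array([float(profile[t]) for t in target_panel])
    else:
        x = np.asarray(profile, dtype=float).ravel()

    def tier_scores(models: Mapping[str, EndpointModel], tier: str) -> dict[str, float]:
        codes = sorted(models, key=_code_sort_key)
        for c in codes:
            if models[c].n_features != x.size:
                raise ValueError(
                    f"{tier} model {c!r} expects {models[c].n_features} targets, "
                    f"profile has {x.size}"
                )
        raw = np.array([float(predict_scores(models[c], x[None, :])[0]) for c in codes])
        if eb is None:
            conf = raw
        else:
            dist = eb[tier] if isinstance(eb, Mapping) else eb
            conf = normalize_profile(raw, dist)
        return dict(zip(codes, conf.tolist()))

    return tier_scores(models_disease, "disease"), tier_scores(models_family, "family")


def build_ranked_report(
    disease_confidences: Mapping[str, float],
    family_confidences: Mapping[str, float],
    top_n: int | None = None,
    confidence_floor: float = DEFAULT_CONFIDENCE_FLOOR,
) -> RankedReport:
    """Assemble the hierarchical ranked indication report.

    Families are ordered by family-tier confidence descending, ties broken by
    ascending code; members within a family by confidence descending, ties by
    ascending code.  ``top_n=None`` keeps every family whose confidence
    exceeds ``confidence_floor`` (or that is only present through members);
    an integer keeps the best ``top_n`` scored families.  Ranks run 1..n.
    Raises ``ValueError`` when both confidence maps are empty.
    """
    if not disease_confidences and not family_confidences:
        raise ValueError("empty confidence map; nothing to rank")
    for v in list(disease_confidences.values()) + list(family_confidences.values()):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"confidence {v} outside [0, 1]")

    members_by_family: dict[str, list[tuple[str, float]]] = {}
    for code, conf in disease_confidences.items():
        fam = parse_icd9(code).family
        members_by_family.setdefault(fam, []).append((code, conf))
    for fam, members in members_by_family.items():
        members.sort(key=lambda m: (-m[1], _code_sort_key(m[0])))

    scored = sorted(
        family_confidences.items(), key=lambda kv: (-kv[1], _code_sort_key(kv[0]))
    )
    if top_n is not None:
        scored = scored[: int(top_n)]
    else:
        scored = [(f, c) for f, c in scored if c > confidence_floor]
    # families seen only through members: flagged, appended after scored ones
    orphan = sorted(set(members_by_family) - set(family_confidences), key=_code_sort_key)

    families: list[FamilyEntry] = []
    rank = 0
    for fam, conf in scored:
        rank += 1
        families.append(FamilyEntry(rank, fam, conf, members_by_family.get(fam, [])))
    for fam in orphan:
        rank += 1
        families.append(FamilyEntry(rank, fam, None, members_by_family[fam]))
    return RankedReport(families=families)
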