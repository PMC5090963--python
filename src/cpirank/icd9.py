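"""ICD-9 code handling and endpoint construction.

An *endpoint* is one binary classification task -- "does drug X treat disease
code Y" -- at either the individual ICD-9 code level or the 3-digit family
level (the rubric obtained by truncating a code at its decimal point, e.g.
250.10 -> 250).  Endpoints are filtered twice before model training:

* codes whose numeric family lies in 780-999 (symptoms, injuries, poisoning)
  are removed;
* endpoints with fewer than five positive drugs are removed, because the
  positive class would be too small to train on.

At the family level a drug counts as positive for a family iff it is positive
for at least one member code; both filters apply after that rollup.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable

if TYPE_CHECKING:  # pragma: no cover
    from cpirank.io import IndicationLabels

__all__ = ["ICD9Code", "EndpointSet", "parse_icd9", "build_endpoints"]

_ICD9_RE = re.compile(r"^[VE]?\d{1,3}(\.\d{1,2})?$")

DEFAULT_MIN_POSITIVES = 5
DEFAULT_EXCLUDED_RANGE = (780, 999)


@dataclass(frozen=True)
class ICD9Code:
    """A validated ICD-9 code with its 3-digit family.

    ``family`` is the portion before the decimal point; ``numeric_family`` is
    its integer value for purely numeric codes and ``None`` for V/E codes.
    """

    raw: str
    family: str
    numeric_family: int | None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.raw


def parse_icd9(code: str) -> ICD9Code:
    """Parse and validate an ICD-9 code string.

    Raises ``ValueError`` naming the offending string when it does not match
    the ICD-9 shape ``[VE]?ddd[.dd]``.
    """
    if not isinstance(code, str) or not code:
        raise ValueError(f"ICD-9 code must be a non-empty string, got {code!r}")
    if not _ICD9_RE.match(code):
        raise ValueError(f"invalid ICD-9 code: {code!r}")
    family = code.split(".", 1)[0]
    numeric_family = int(family) if family.isdigit() else None
    return ICD9Code(raw=code, family=family, numeric_family=numeric_family)


@dataclass
class EndpointSet:
    """Filtered endpoints at one hierarchy level, each with its positive drugs.

    ``endpoints`` maps endpoint code (an individual ICD-9 code or a 3-digit
    family rubric) to its positive drug set, in sorted-code order.
    """

    level: str  # "disease" | "family"
    endpoints: dict[str, frozenset[str]] = field(default_factory=dict)
    min_positives: int = DEFAULT_MIN_POSITIVES
    excluded_range: tuple[int, int] = DEFAULT_EXCLUDED_RANGE

    @property
    def codes(self) -> list[str]:
        return list(self.endpoints)

    def __len__(self) -> int:
        return len(self.endpoints)


def _family_excluded(numeric_family: int | None, excluded_range: tuple[int, int]) -> bool:
    if numeric_family is None:
        return False
    lo, hi = excluded_range
    return lo <= numeric_family <= hi


def build_endpoints(
    labels: "IndicationLabels",
    level: str = "disease",
    min_positives: int = DEFAULT_MIN_POSITIVES,
    excluded_range: tuple[int, int] = DEFAULT_EXCLUDED_RANGE,
    keep_ve: bool = False,
) -> EndpointSet:
    """Build the filtered endpoint set at ``level`` from an indication table.

    ``level="disease"`` keeps individual codes; ``level="family"`` rolls codes
    up to 3-digit rubrics, a drug being positive for a family iff positive for
    at least one member code.  After rollup, endpoints whose numeric family
    falls inside ``excluded_range`` (inclusive) and endpoints with fewer than
    ``min_positives`` positive drugs are dropped.  V- and E-codes are dropped
    unless ``keep_ve`` is set (the exclusion-range rule presumes numeric
    families).

    Raises ``ValueError`` if no endpoint survives.
    """
    if level not in ("disease", "family"):
        raise ValueError(f"level must be 'disease' or 'family', got {level!r}")
    if min_positives < 1:
        raise ValueError("min_positives must be >= 1")

    positives_by_code: dict[str, set[str]] = {}
    numeric_by_code: dict[str, int | None] = {}
    for drug, raw in labels.positives:
        parsed = parse_icd9(raw)
        key = parsed.family if level == "family" else parsed.raw
        positives_by_code.setdefault(key, set()).add(drug)
        numeric_by_code[key] = parsed.numeric_family

    kept: dict[str, frozenset[str]] = {}
    for code in sorted(positives_by_code):
        nf = numeric_by_code[code]
        if nf is None and not keep_ve:
            continue
        if _family_excluded(nf, excluded_range):
            continue
        drugs = positives_by_code[code]
        if len(drugs) < min_positives:
            continue
        kept[code] = frozenset(drugs)

    if not kept:
        raise ValueError(
            "no endpoint survives filtering; relax min_positives or the "
            "excluded range, or supply more labels"
        )
    return EndpointSet(
        level=level,
        endpoints=kept,
        min_positives=min_positives,
        excluded_range=excluded_range,
    )
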