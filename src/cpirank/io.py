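"""Tabular readers and writers for every artifact the pipeline touches.

File formats (all plain text, '.' decimal separator, no locale):

* CPI matrix: TSV/CSV; header row of target ids, first column drug ids, body
  floats in kcal/mol (more negative = stronger predicted binding).  Scores
  are stored as-is; any sign handling happens inside model standardization.
* Indication labels: TSV with columns ``drug_id<TAB>icd9_code[<TAB>label]``;
  rows with label 0 are ignored with a warning.
* Fingerprints: TSV, either ``drug_id<TAB>bitstring`` or
  ``drug_id<TAB>length<TAB>i1,i2,...`` (on-bit indices).
* Ranked reports: TSV or JSON with fixed 6-decimal floats so identical
  reports serialize to identical bytes.

Readers reject malformed input with precise coordinates rather than coerce.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd

from cpirank.icd9 import parse_icd9

if TYPE_CHECKING:  # pragma: no cover
    from cpirank.ranking import RankedReport

__all__ = [
    "CPIMatrix",
    "IndicationLabels",
    "FingerprintSet",
    "read_cpi_matrix",
    "write_cpi_matrix",
    "read_indication_labels",
    "write_indication_labels",
    "read_fingerprints",
    "write_ranked_report",
    "read_predictions",
    "write_predictions",
    "save_models",
    "load_models",
    "write_metric_report",
]

FLOAT_FMT = "%.6f"


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {kind} id: {i!r}")
        seen.add(i)


@dataclass
class CPIMatrix:
    """Drugs x targets docking-score matrix (kcal/mol)."""

    drug_ids: list[str]
    target_ids: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.drug_ids), len(self.target_ids)):
            raise ValueError(
                f"score matrix shape {self.scores.shape} does not match "
                f"{len(self.drug_ids)} drugs x {len(self.target_ids)} targets"
            )
        _check_unique(self.drug_ids, "drug")
        _check_unique(self.target_ids, "target")
        if not np.all(np.isfinite(self.scores)):
            r, c = np.argwhere(~np.isfinite(self.scores))[0]
            raise ValueError(
                f"non-finite docking score at drug {self.drug_ids[r]!r}, "
                f"target {self.target_ids[c]!r}"
            )

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_targets(self) -> int:
        return len(self.target_ids)

    def row(self, drug_id: str) -> np.ndarray:
        """Docking-score profile for one drug."""
        try:
            idx = self.drug_ids.index(drug_id)
        except ValueError:
            raise KeyError(f"unknown drug id {drug_id!r}") from None
        return self.scores[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.drug_ids, columns=self.target_ids)


@dataclass
class IndicationLabels:
    """Sparse positive drug -> ICD-9 indication pairs over a drug universe.

    A pair present in ``positives`` means label 1; any other
    (universe drug, code) combination is an implicit 0.
    """

    drug_universe: frozenset[str]
    positives: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        self.drug_universe = frozenset(self.drug_universe)
        self.positives = frozenset(self.positives)
        for drug, code in self.positives:
            if drug not in self.drug_universe:
                raise ValueError(f"positive pair references drug {drug!r} outside the universe")
            parse_icd9(code)

    @property
    def codes(self) -> list[str]:
        return sorted({c for _, c in self.positives})

    def positives_for(self, code: str) -> frozenset[str]:
        return frozenset(d for d, c in self.positives if c == code)

    def label_vector(self, drug_ids: Sequence[str], positive_drugs: Iterable[str]) -> np.ndarray:
        pos = set(positive_drugs)
        return np.fromiter((1 if d in pos else 0 for d in drug_ids), dtype=int, count=len(drug_ids))


@dataclass
class FingerprintSet:
    """Binary molecular fingerprints: per drug, the set of on-bit indices."""

    bit_length: int
    bits: dict[str, frozenset[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bit_length <= 0:
            raise ValueError("bit_length must be positive")
        for drug, on in self.bits.items():
            on = frozenset(on)
            if any(i < 0 or i >= self.bit_length for i in on):
                raise ValueError(f"fingerprint bit out of range for drug {drug!r}")
            self.bits[drug] = on

    def __contains__(self, drug_id: str) -> bool:
        return drug_id in self.bits

    def __getitem__(self, drug_id: str) -> frozenset[int]:
        try:
            return self.bits[drug_id]
        except KeyError:
            raise KeyError(f"no fingerprint for drug {drug_id!r}") from None


def read_cpi_matrix(
    path: str | Path,
    dialect: str = "tsv",
    impute: str | None = None,
) -> CPIMatrix:
    """Read a CPI matrix from a delimited text file.

    ``impute=None`` (default) treats any missing/non-numeric cell as a hard
    error with its coordinates; ``impute="target_mean"`` replaces missing
    cells with the column mean of the remaining entries.
    """
    path = Path(path)
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise ValueError(f"dialect must be 'tsv' or 'csv', got {dialect!r}")
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    drug_ids = [str(d) for d in df.index]
    target_ids = [str(t) for t in df.columns]
    _check_unique(drug_ids, "drug")
    _check_unique(target_ids, "target")

    scores = np.empty(df.shape, dtype=float)
    missing: list[tuple[int, int]] = []
    for j in range(df.shape[1]):
        col = df.iloc[:, j].to_numpy()
        for i, cell in enumerate(col):
            text = cell.strip()
            if text in ("", "NA", "NaN", "nan"):
                missing.append((i, j))
                scores[i, j] = np.nan
                continue
            try:
                scores[i, j] = float(text)
            except ValueError:
                raise ValueError(
                    f"non-numeric docking score {cell!r} at row {i + 2}, "
                    f"column {j + 2} (drug {drug_ids[i]!r}, target {target_ids[j]!r})"
                ) from None

    if missing:
        if impute is None:
            i, j = missing[0]
            raise ValueError(
                f"missing docking score at row {i + 2}, column {j + 2} "
                f"(drug {drug_ids[i]!r}, target {target_ids[j]!r}); "
                "enable impute='target_mean' to fill with column means"
            )
        if impute != "target_mean":
            raise ValueError(f"unknown impute policy {impute!r}")
        for j in set(c for _, c in missing):
            col = scores[:, j]
            finite = col[np.isfinite(col)]
            if finite.size == 0:
                raise ValueError(f"target {target_ids[j]!r} has no observed scores to impute from")
            col[~np.isfinite(col)] = finite.mean()
    return CPIMatrix(drug_ids=drug_ids, target_ids=target_ids, scores=scores)


def write_cpi_matrix(cpi: CPIMatrix, path: str | Path, dialect: str = "tsv") -> None:
    sep = {"tsv": "\t", "csv": ","}[dialect]
    cpi.to_frame().to_csv(Path(path), sep=sep, float_format=FLOAT_FMT)


def read_indication_labels(
    path: str | Path,
    universe_path: str | Path | None = None,
) -> IndicationLabels:
    """Read drug -> ICD-9 positive pairs from a 2- or 3-column TSV.

    The drug universe is the union of drug ids seen, plus the ids listed in
    ``universe_path`` (one per line) when given.  Duplicated pairs collapse;
    rows with an explicit label 0 are skipped with a warning.
    """
    path = Path(path)
    positives: set[tuple[str, str]] = set()
    universe: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (2, 3):
                raise ValueError(f"{path}:{lineno}: expected 2 or 3 tab-separated columns")
            drug, code = parts[0].strip(), parts[1].strip()
            if lineno == 1 and code.lower() in ("icd9", "icd9_code", "code"):
                continue  # header row
            try:
                parse_icd9(code)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            universe.add(drug)
            if len(parts) == 3:
                label = parts[2].strip()
                if label not in ("0", "1"):
                    raise ValueError(f"{path}:{lineno}: label must be 0 or 1, got {label!r}")
                if label == "0":
                    warnings.warn(f"{path}:{lineno}: explicit 0 label ignored (absence means 0)")
                    continue
            positives.add((drug, code))
    if universe_path is not None:
        with open(universe_path) as fh:
            for line in fh:
                drug = line.strip()
                if drug:
                    universe.add(drug)
    return IndicationLabels(drug_universe=frozenset(universe), positives=frozenset(positives))


def write_indication_labels(labels: IndicationLabels, path: str | Path) -> None:
    """Write positives as sorted 2-column TSV (universe-only drugs appended as comments)."""
    with open(path, "w") as fh:
        for drug, code in sorted(labels.positives):
            fh.write(f"{drug}\t{code}\n")
        labelled = {d for d, _ in labels.positives}
        for drug in sorted(labels.drug_universe - labelled):
            fh.write(f"# universe-only\t{drug}\n")


def read_fingerprints(path: str | Path, format: str = "bitstring") -> FingerprintSet:
    """Read binary fingerprints, one drug per line.

    ``bitstring``: ``drug_id<TAB>0101...``; ``indices``:
    ``drug_id<TAB>length<TAB>i1,i2,...`` (empty index list allowed).
    """
    path = Path(path)
    bits: dict[str, frozenset[int]] = {}
    bit_length: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if format == "bitstring":
                if len(parts) != 2:
                    raise ValueError(f"{path}:{lineno}: expected 'drug<TAB>bitstring'")
                drug, bs = parts[0].strip(), parts[1].strip()
                if set(bs) - {"0", "1"}:
                    raise ValueError(f"{path}:{lineno}: bitstring contains non-binary characters")
                length = len(bs)
                on = frozenset(i for i, b in enumerate(bs) if b == "1")
            elif format == "indices":
                if len(parts) != 3:
                    raise ValueError(f"{path}:{lineno}: expected 'drug<TAB>length<TAB>i1,i2,...'")
                drug = parts[0].strip()
                length = int(parts[1])
                idx_text = parts[2].strip()
                on = frozenset(int(i) for i in idx_text.split(",") if i.strip()) if idx_text else frozenset()
            else:
                raise ValueError(f"format must be 'bitstring' or 'indices', got {format!r}")
            if bit_length is None:
                bit_length = length
            elif length != bit_length:
                raise ValueError(
                    f"{path}:{lineno}: inconsistent fingerprint length {length} (expected {bit_length})"
                )
            if drug in bits:
                raise ValueError(f"{path}:{lineno}: duplicate fingerprint for drug {drug!r}")
            bits[drug] = on
    if bit_length is None:
        raise ValueError(f"{path}: no fingerprints found")
    return FingerprintSet(bit_length=bit_length, bits=bits)


def write_ranked_report(report: "RankedReport", path: str | Path, format: str = "tsv") -> None:
    """Serialize a ranked indication report deterministically.

    TSV rows are ordered family then members; JSON keys are ordered and all
    confidences are printed with 6 decimals, so identical reports produce
    byte-identical files.
    """
    path = Path(path)
    if format == "tsv":
        lines = ["rank\tlevel\tcode\tconfidence"]
        for entry in report.families:
            conf = "" if entry.confidence is None else FLOAT_FMT % entry.confidence
            lines.append(f"{entry.rank}\tfamily\t{entry.code}\t{conf}")
            for code, c in entry.members:
                lines.append(f"{entry.rank}\tdisease\t{code}\t{FLOAT_FMT % c}")
        path.write_text("\n".join(lines) + "\n")
    elif format == "json":
        payload = [
            {
                "rank": entry.rank,
                "family": entry.code,
                "confidence": None if entry.confidence is None else round(entry.confidence, 6),
                "members": [
                    {"code": code, "confidence": round(c, 6)} for code, c in entry.members
                ],
            }
            for entry in report.families
        ]
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    else:
        raise ValueError(f"format must be 'tsv' or 'json', got {format!r}")


def write_predictions(preds: "PredictionSet", path: str | Path) -> None:  # noqa: F821
    """Write a drug x endpoint score matrix as TSV (blank cell = unscored)."""
    df = pd.DataFrame(preds.scores, index=preds.drug_ids, columns=preds.endpoint_codes)
    df.to_csv(Path(path), sep="\t", float_format=FLOAT_FMT, na_rep="")


def save_models(models: dict[str, "EndpointModel"], path: str | Path) -> None:  # noqa: F821
    """Serialize fitted endpoint models to deterministic JSON."""
    payload = {
        code: {
            "weights": [round(float(w), 10) for w in m.weights],
            "intercept": round(float(m.intercept), 10),
            "feature_means": [round(float(v), 10) for v in m.feature_means],
            "feature_sds": [round(float(v), 10) for v in m.feature_sds],
            "reg_strength": m.reg_strength,
            "threshold": m.threshold,
        }
        for code, m in models.items()
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def load_models(path: str | Path) -> dict[str, "EndpointModel"]:  # noqa: F821
    from cpirank.classifier import EndpointModel

    payload = json.loads(Path(path).read_text())
    return {
        code: EndpointModel(
            endpoint_code=code,
            weights=np.array(m["weights"]),
            intercept=m["intercept"],
            feature_means=np.array(m["feature_means"]),
            feature_sds=np.array(m["feature_sds"]),
            reg_strength=m["reg_strength"],
            threshold=m.get("threshold"),
        )
        for code, m in payload.items()
    }


def write_metric_report(report: "MetricReport", path: str | Path) -> None:  # noqa: F821
    """Write a metric report as deterministic TSV (metric, mean, sd)."""
    lines = [f"# mode\t{report.mode}",
             f"# n_entities_evaluated\t{report.n_entities_evaluated}",
             f"# n_entities_skipped\t{report.n_entities_skipped}",
             "metric\tmean\tsd"]
    for name in sorted(report.metrics):
        s = report.metrics[name]
        sd = "" if s.sd is None else FLOAT_FMT % s.sd
        lines.append(f"{name}\t{FLOAT_FMT % s.mean}\t{sd}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_predictions(path: str | Path) -> "PredictionSet":  # noqa: F821
    from cpirank.classifier import PredictionSet

    df = pd.read_csv(Path(path), sep="\t", index_col=0)
    scores = df.to_numpy(dtype=float)
    return PredictionSet(
        drug_ids=[str(d) for d in df.index],
        endpoint_codes=[str(c) for c in df.columns],
        scores=scores,
        provenance={"source": str(path)},
    )
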