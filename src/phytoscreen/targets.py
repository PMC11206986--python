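"""Target-prediction aggregation and the two retention filters.

Per-compound ligand-based target predictions (one probability score per
compound–protein pair, as exported by similarity-based target-prediction
services) are aggregated per gene symbol. A target is retained iff

* its mean score over the compounds predicting it is strictly greater
  than the score threshold (default 0.1), and
* strictly more than ``support_threshold`` distinct compounds predict it
  (default 2, i.e. at least 3 supporting compounds).

The mean is taken over the supporting compounds only, not over the whole
library: prediction services emit per-compound probability lists, and
averaging in zeros for non-predicting compounds would make the 0.1
threshold effectively unreachable. Under this definition the order of the
two filters does not matter.
"""

from __future__ import annotations

import csv
import glob
from fractions import Fraction
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Optional

import pandas as pd

from phytoscreen.errors import ConfigurationError, ValidationError

#: Logical field -> default column name. The alternates cover the export
#: dialect of the SwissTargetPrediction service out of the box.
DEFAULT_DIALECT = {
    "compound_id": "compound_id",
    "target_name": "target_name",
    "gene_symbol": "gene_symbol",
    "uniprot_id": "uniprot_id",
    "score": "score",
}
_DIALECT_ALTERNATES = {
    "target_name": ["Target", "target"],
    "gene_symbol": ["Common name", "common_name", "gene"],
    "uniprot_id": ["Uniprot ID", "uniprot"],
    "score": ["Probability*", "Probability", "probability"],
}


@dataclass(frozen=True)
class TargetPrediction:
    compound_id: str
    gene_symbol: str
    score: float
    target_name: str = ""
    uniprot_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValidationError(
                f"prediction score must be in [0, 1], got {self.score}"
            )


@dataclass(frozen=True)
class TargetRecord:
    """Aggregated view of one target across the compound set."""

    gene_symbol: str
    n_supporting_compounds: int
    mean_score: float
    retained: bool
    supporting_compounds: tuple[str, ...] = ()
    uniprot_id: Optional[str] = None


class TargetSet(NamedTuple):
    records: list[TargetRecord]

    @property
    def retained_symbols(self) -> list[str]:
        return [r.gene_symbol for r in self.records if r.retained]


class PredictionIngest(NamedTuple):
    predictions: list[TargetPrediction]
    rejected: list[tuple[int, str, str]]  # (row, compound_id, reason)


def _resolve_column(frame: pd.DataFrame, logical: str, mapping: dict) -> Optional[str]:
    if mapping[logical] in frame.columns:
        return mapping[logical]
    for alt in _DIALECT_ALTERNATES.get(logical, []):
        if alt in frame.columns:
            return alt
    return None


def read_target_predictions(
    path,
    dialect: Optional[dict] = None,
    compound_id: Optional[str] = None,
) -> PredictionIngest:
    """Read one prediction table (CSV/TSV).

    Long-format tables carry a ``compound_id`` column; per-compound export
    files instead pass the owning compound's id via ``compound_id``. Rows
    with scores outside [0, 1] are rejected with a report; duplicate
    (compound, gene) rows collapse to the maximum score.
    """
    path = Path(path)
    mapping = dict(DEFAULT_DIALECT)
    if dialect:
        mapping.update(dialect)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    gene_col = _resolve_column(frame, "gene_symbol", mapping)
    score_col = _resolve_column(frame, "score", mapping)
    if gene_col is None or score_col is None:
        raise ConfigurationError(
            f"mandatory columns gene_symbol/score missing from {path.name}; "
            f"present: {list(frame.columns)}"
        )
    cid_col = _resolve_column(frame, "compound_id", mapping)
    if cid_col is None and compound_id is None:
        raise ConfigurationError(
            f"{path.name} has no compound_id column and no compound_id "
            f"was supplied for a per-compound file"
        )
    name_col = _resolve_column(frame, "target_name", mapping)
    uni_col = _resolve_column(frame, "uniprot_id", mapping)

    best: dict[tuple[str, str], TargetPrediction] = {}
    rejected: list[tuple[int, str, str]] = []
    for idx, row in frame.iterrows():
        cid = str(row[cid_col]).strip() if cid_col else str(compound_id)
        gene = str(row[gene_col]).strip()
        if not gene:
            rejected.append((int(idx), cid, "empty gene symbol"))
            continue
        try:
            score = float(row[score_col])
        except ValueError:
            rejected.append((int(idx), cid, f"non-numeric score {row[score_col]!r}"))
            continue
        if not 0.0 <= score <= 1.0:
            rejected.append((int(idx), cid, f"score {score} outside [0, 1]"))
            continue
        pred = TargetPrediction(
            compound_id=cid,
            gene_symbol=gene,
            score=score,
            target_name=str(row[name_col]).strip() if name_col else "",
            uniprot_id=(str(row[uni_col]).strip() or None) if uni_col else None,
        )
        key = (cid, gene)
        if key not in best or score > best[key].score:
            best[key] = pred
    return PredictionIngest(list(best.values()), rejected)


def read_prediction_directory(pattern: str, dialect: Optional[dict] = None) -> PredictionIngest:
    """Read every per-compound table matching a glob pattern; the file stem
    is used as the compound id."""
    predictions: list[TargetPrediction] = []
    rejected: list[tuple[int, str, str]] = []
    for filename in sorted(glob.glob(pattern)):
        stem = Path(filename).stem
        result = read_target_predictions(filename, dialect=dialect, compound_id=stem)
        predictions.extend(result.predictions)
        rejected.extend(result.rejected)
    return PredictionIngest(predictions, rejected)


def aggregate_and_filter(
    predictions: Iterable[TargetPrediction],
    score_threshold: float = 0.1,
    support_threshold: int = 2,
) -> TargetSet:
    """Aggregate per gene symbol and apply the two retention filters.

    Retained iff ``mean_score > score_threshold`` (strict) and
    ``n_supporting_compounds > support_threshold`` (strict — the defaults
    demand at least 3 compounds). Duplicate (compound, gene) pairs are
    collapsed to the maximum score before averaging, so aggregation is
    independent of row order.
    """
    predictions = list(predictions)
    if not predictions:
        raise ValidationError("no predictions to aggregate")
    best: dict[tuple[str, str], TargetPrediction] = {}
    for pred in predictions:
        key = (pred.compound_id, pred.gene_symbol)
        if key not in best or pred.score > best[key].score:
            best[key] = pred
    by_gene: dict[str, list[TargetPrediction]] = {}
    for pred in best.values():
        by_gene.setdefault(pred.gene_symbol, []).append(pred)
    threshold = Fraction(str(score_threshold))
    records = []
    for gene in sorted(by_gene):
        group = sorted(by_gene[gene], key=lambda p: p.compound_id)
        # exact decimal mean, so a mean of exactly 0.1 is excluded by the
        # strict comparison rather than passing on float round-off
        exact_mean = sum((Fraction(str(p.score)) for p in group), Fraction(0)) / len(group)
        uniprot = next((p.uniprot_id for p in group if p.uniprot_id), None)
        records.append(TargetRecord(
            gene_symbol=gene,
            n_supporting_compounds=len(group),
            mean_score=float(exact_mean),
            retained=(exact_mean > threshold and len(group) > support_threshold),
            supporting_compounds=tuple(p.compound_id for p in group),
            uniprot_id=uniprot,
        ))
    return TargetSet(records)


def write_target_set(target_set: TargetSet, path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t")
        writer.writerow([
            "gene_symbol", "n_supporting_compounds", "mean_score",
            "retained", "supporting_compounds", "uniprot_id",
        ])
        for r in target_set.records:
            writer.writerow([
                r.gene_symbol, r.n_supporting_compounds, f"{r.mean_score:.6f}",
                str(r.retained).lower(), ",".join(r.supporting_compounds),
                r.uniprot_id or "",
            ])
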