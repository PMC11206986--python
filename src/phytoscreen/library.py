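"""Compound-library ingest, validation, canonicalization and activity labeling.

The library is the data backbone of the screen: an ordered collection of
compound records, each with an identity, a SMILES structure, a chemical
class and an activity status (``known_active`` for compounds with reported
activity against the indication, ``candidate`` for everything else).
Records whose structures do not parse are excluded at ingest with a
per-row rejection report rather than aborting the run, because herbal
libraries routinely contain unresolved entries.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Optional

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

from phytoscreen.errors import ConfigurationError, ValidationError

RDLogger.DisableLog("rdApp.error")
RDLogger.DisableLog("rdApp.warning")

KNOWN_ACTIVE = "known_active"
CANDIDATE = "candidate"

#: Controlled chemical-class vocabulary; unrecognized labels map to "other".
COMPOUND_CLASSES = frozenset({
    "flavonoid", "acid", "ester", "glycoside",
    "hydrocarbon", "lignan", "phenol", "steroid", "other",
})

#: Logical field -> default column name in library tables.
DEFAULT_DIALECT = {
    "compound_id": "compound_id",
    "name": "name",
    "cas": "cas",
    "smiles": "smiles",
    "compound_class": "compound_class",
    "activity_status": "activity_status",
    "commercially_available": "commercially_available",
    "provenance": "provenance",
}

MANDATORY_FIELDS = ("compound_id", "smiles")


@dataclass(frozen=True)
class CompoundRecord:
    """One library entry: identity, structure, class and activity status."""

    compound_id: str
    smiles: str
    name: str = ""
    cas: Optional[str] = None
    compound_class: str = "other"
    activity_status: str = CANDIDATE
    commercially_available: Optional[bool] = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.activity_status not in (KNOWN_ACTIVE, CANDIDATE):
            raise ValidationError(
                f"activity_status must be {KNOWN_ACTIVE!r} or {CANDIDATE!r}, "
                f"got {self.activity_status!r}"
            )


@dataclass
class CompoundLibrary:
    """Ordered collection of :class:`CompoundRecord` with unique ids."""

    records: list[CompoundRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.compound_id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate compound_id(s): {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CompoundRecord]:
        return iter(self.records)

    def get(self, compound_id: str) -> CompoundRecord:
        for r in self.records:
            if r.compound_id == compound_id:
                return r
        raise KeyError(compound_id)

    @property
    def ids(self) -> list[str]:
        return [r.compound_id for r in self.records]

    @property
    def n_known(self) -> int:
        return sum(r.activity_status == KNOWN_ACTIVE for r in self.records)

    @property
    def n_candidate(self) -> int:
        return sum(r.activity_status == CANDIDATE for r in self.records)

    def known(self) -> list[CompoundRecord]:
        return [r for r in self.records if r.activity_status == KNOWN_ACTIVE]

    def candidates(self) -> list[CompoundRecord]:
        return [r for r in self.records if r.activity_status == CANDIDATE]


class Rejection(NamedTuple):
    """One rejected input row and the reason it was dropped."""

    row: int  # 0-based data-row index in the source table
    compound_id: str
    reason: str


class IngestResult(NamedTuple):
    library: CompoundLibrary
    rejected: list[Rejection]


class DedupResult(NamedTuple):
    library: CompoundLibrary
    #: kept compound_id -> ids of structurally identical records merged into it
    merged: dict[str, list[str]]


def _parse_bool(value) -> Optional[bool]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in ("", "nan", "unknown", "na"):
        return None
    if text in ("true", "1", "yes", "y"):
        return True
    if text in ("false", "0", "no", "n"):
        return False
    return None


def _read_table(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_compound_table(path, dialect: Optional[dict] = None) -> IngestResult:
    """Read a compound library from a CSV/TSV table.

    ``dialect`` maps logical field names (``compound_id``, ``smiles``,
    ``name``, ``cas``, ``compound_class``, ``activity_status``,
    ``commercially_available``, ``provenance``) to column names in the
    file; unmapped optional fields fall back to :data:`DEFAULT_DIALECT`.
    Rows whose SMILES do not parse, or that repeat an id, go to the
    rejection report instead of the library.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"compound table not found: {path}")
    mapping = dict(DEFAULT_DIALECT)
    if dialect:
        mapping.update(dialect)
    frame = _read_table(path)
    for logical in MANDATORY_FIELDS:
        if mapping[logical] not in frame.columns:
            raise ConfigurationError(
                f"mandatory column {mapping[logical]!r} (field {logical!r}) "
                f"missing from {path.name}; present: {list(frame.columns)}"
            )

    def cell(row, logical, default=""):
        col = mapping[logical]
        if col in frame.columns:
            return row[col]
        return default

    records: list[CompoundRecord] = []
    rejected: list[Rejection] = []
    seen: set[str] = set()
    for idx, row in frame.iterrows():
        cid = str(cell(row, "compound_id")).strip()
        smiles = str(cell(row, "smiles")).strip()
        if not cid:
            rejected.append(Rejection(int(idx), cid, "empty compound_id"))
            continue
        if cid in seen:
            rejected.append(Rejection(int(idx), cid, "duplicate compound_id"))
            continue
        if Chem.MolFromSmiles(smiles) is None:
            rejected.append(Rejection(int(idx), cid, "unparseable structure"))
            continue
        compound_class = str(cell(row, "compound_class", "other")).strip() or "other"
        if compound_class not in COMPOUND_CLASSES:
            compound_class = "other"
        status = str(cell(row, "activity_status", CANDIDATE)).strip() or CANDIDATE
        if status not in (KNOWN_ACTIVE, CANDIDATE):
            rejected.append(
                Rejection(int(idx), cid, f"unknown activity_status {status!r}")
            )
            continue
        cas = str(cell(row, "cas")).strip() or None
        records.append(CompoundRecord(
            compound_id=cid,
            smiles=smiles,
            name=str(cell(row, "name")).strip(),
            cas=cas,
            compound_class=compound_class,
            activity_status=status,
            commercially_available=_parse_bool(cell(row, "commercially_available", None)),
            provenance=str(cell(row, "provenance")).strip(),
        ))
        seen.add(cid)
    return IngestResult(CompoundLibrary(records), rejected)


def write_compound_table(library: CompoundLibrary, path) -> None:
    """Write the library back to CSV/TSV in the default dialect.

    Round-trips bit-exactly through :func:`read_compound_table` for
    valid records.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter=sep)
        writer.writerow(list(DEFAULT_DIALECT))
        for r in library:
            avail = "" if r.commercially_available is None else str(r.commercially_available).lower()
            writer.writerow([
                r.compound_id, r.name, r.cas or "", r.smiles,
                r.compound_class, r.activity_status, avail, r.provenance,
            ])


def write_rejection_report(rejected: Iterable[Rejection], path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t")
        writer.writerow(["row", "compound_id", "reason"])
        for rej in rejected:
            writer.writerow([rej.row, rej.compound_id, rej.reason])


def read_sdf_structures(path, id_property: str = "compound_id") -> dict[str, str]:
    """Read an SDF and return compound_id -> SMILES for records carrying
    the id property; used to supply structures for table rows whose
    SMILES column is empty or unresolved."""
    structures: dict[str, str] = {}
    for mol in Chem.SDMolSupplier(str(path)):
        if mol is None or not mol.HasProp(id_property):
            continue
        structures[mol.GetProp(id_property)] = Chem.MolToSmiles(mol)
    return structures


def apply_sdf_structures(library: CompoundLibrary, structures: dict[str, str]) -> CompoundLibrary:
    """Replace record structures with SDF-derived SMILES where available."""
    records = [
        replace(r, smiles=structures[r.compound_id])
        if r.compound_id in structures else r
        for r in library
    ]
    return CompoundLibrary(records)


_FRAGMENT_CHOOSER = rdMolStandardize.LargestFragmentChooser()


def canonical_smiles(smiles: str, strip_salts: bool = True) -> str:
    """Canonical isomeric SMILES; optionally keep only the largest fragment.

    Isomeric information is preserved because stereochemistry (e.g. sugar
    configuration in glycosides) distinguishes many natural products that
    would otherwise collapse to one flat structure.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValidationError(f"unparseable structure: {smiles!r}")
    if strip_salts and "." in Chem.MolToSmiles(mol):
        mol = _FRAGMENT_CHOOSER.choose(mol)
    return Chem.MolToSmiles(mol)


def canonicalize_and_dedup(
    library: CompoundLibrary,
    strip_salts: bool = True,
    dedup: bool = True,
) -> DedupResult:
    """Canonicalize every SMILES and merge structurally identical records.

    The first-seen record of each canonical structure wins; ids of records
    merged into it are returned in the ``merged`` map. With ``dedup``
    disabled only canonicalization is applied. Idempotent.
    """
    canon_records: list[CompoundRecord] = []
    merged: dict[str, list[str]] = {}
    first_by_structure: dict[str, str] = {}
    for record in library:
        canon = canonical_smiles(record.smiles, strip_salts=strip_salts)
        if dedup and canon in first_by_structure:
            merged.setdefault(first_by_structure[canon], []).append(record.compound_id)
            continue
        first_by_structure.setdefault(canon, record.compound_id)
        canon_records.append(replace(record, smiles=canon))
    return DedupResult(CompoundLibrary(canon_records), merged)


def label_activity(library: CompoundLibrary, known_ids: Iterable[str]) -> CompoundLibrary:
    """Partition the library: ids in ``known_ids`` become known actives,
    every other record becomes a candidate."""
    known = set(known_ids)
    missing = known - set(library.ids)
    if missing:
        raise ValidationError(
            f"known_ids not present in library: {sorted(missing)}"
        )
    records = [
        replace(r, activity_status=KNOWN_ACTIVE if r.compound_id in known else CANDIDATE)
        for r in library
    ]
    return CompoundLibrary(records)
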