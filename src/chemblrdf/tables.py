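"""Load and write relational snapshots.

Two dialects share one table/column layout mirroring the ChEMBL 13 table
names, so the same loader ingests both the bundled fixtures and a real
schema subset:

* a directory of UTF-8 tab-separated files, one per table, header row
  mandatory — an empty field reads as ABSENT (SQL NULL has no delimited
  representation);
* an embedded SQLite database file with the same table and column names.

Tables: molecule_dictionary, compound_structures, compound_properties,
assays, assay2target, target_dictionary, activities, docs.
"""

from __future__ import annotations

import csv
import sqlite3
from pathlib import Path
from typing import Iterator, Optional

from .records import (
    ActivityRecord,
    AssayRecord,
    AssayType,
    DocumentRecord,
    MoleculeRecord,
    MoleculeType,
    TargetAssignment,
    TargetRecord,
    TargetType,
)
from .snapshot import RelationalSnapshot


class MissingTableError(FileNotFoundError):
    pass


TABLE_COLUMNS: dict[str, list[str]] = {
    "molecule_dictionary": [
        "chembl_id", "pref_name", "synonyms", "molecule_type", "approved_drug",
    ],
    "compound_structures": [
        "chembl_id", "canonical_smiles", "standard_inchi", "standard_inchi_key",
    ],
    "compound_properties": [
        "chembl_id", "property_name", "property_value", "software",
    ],
    "assays": ["assay_id", "assay_type", "description", "doc_id"],
    "assay2target": [
        "assay_id", "target_id", "confidence_score", "relationship_type",
        "multi_flag", "complex_flag",
    ],
    "target_dictionary": [
        "target_id", "target_type", "protein_accession", "pref_name",
    ],
    "activities": [
        "activity_id", "assay_id", "chembl_id", "standard_type",
        "standard_value", "standard_units", "standard_relation", "doc_id",
    ],
    "docs": ["doc_id", "pubmed_id", "doi", "title", "journal", "year"],
}


def _none_if_empty(value: Optional[str]) -> Optional[str]:
    if value is None or value == "":
        return None
    return value


def _opt_int(value) -> Optional[int]:
    value = _none_if_empty(None if value is None else str(value))
    return None if value is None else int(value)


def _opt_float(value) -> Optional[float]:
    value = _none_if_empty(None if value is None else str(value))
    return None if value is None else float(value)


def _bool(value) -> bool:
    return str(value) in ("1", "True", "true")


# -- row <-> record -------------------------------------------------------

def _rows_to_snapshot(rows: dict[str, list[dict]]) -> RelationalSnapshot:
    structures = {r["chembl_id"]: r for r in rows["compound_structures"]}
    properties: dict[str, dict[str, tuple[float, Optional[str]]]] = {}
    for r in rows["compound_properties"]:
        properties.setdefault(r["chembl_id"], {})[r["property_name"]] = (
            float(r["property_value"]),
            _none_if_empty(r.get("software")),
        )
    molecules = []
    for r in rows["molecule_dictionary"]:
        struct = structures.get(r["chembl_id"], {})
        synonyms = _none_if_empty(r.get("synonyms"))
        molecules.append(MoleculeRecord(
            chembl_id=r["chembl_id"],
            pref_name=_none_if_empty(r.get("pref_name")),
            synonyms=synonyms.split("|") if synonyms else [],
            molecule_type=MoleculeType(r["molecule_type"]),
            approved_drug=_bool(r.get("approved_drug", "0")),
            smiles=_none_if_empty(struct.get("canonical_smiles")),
            inchi=_none_if_empty(struct.get("standard_inchi")),
            inchikey=_none_if_empty(struct.get("standard_inchi_key")),
            properties=properties.get(r["chembl_id"], {}),
        ))
    assays = [
        AssayRecord(
            assay_id=r["assay_id"],
            assay_type=(AssayType(t) if (t := _none_if_empty(r.get("assay_type")))
                        else None),
            description=_none_if_empty(r.get("description")),
            doc_id=int(r["doc_id"]),
        )
        for r in rows["assays"]
    ]
    assignments = [
        TargetAssignment(
            assay_id=r["assay_id"],
            target_id=r["target_id"],
            confidence_score=int(r["confidence_score"]),
            relationship_type=_none_if_empty(r.get("relationship_type")),
            multi_flag=_bool(r.get("multi_flag", "0")),
            complex_flag=_bool(r.get("complex_flag", "0")),
        )
        for r in rows["assay2target"]
    ]
    targets = [
        TargetRecord(
            target_id=r["target_id"],
            target_type=TargetType(r["target_type"]),
            uniprot_accession=_none_if_empty(r.get("protein_accession")),
            label=r["pref_name"],
        )
        for r in rows["target_dictionary"]
    ]
    activities = [
        ActivityRecord(
            activity_id=r["activity_id"],
            assay_id=r["assay_id"],
            chembl_id=r["chembl_id"],
            activity_type=r["standard_type"],
            std_value=_opt_float(r.get("standard_value")),
            std_units=_none_if_empty(r.get("standard_units")),
            relation=r.get("standard_relation") or "=",
            doc_id=int(r["doc_id"]),
        )
        for r in rows["activities"]
    ]
    documents = [
        DocumentRecord(
            doc_id=int(r["doc_id"]),
            pmid=_opt_int(r.get("pubmed_id")),
            doi=_none_if_empty(r.get("doi")),
            title=_none_if_empty(r.get("title")),
            journal=_none_if_empty(r.get("journal")),
            year=_opt_int(r.get("year")),
        )
        for r in rows["docs"]
    ]
    snapshot = RelationalSnapshot(
        molecules=molecules, assays=assays, assignments=assignments,
        targets=targets, activities=activities, documents=documents,
    )
    snapshot.check_integrity()
    return snapshot


def _snapshot_to_rows(s: RelationalSnapshot) -> dict[str, list[dict]]:
    def fmt(value) -> str:
        if value is None:
            return ""
        if isinstance(value, bool):
            return "1" if value else "0"
        return str(value)

    rows: dict[str, list[dict]] = {name: [] for name in TABLE_COLUMNS}
    for m in s.molecules:
        rows["molecule_dictionary"].append({
            "chembl_id": m.chembl_id,
            "pref_name": fmt(m.pref_name),
            "synonyms": "|".join(m.synonyms),
            "molecule_type": m.molecule_type.value,
            "approved_drug": fmt(m.approved_drug),
        })
        if m.smiles is not None or m.inchi is not None:
            rows["compound_structures"].append({
                "chembl_id": m.chembl_id,
                "canonical_smiles": fmt(m.smiles),
                "standard_inchi": fmt(m.inchi),
                "standard_inchi_key": fmt(m.inchikey),
            })
        for name, (value, software) in m.properties.items():
            rows["compound_properties"].append({
                "chembl_id": m.chembl_id,
                "property_name": name,
                "property_value": repr(value),
                "software": fmt(software),
            })
    for a in s.assays:
        rows["assays"].append({
            "assay_id": a.assay_id,
            "assay_type": a.assay_type.value if a.assay_type else "",
            "description": fmt(a.description),
            "doc_id": str(a.doc_id),
        })
    for asg in s.assignments:
        rows["assay2target"].append({
            "assay_id": asg.assay_id,
            "target_id": asg.target_id,
            "confidence_score": str(asg.confidence_score),
            "relationship_type": fmt(asg.relationship_type),
            "multi_flag": fmt(asg.multi_flag),
            "complex_flag": fmt(asg.complex_flag),
        })
    for t in s.targets:
        rows["target_dictionary"].append({
            "target_id": t.target_id,
            "target_type": t.target_type.value,
            "protein_accession": fmt(t.uniprot_accession),
            "pref_name": t.label,
        })
    for act in s.activities:
        rows["activities"].append({
            "activity_id": act.activity_id,
            "assay_id": act.assay_id,
            "chembl_id": act.chembl_id,
            "standard_type": act.activity_type,
            "standard_value": "" if act.std_value is None else repr(act.std_value),
            "standard_units": fmt(act.std_units),
            "standard_relation": act.relation,
            "doc_id": str(act.doc_id),
        })
    for d in s.documents:
        rows["docs"].append({
            "doc_id": str(d.doc_id),
            "pubmed_id": fmt(d.pmid),
            "doi": fmt(d.doi),
            "title": fmt(d.title),
            "journal": fmt(d.journal),
            "year": fmt(d.year),
        })
    return rows


# -- delimited-text dialect -----------------------------------------------

def _read_tsv_dir(directory: Path) -> dict[str, list[dict]]:
    rows: dict[str, list[dict]] = {}
    for table, columns in TABLE_COLUMNS.items():
        path = directory / f"{table}.tsv"
        if not path.exists():
            raise MissingTableError(f"missing table file: {path}")
        with path.open(encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            missing = set(columns) - set(reader.fieldnames or [])
            if missing:
                raise ValueError(
                    f"{path}: missing columns {sorted(missing)}")
            rows[table] = list(reader)
    return rows


def write_snapshot(snapshot: RelationalSnapshot, directory: str | Path) -> Path:
    """Write the delimited-text dialect (one .tsv per table)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for table, table_rows in _snapshot_to_rows(snapshot).items():
        columns = TABLE_COLUMNS[table]
        with (directory / f"{table}.tsv").open(
                "w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=columns, delimiter="\t",
                                    lineterminator="\n")
            writer.writeheader()
            writer.writerows(table_rows)
    return directory


# -- embedded SQL dialect -------------------------------------------------

def _read_sqlite(path: Path) -> dict[str, list[dict]]:
    con = sqlite3.connect(f"file:{path}?mode=ro", uri=True)
    con.row_factory = sqlite3.Row
    try:
        existing = {
            r[0] for r in con.execute(
                "SELECT name FROM sqlite_master WHERE type='table'")
        }
        rows: dict[str, list[dict]] = {}
        for table, columns in TABLE_COLUMNS.items():
            if table not in existing:
                raise MissingTableError(f"missing table {table!r} in {path}")
            fetched = [dict(r) for r in con.execute(
                f"SELECT {', '.join(columns)} FROM {table}")]
            rows[table] = [
                {k: ("" if v is None else v) for k, v in r.items()}
                for r in fetched
            ]
        return rows
    finally:
        con.close()


def write_snapshot_sqlite(snapshot: RelationalSnapshot, path: str | Path) -> Path:
    path = Path(path)
    con = sqlite3.connect(path)
    try:
        for table, columns in TABLE_COLUMNS.items():
            con.execute(f"DROP TABLE IF EXISTS {table}")
            con.execute(f"CREATE TABLE {table} ({', '.join(columns)})")
        for table, table_rows in _snapshot_to_rows(snapshot).items():
            columns = TABLE_COLUMNS[table]
            placeholders = ", ".join("?" for _ in columns)
            con.executemany(
                f"INSERT INTO {table} VALUES ({placeholders})",
                [tuple(r[c] for c in columns) for r in table_rows],
            )
        con.commit()
    finally:
        con.close()
    return path


def load_snapshot(source: str | Path, dialect: str | None = None) -> RelationalSnapshot:
    """Load a snapshot from a TSV directory or an SQLite database file.

    ``dialect`` is ``"tsv"`` or ``"sqlite"``; by default it is inferred
    from whether ``source`` is a directory.
    """
    source = Path(source)
    if not source.exists():
        raise FileNotFoundError(source)
    if dialect is None:
        dialect = "tsv" if source.is_dir() else "sqlite"
    if dialect == "tsv":
        rows = _read_tsv_dir(source)
    elif dialect == "sqlite":
        rows = _read_sqlite(source)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return _rows_to_snapshot(rows)


def read_csid_mapping(path: str | Path) -> dict[str, int]:
    """Two-column delimited mapping file: chembl_id <tab> csid."""
    mapping: dict[str, int] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        chembl_id, _, csid = line.partition("\t")
        mapping[chembl_id.strip()] = int(csid.strip())
    return mapping


def iter_tables(snapshot: RelationalSnapshot) -> Iterator[tuple[str, int]]:
    """(table name, row count) pairs, for progress/summary logging."""
    for table, table_rows in _snapshot_to_rows(snapshot).items():
        yield table, len(table_rows)
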