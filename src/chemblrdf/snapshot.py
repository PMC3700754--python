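"""In-memory snapshot of the relational tables, with referential integrity."""

from __future__ import annotations

from dataclasses import dataclass, field

from .records import (
    SENTINEL_DOC_ID,
    ActivityRecord,
    AssayRecord,
    DocumentRecord,
    MoleculeRecord,
    TargetAssignment,
    TargetRecord,
)


class IntegrityError(ValueError):
    """A foreign key does not resolve inside the snapshot."""


class DuplicateIdError(ValueError):
    """A primary key occurs more than once."""


@dataclass
class RelationalSnapshot:
    molecules: list[MoleculeRecord] = field(default_factory=list)
    assays: list[AssayRecord] = field(default_factory=list)
    assignments: list[TargetAssignment] = field(default_factory=list)
    targets: list[TargetRecord] = field(default_factory=list)
    activities: list[ActivityRecord] = field(default_factory=list)
    documents: list[DocumentRecord] = field(default_factory=list)

    def molecule(self, chembl_id: str) -> MoleculeRecord:
        return self._index_molecules()[chembl_id]

    def assignments_for(self, assay_id: str) -> list[TargetAssignment]:
        return [a for a in self.assignments if a.assay_id == assay_id]

    def _index_molecules(self) -> dict[str, MoleculeRecord]:
        return {m.chembl_id: m for m in self.molecules}

    def check_integrity(self) -> None:
        """Validate uniqueness and foreign keys; raise naming offenders."""
        for name, ids in (
            ("molecule", [m.chembl_id for m in self.molecules]),
            ("assay", [a.assay_id for a in self.assays]),
            ("target", [t.target_id for t in self.targets]),
            ("activity", [a.activity_id for a in self.activities]),
            ("document", [str(d.doc_id) for d in self.documents]),
        ):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise DuplicateIdError(f"duplicate {name} id {i!r}")
                seen.add(i)
        sentinels = [d for d in self.documents if d.doc_id == SENTINEL_DOC_ID]
        if len(sentinels) > 1:
            raise DuplicateIdError("sentinel doc_id -1 occurs more than once")

        mol_ids = {m.chembl_id for m in self.molecules}
        assay_ids = {a.assay_id for a in self.assays}
        target_ids = {t.target_id for t in self.targets}
        # the sentinel always resolves (it denotes "unpublished", with or
        # without a docs row)
        doc_ids = {d.doc_id for d in self.documents} | {SENTINEL_DOC_ID}
        dangling: list[str] = []
        for asg in self.assignments:
            if asg.assay_id not in assay_ids:
                dangling.append(f"assay2target -> assay {asg.assay_id!r}")
            if asg.target_id not in target_ids:
                dangling.append(f"assay2target -> target {asg.target_id!r}")
        for act in self.activities:
            if act.assay_id not in assay_ids:
                dangling.append(f"activity {act.activity_id!r} -> assay {act.assay_id!r}")
            if act.chembl_id not in mol_ids:
                dangling.append(
                    f"activity {act.activity_id!r} -> molecule {act.chembl_id!r}"
                )
            if act.doc_id not in doc_ids:
                dangling.append(f"activity {act.activity_id!r} -> doc {act.doc_id}")
        for assay in self.assays:
            if assay.doc_id not in doc_ids:
                dangling.append(f"assay {assay.assay_id!r} -> doc {assay.doc_id}")
        if dangling:
            raise IntegrityError(
                "dangling foreign keys: " + "; ".join(sorted(dangling))
            )

    @property
    def typeless_assay_count(self) -> int:
        return sum(1 for a in self.assays if a.assay_type is None)

    @property
    def has_sentinel_doc(self) -> bool:
        return any(d.doc_id == SENTINEL_DOC_ID for d in self.documents)
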