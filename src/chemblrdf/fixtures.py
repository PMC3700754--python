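"""Synthetic ChEMBL-schema snapshots with planted structure.

The generator emulates the features of the source database that the
conversion rules and queries depend on: the mix of compound types
(dominated by small molecules), approved-drug flags, structure
identifiers with occasionally very long InChIs, assays with sometimes
*missing* assay types, per-target confidence scores 0-9, standardized
activity values with string units, and documents with PMIDs/DOIs plus
the sentinel "unpublished" document (doc_id -1).

Activity-type shares follow the distribution printed with the source
release (Potency 43%, IC50 13%, MIC 4.6%, Inhibition 3.7%, Ki 3.6%, the
rest spread over minor types).

A selectivity scenario can be *planted*: k molecules receive a
high-affinity measurement (< the high-affinity bound) on protein target
A and a low-affinity one (> the low-affinity bound) on protein target B,
both of the planted activity type; targets A and B are reserved for the
planted assays so the planted set is exactly the answer to the
corresponding selectivity query.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Optional

from .records import (
    SENTINEL_DOC_ID,
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

#: (type, weight) pairs approximating the release's activity-type shares
ACTIVITY_TYPE_WEIGHTS: list[tuple[str, float]] = [
    ("Potency", 43.0),
    ("IC50", 13.0),
    ("MIC", 4.6),
    ("Inhibition", 3.7),
    ("Ki", 3.6),
    ("EC50", 3.0),
    ("GI50", 2.5),
    ("Activity", 2.0),
    ("Kd", 1.5),
    ("ED50", 1.1),
    # stand-ins for the long tail of minor types; weights total 100 so
    # each named share above is a true percentage
    ("Ratio", 5.0),
    ("T1/2", 4.0),
    ("AUC", 4.0),
    ("CC50", 3.5),
    ("LD50", 3.5),
    ("Dose", 2.0),
]

_MOLECULE_TYPE_WEIGHTS = [
    (MoleculeType.SMALL_MOLECULE, 90.0),
    (MoleculeType.PEPTIDE, 3.0),
    (MoleculeType.PROTEIN, 2.5),
    (MoleculeType.ANTIBODY, 1.5),
    (MoleculeType.OLIGOSACCHARIDE, 1.0),
    (MoleculeType.OLIGONUCLEOTIDE, 1.0),
    (MoleculeType.CELL, 1.0),
]

_NONPROTEIN_TARGET_TYPES = [
    TargetType.ADMET, TargetType.CELL_LINE, TargetType.NUCLEIC_ACID,
    TargetType.ORGANISM, TargetType.SUBCELLULAR, TargetType.TISSUE,
    TargetType.UNCHECKED, TargetType.UNKNOWN,
]

_UNIT_POOL = ["nM", "uM", "ug.mL-1", "%", ""]


class ConfigError(ValueError):
    pass


@dataclass
class PlantedSelectivity:
    """Selective-binder scenario planted into a snapshot."""

    target_a_id: str = "t_cdk2"
    target_b_id: str = "t_cdk4"
    accession_a: str = "P24941"
    accession_b: str = "P11802"
    n_molecules: int = 7
    activity_type: str = "IC50"
    value_a: float = 10.0   # high affinity on A (below a < 50 nM bound)
    value_b: float = 500.0  # low affinity on B (above a > 200 nM bound)
    units: str = "nM"


@dataclass
class FixtureConfig:
    n_molecules: int = 40
    n_assays: int = 20
    n_targets: int = 10
    n_activities: int = 120
    n_documents: int = 8
    seed: int = 0
    fraction_assays_missing_type: float = 0.0
    include_sentinel_doc: bool = True
    planted: Optional[PlantedSelectivity] = None
    fraction_overlong_inchi: float = 0.0
    fraction_approved: float = 0.1

    def __post_init__(self) -> None:
        for name in ("n_molecules", "n_assays", "n_targets",
                     "n_activities", "n_documents"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("fraction_assays_missing_type",
                     "fraction_overlong_inchi", "fraction_approved"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {value}")
        if self.planted is not None:
            p = self.planted
            if p.n_molecules > self.n_molecules:
                raise ConfigError(
                    f"planted selectivity needs {p.n_molecules} molecules, "
                    f"config has only {self.n_molecules}"
                )
            if self.n_targets < 2:
                raise ConfigError("planted selectivity needs >= 2 targets")
            n_missing = math.ceil(
                self.fraction_assays_missing_type * self.n_assays)
            if self.n_assays < 2 + n_missing:
                raise ConfigError(
                    "planted selectivity needs 2 typed assays on top of "
                    f"{n_missing} typeless ones"
                )
            if self.n_activities < 2 * p.n_molecules:
                raise ConfigError(
                    "planted selectivity needs 2 activities per planted "
                    "molecule"
                )


def _weighted_choice(rng: random.Random, weights):
    items = [w[0] for w in weights]
    return rng.choices(items, weights=[w[1] for w in weights], k=1)[0]


def _fake_inchi(rng: random.Random, overlong: bool, max_len: int = 2000) -> str:
    if overlong:
        # formula layer padded well past any practical URI length cap
        chain = "".join(rng.choices("ch123456-", k=max_len + 200))
        return f"InChI=1S/C{rng.randint(100, 999)}H{rng.randint(100, 999)}/c{chain}"
    c = rng.randint(2, 30)
    h = rng.randint(2, 2 * c + 2)
    layer = "-".join(str(rng.randint(1, c)) for _ in range(min(c, 6)))
    return f"InChI=1S/C{c}H{h}/c{layer}/h1-{h}H"


def _fake_inchikey(rng: random.Random) -> str:
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    return (
        "".join(rng.choices(letters, k=14)) + "-"
        + "".join(rng.choices(letters, k=10)) + "-N"
    )


def _fake_smiles(rng: random.Random) -> str:
    return "".join(rng.choices(["C", "c1ccccc1", "N", "O", "Cl", "(", ")"], k=0)) or \
        "C" * rng.randint(1, 8) + rng.choice(["", "O", "N", "c1ccccc1"])


def generate_snapshot(config: FixtureConfig) -> RelationalSnapshot:
    """Deterministic snapshot for ``config`` (a pure function of it)."""
    rng = random.Random(config.seed)
    planted = config.planted

    # -- documents ---------------------------------------------------------
    documents: list[DocumentRecord] = []
    n_regular_docs = config.n_documents - (1 if config.include_sentinel_doc else 0)
    if config.include_sentinel_doc and config.n_documents >= 1:
        documents.append(DocumentRecord(doc_id=SENTINEL_DOC_ID))
    for i in range(max(n_regular_docs, 0)):
        doc_id = 2000 + i
        documents.append(DocumentRecord(
            doc_id=doc_id,
            pmid=rng.randint(10_000_000, 29_999_999) if rng.random() < 0.85 else None,
            doi=(f"10.{rng.randint(1000, 9999)}/j.fake.{doc_id}"
                 if rng.random() < 0.7 else None),
            title=f"Synthetic bioactivity study {doc_id}",
            journal=rng.choice(["J Med Chem", "Bioorg Med Chem Lett", None]),
            year=rng.randint(1995, 2012),
        ))
    regular_doc_ids = [d.doc_id for d in documents if d.doc_id != SENTINEL_DOC_ID]
    citable_doc_ids = [d.doc_id for d in documents] or [SENTINEL_DOC_ID]

    def pick_doc() -> int:
        return rng.choice(regular_doc_ids) if regular_doc_ids else SENTINEL_DOC_ID

    # -- targets -----------------------------------------------------------
    targets: list[TargetRecord] = []
    reserved_targets: set[str] = set()
    if planted is not None:
        targets.append(TargetRecord(planted.target_a_id, TargetType.PROTEIN,
                                    "Cyclin-dependent kinase 2 (synthetic)",
                                    planted.accession_a))
        targets.append(TargetRecord(planted.target_b_id, TargetType.PROTEIN,
                                    "Cyclin-dependent kinase 4 (synthetic)",
                                    planted.accession_b))
        reserved_targets = {planted.target_a_id, planted.target_b_id}
    for i in range(config.n_targets - len(targets)):
        if rng.random() < 0.6:
            ttype = TargetType.PROTEIN
            accession = (
                f"P{rng.randint(10000, 99999)}" if rng.random() < 0.8 else None
            )
        else:
            ttype = rng.choice(_NONPROTEIN_TARGET_TYPES)
            accession = None
        targets.append(TargetRecord(f"t{100 + i}", ttype,
                                    f"Synthetic target {100 + i}", accession))
    background_target_ids = [t.target_id for t in targets
                             if t.target_id not in reserved_targets]

    # -- molecules ---------------------------------------------------------
    molecules: list[MoleculeRecord] = []
    n_approved = round(config.fraction_approved * config.n_molecules)
    approved_idx = set(rng.sample(range(config.n_molecules),
                                  min(n_approved, config.n_molecules)))
    with_inchi_idx = [i for i in range(config.n_molecules) if rng.random() < 0.9]
    n_overlong = math.ceil(config.fraction_overlong_inchi * len(with_inchi_idx))
    overlong_idx = set(rng.sample(with_inchi_idx, n_overlong))
    for i in range(config.n_molecules):
        mtype = _weighted_choice(rng, _MOLECULE_TYPE_WEIGHTS)
        has_structure = i in with_inchi_idx and mtype in (
            MoleculeType.SMALL_MOLECULE, MoleculeType.PEPTIDE,
            MoleculeType.OLIGOSACCHARIDE, MoleculeType.OLIGONUCLEOTIDE,
        )
        inchi = (_fake_inchi(rng, overlong=i in overlong_idx)
                 if has_structure else None)
        properties = {}
        if mtype is MoleculeType.SMALL_MOLECULE and rng.random() < 0.8:
            properties["alogp"] = (round(rng.uniform(-2, 7), 2), "ACD/Labs")
            properties["full_mwt"] = (round(rng.uniform(80, 900), 2), None)
        molecules.append(MoleculeRecord(
            chembl_id=f"ChEMBL{400000 + i}",
            molecule_type=mtype,
            pref_name=(f"Compound {400000 + i}" if rng.random() < 0.5 else None),
            synonyms=([f"SYN-{i}-{j}" for j in range(rng.randint(1, 2))]
                      if rng.random() < 0.3 else []),
            approved_drug=i in approved_idx,
            smiles=_fake_smiles(rng) if has_structure else None,
            inchi=inchi,
            inchikey=_fake_inchikey(rng) if inchi is not None else None,
            properties=properties,
        ))

    # -- assays ------------------------------------------------------------
    assays: list[AssayRecord] = []
    assignments: list[TargetAssignment] = []
    planted_assay_a = planted_assay_b = None
    if planted is not None:
        planted_assay_a, planted_assay_b = "a_sel_a", "a_sel_b"
        for assay_id, target_id in ((planted_assay_a, planted.target_a_id),
                                    (planted_assay_b, planted.target_b_id)):
            assays.append(AssayRecord(
                assay_id, AssayType.BINDING,
                f"Inhibition assay against {target_id} (synthetic)",
                pick_doc()))
            assignments.append(TargetAssignment(
                assay_id, target_id, confidence_score=9,
                relationship_type="D"))
    n_background_assays = config.n_assays - len(assays)
    n_missing = math.ceil(
        config.fraction_assays_missing_type * config.n_assays)
    missing_idx = set(rng.sample(range(n_background_assays),
                                 min(n_missing, n_background_assays)))
    for i in range(n_background_assays):
        assay_id = f"a{31860 + i}"
        atype = None if i in missing_idx else rng.choice(list(AssayType))
        assays.append(AssayRecord(
            assay_id, atype,
            (f"Synthetic assay {i}" if rng.random() < 0.9 else None),
            pick_doc()))
        if background_target_ids:
            for target_id in rng.sample(
                    background_target_ids,
                    min(rng.randint(1, 2), len(background_target_ids))):
                assignments.append(TargetAssignment(
                    assay_id, target_id,
                    confidence_score=rng.randint(0, 9),
                    relationship_type=rng.choice(["D", "H", "M", None]),
                    multi_flag=rng.random() < 0.1,
                    complex_flag=rng.random() < 0.1,
                ))

    # -- activities --------------------------------------------------------
    activities: list[ActivityRecord] = []
    act_no = 31863
    if planted is not None:
        planted_molecules = rng.sample(molecules, planted.n_molecules)
        for mol in planted_molecules:
            for assay_id, value in ((planted_assay_a, planted.value_a),
                                    (planted_assay_b, planted.value_b)):
                activities.append(ActivityRecord(
                    activity_id=f"a{act_no}",
                    assay_id=assay_id,
                    chembl_id=mol.chembl_id,
                    activity_type=planted.activity_type,
                    doc_id=pick_doc(),
                    std_value=value,
                    std_units=planted.units,
                    relation="=",
                ))
                act_no += 1
    background_assay_ids = [a.assay_id for a in assays
                            if a.assay_id not in (planted_assay_a, planted_assay_b)]
    n_background_acts = config.n_activities - len(activities)
    for _ in range(max(n_background_acts, 0)):
        if not background_assay_ids or not molecules:
            break
        units = rng.choice(_UNIT_POOL)
        activities.append(ActivityRecord(
            activity_id=f"a{act_no}",
            assay_id=rng.choice(background_assay_ids),
            chembl_id=rng.choice(molecules).chembl_id,
            activity_type=_weighted_choice(rng, ACTIVITY_TYPE_WEIGHTS),
            doc_id=rng.choice(citable_doc_ids),
            std_value=(round(rng.lognormvariate(4, 2), 3)
                       if rng.random() < 0.9 else None),
            std_units=units or None,
            relation=rng.choice(["=", "=", "=", "<", ">"]),
        ))
        act_no += 1

    snapshot = RelationalSnapshot(
        molecules=molecules, assays=assays, assignments=assignments,
        targets=targets, activities=activities, documents=documents,
    )
    snapshot.check_integrity()
    return snapshot
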