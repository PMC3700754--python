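"""Relational entity records mirroring the ChEMBL 13 schema subset.

The converter consumes an in-memory image of the eight relational tables
it touches (molecule_dictionary, compound_structures, compound_properties,
assays, assay2target, target_dictionary, activities, docs).  Optional
fields are ``None`` when the source value is SQL NULL / an empty delimited
field.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

#: doc_id reserved for the unpublished dataset; never becomes an article.
SENTINEL_DOC_ID = -1


class MoleculeType(enum.Enum):
    SMALL_MOLECULE = "Small molecule"
    PROTEIN = "Protein"
    PEPTIDE = "Peptide"
    ANTIBODY = "Antibody"
    OLIGOSACCHARIDE = "Oligosaccharide"
    OLIGONUCLEOTIDE = "Oligonucleotide"
    CELL = "Cell"


class AssayType(enum.Enum):
    """Assay type codes as released with ChEMBL 13."""

    ADMET = "A"
    BINDING = "B"
    FUNCTIONAL = "F"
    PHYSICOCHEMICAL = "P"
    UNASSIGNED = "U"


class TargetType(enum.Enum):
    PROTEIN = "PROTEIN"
    ADMET = "ADMET"
    CELL_LINE = "CELL-LINE"
    NUCLEIC_ACID = "NUCLEIC-ACID"
    ORGANISM = "ORGANISM"
    SUBCELLULAR = "SUBCELLULAR"
    TISSUE = "TISSUE"
    UNCHECKED = "UNCHECKED"
    UNKNOWN = "UNKNOWN"


@dataclass
class MoleculeRecord:
    chembl_id: str
    molecule_type: MoleculeType
    pref_name: Optional[str] = None
    synonyms: list[str] = field(default_factory=list)
    approved_drug: bool = False
    smiles: Optional[str] = None
    inchi: Optional[str] = None
    inchikey: Optional[str] = None
    #: property name -> (numeric value, software tag or None)
    properties: dict[str, tuple[float, Optional[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.chembl_id:
            raise ValueError("chembl_id must be non-empty")
        if self.inchikey is not None and self.inchi is None:
            raise ValueError(
                f"molecule {self.chembl_id}: inchikey present without inchi"
            )


@dataclass
class AssayRecord:
    assay_id: str
    assay_type: Optional[AssayType] = None
    description: Optional[str] = None
    doc_id: int = SENTINEL_DOC_ID


@dataclass
class TargetAssignment:
    assay_id: str
    target_id: str
    confidence_score: int
    relationship_type: Optional[str] = None
    multi_flag: bool = False
    complex_flag: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.confidence_score <= 9:
            raise ValueError(
                f"confidence_score {self.confidence_score} for assay "
                f"{self.assay_id} outside 0-9"
            )


@dataclass
class TargetRecord:
    target_id: str
    target_type: TargetType
    label: str
    uniprot_accession: Optional[str] = None


@dataclass
class ActivityRecord:
    activity_id: str
    assay_id: str
    chembl_id: str
    activity_type: str
    doc_id: int = SENTINEL_DOC_ID
    std_value: Optional[float] = None
    std_units: Optional[str] = None
    relation: str = "="


@dataclass
class DocumentRecord:
    doc_id: int
    pmid: Optional[int] = None
    doi: Optional[str] = None
    title: Optional[str] = None
    journal: Optional[str] = None
    year: Optional[int] = None
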