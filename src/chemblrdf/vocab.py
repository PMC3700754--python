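"""Central vocabulary: namespace table and predicate/class IRIs.

The dataset mixes community ontologies (BIBO, ChEBI, CHEMINF/SIO, CiTO,
PRotein Ontology, BFO) with an ad hoc ``chembl:`` namespace used where no
community alternative exists.  Predicates whose exact spelling is a local
convention (the relational-column-derived ones, the CiTO citation
property, the SIO attribute/value pattern) are collected here so they can
be swapped in one place.
"""

from __future__ import annotations

from rdflib import Namespace
from rdflib.namespace import OWL, RDF, RDFS, SKOS, XSD  # noqa: F401  (re-export)

# -- community vocabularies ------------------------------------------------
BIBO = Namespace("http://purl.org/ontology/bibo/")
CHEBI = Namespace("http://purl.org/obo/owl/CHEBI#")
CHEMINF = Namespace("http://semanticscience.org/resource/")  # CHEMINF + SIO terms
CITO = Namespace("http://purl.org/spar/cito/")
OBO = Namespace("http://purl.obolibrary.org/obo/")  # PRotein Ontology lives here
BFO = Namespace("http://www.ifomis.org/bfo/1.1/snap#")
DCTERMS = Namespace("http://purl.org/dc/terms/")

# -- dataset namespaces ----------------------------------------------------
CHEMBL = Namespace("http://rdf.farmbio.uu.se/chembl/onto/#")

CANONICAL_DATA_ROOT = "http://linkedchemistry.info/chembl/"
LEGACY_DATA_ROOT = "http://data.kasabi.com/dataset/chembl-rdf/"

# -- upper classes ---------------------------------------------------------
MATERIAL_ENTITY = BFO.MaterialEntity
CHEMICAL_ENTITY = CHEMINF.CHEMINF_000000
PROTEIN_CLASS = OBO.PR_000000001
OLIGOSACCHARIDE_CLASS = CHEBI.CHEBI_50699
OLIGONUCLEOTIDE_CLASS = CHEBI.CHEBI_7754
DRUG_ROLE = CHEBI.CHEBI_23888
HAS_ROLE = OBO.RO_0000087

# -- chembl: ad hoc terms --------------------------------------------------
ACTIVITY_CLASS = CHEMBL.Activity
ASSAY_CLASS = CHEMBL.Assay
TARGET_CLASS = CHEMBL.Target
ACTIVITY_TYPE = CHEMBL.type
STANDARD_VALUE = CHEMBL.standardValue
STANDARD_UNITS = CHEMBL.standardUnits
STANDARD_RELATION = CHEMBL.standardRelation
ON_ASSAY = CHEMBL.onAssay
FOR_MOLECULE = CHEMBL.forMolecule
ASSAY_TYPE = CHEMBL.assayType
DESCRIPTION = CHEMBL.hasDescription
HAS_TARGET_DESCRIPTION = CHEMBL.hasTargetDescription
HAS_TARGET = CHEMBL.hasTarget
HAS_CONF_SCORE = CHEMBL.hasConfScore
RELATIONSHIP_TYPE = CHEMBL.relationshipType
MULTI_FLAG = CHEMBL.multiFlag
COMPLEX_FLAG = CHEMBL.complexFlag
JOURNAL = CHEMBL.journal

# -- citation --------------------------------------------------------------
CITES = CITO.citesAsDataSource

# -- CHEMINF descriptor pattern (SIO attribute/value) ----------------------
HAS_ATTRIBUTE = CHEMINF.SIO_000008
HAS_VALUE = CHEMINF.SIO_000300
HAS_SOURCE = CHEMINF.SIO_000253  # software provenance of a calculated value

SMILES_DESCRIPTOR = CHEMINF.CHEMINF_000018
INCHI_DESCRIPTOR = CHEMINF.CHEMINF_000113
INCHIKEY_DESCRIPTOR = CHEMINF.CHEMINF_000059
CSID_DESCRIPTOR = CHEMINF.CHEMINF_000405  # ChemSpider identifier
GENERIC_DESCRIPTOR = CHEMINF.CHEMINF_000123  # calculated molecular property

#: calculated-property column name -> CHEMINF descriptor class
PROPERTY_DESCRIPTOR_CLASSES: dict[str, str] = {
    "alogp": str(CHEMINF.CHEMINF_000251),
    "hbd": str(CHEMINF.CHEMINF_000245),
    "hba": str(CHEMINF.CHEMINF_000244),
    "rtb": str(CHEMINF.CHEMINF_000261),
    "psa": str(CHEMINF.CHEMINF_000307),
    "full_mwt": str(CHEMINF.CHEMINF_000216),
}

#: prefix -> namespace, as bound on every emitted graph
PREFIXES = {
    "bibo": BIBO,
    "chebi": CHEBI,
    "cheminf": CHEMINF,
    "cito": CITO,
    "obo": OBO,
    "bfo": BFO,
    "chembl": CHEMBL,
    "dcterms": DCTERMS,
    "act": Namespace(CANONICAL_DATA_ROOT + "activity/"),
    "assay": Namespace(CANONICAL_DATA_ROOT + "assay/"),
    "mol": Namespace(CANONICAL_DATA_ROOT + "molecule/"),
    "res": Namespace(CANONICAL_DATA_ROOT + "resource/"),
    "target": Namespace(CANONICAL_DATA_ROOT + "target/"),
    "owl": OWL,
    "skos": SKOS,
}


def bind_prefixes(graph) -> None:
    for prefix, ns in PREFIXES.items():
        graph.bind(prefix, ns)
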