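"""Relational records -> RDF triple patterns.

Modelling conventions:

* Compounds and protein targets are *classes* (``rdfs:subClassOf`` their
  ontological superclass), never instances of it; assays, activities and
  articles are plain instances (``rdf:type``).  This class/instance split
  follows the CHEMINF convention that a chemical species is a class whose
  instances are individual molecules.
* Every compound class additionally subclasses the BFO 1.1
  ``MaterialEntity`` root directly, so one query retrieves all entities
  for which activities are captured.
* The drug role (ChEBI drug role, CHEBI_23888) is attached only to
  approved drugs, as an existential role restriction on the compound
  class — compounds are not ontologically drugs, they merely carry the
  role in a therapeutic context.
* Chemical identifiers (SMILES, InChI, InChIKey) and calculated
  properties (logP, ...) are typed descriptor nodes carrying their value
  and, where known, the software that computed it (the CHEMINF / SIO
  attribute-value pattern).
* Only *standardized* activity values are emitted, never the original
  literature values; units and activity types stay plain string literals.
* Assays without a defined assay type and the sentinel "unpublished"
  document (doc_id -1) are skipped entirely — these are the two, and the
  only two, classes of source rows that do not reach the graph.
"""

from __future__ import annotations

from decimal import Decimal

from rdflib import BNode, Graph, Literal, URIRef
from rdflib.namespace import OWL, RDF, RDFS, XSD

from . import vocab
from .records import (
    SENTINEL_DOC_ID,
    ActivityRecord,
    AssayRecord,
    DocumentRecord,
    MoleculeRecord,
    MoleculeType,
    TargetAssignment,
    TargetRecord,
    TargetType,
)
from .snapshot import RelationalSnapshot
from .uris import UriPolicy

#: molecule type -> type-specific superclass (CELL has no community match
#: and hangs directly off the material-entity root)
MOLECULE_SUPERCLASSES: dict[MoleculeType, URIRef | None] = {
    MoleculeType.SMALL_MOLECULE: vocab.CHEMICAL_ENTITY,
    MoleculeType.PROTEIN: vocab.PROTEIN_CLASS,
    MoleculeType.PEPTIDE: vocab.PROTEIN_CLASS,
    MoleculeType.ANTIBODY: vocab.PROTEIN_CLASS,
    MoleculeType.OLIGOSACCHARIDE: vocab.OLIGOSACCHARIDE_CLASS,
    MoleculeType.OLIGONUCLEOTIDE: vocab.OLIGONUCLEOTIDE_CLASS,
    MoleculeType.CELL: None,
}

IDENTIFIER_DESCRIPTORS = {
    "smiles": vocab.SMILES_DESCRIPTOR,
    "inchi": vocab.INCHI_DESCRIPTOR,
    "inchikey": vocab.INCHIKEY_DESCRIPTOR,
}


def _decimal_literal(value: float) -> Literal:
    # xsd:decimal keeps the printed precision stable across serialization
    # round trips; the serializer normalizes xsd:double lexical forms
    return Literal(Decimal(repr(float(value))), datatype=XSD.decimal)


def new_graph() -> Graph:
    g = Graph()
    vocab.bind_prefixes(g)
    return g


def _descriptor_node(
    graph: Graph,
    subject: URIRef,
    descriptor_class: URIRef,
    value: Literal,
    software: str | None = None,
) -> BNode:
    node = BNode()
    graph.add((subject, vocab.HAS_ATTRIBUTE, node))
    graph.add((node, RDF.type, descriptor_class))
    graph.add((node, vocab.HAS_VALUE, value))
    if software is not None:
        graph.add((node, vocab.HAS_SOURCE, Literal(software)))
    return node


def triplify_molecule(mol: MoleculeRecord, policy: UriPolicy) -> Graph:
    """Compound class axioms: superclass links, material-entity root, labels."""
    if mol.molecule_type not in MOLECULE_SUPERCLASSES:
        raise ValueError(f"unknown molecule_type: {mol.molecule_type!r}")
    g = new_graph()
    uri = policy.molecule_uri(mol.chembl_id)
    g.add((uri, RDF.type, OWL.Class))
    superclass = MOLECULE_SUPERCLASSES[mol.molecule_type]
    if superclass is not None:
        g.add((uri, RDFS.subClassOf, superclass))
    g.add((uri, RDFS.subClassOf, vocab.MATERIAL_ENTITY))
    if mol.pref_name is not None:
        g.add((uri, RDFS.label, Literal(mol.pref_name)))
    for synonym in mol.synonyms:
        g.add((uri, RDFS.label, Literal(synonym)))
    return g


def attach_drug_role(mol: MoleculeRecord, policy: UriPolicy) -> Graph:
    """Role restriction (has-role some drug role) for approved drugs only."""
    g = new_graph()
    if not mol.approved_drug:
        return g
    uri = policy.molecule_uri(mol.chembl_id)
    restriction = BNode()
    g.add((uri, RDFS.subClassOf, restriction))
    g.add((restriction, RDF.type, OWL.Restriction))
    g.add((restriction, OWL.onProperty, vocab.HAS_ROLE))
    g.add((restriction, OWL.someValuesFrom, vocab.DRUG_ROLE))
    return g


def triplify_descriptors(mol: MoleculeRecord, policy: UriPolicy) -> Graph:
    """One typed descriptor node per present identifier / numeric property."""
    g = new_graph()
    uri = policy.molecule_uri(mol.chembl_id)
    for field_name, descriptor_class in IDENTIFIER_DESCRIPTORS.items():
        value = getattr(mol, field_name)
        if value is not None:
            _descriptor_node(g, uri, descriptor_class, Literal(value))
    for prop_name, (value, software) in mol.properties.items():
        if not isinstance(value, (int, float)) or isinstance(value, bool):
            raise ValueError(
                f"non-numeric property value for {prop_name!r} on "
                f"{mol.chembl_id}: {value!r}"
            )
        descriptor_class = URIRef(
            vocab.PROPERTY_DESCRIPTOR_CLASSES.get(
                prop_name, str(vocab.GENERIC_DESCRIPTOR)
            )
        )
        _descriptor_node(
            g, uri, descriptor_class, _decimal_literal(value), software,
        )
    return g


def triplify_activity(act: ActivityRecord, policy: UriPolicy) -> Graph:
    g = new_graph()
    uri = policy.activity_uri(act.activity_id)
    g.add((uri, RDF.type, vocab.ACTIVITY_CLASS))
    g.add((uri, vocab.ACTIVITY_TYPE, Literal(act.activity_type)))
    if act.std_value is not None:
        g.add((uri, vocab.STANDARD_VALUE, _decimal_literal(act.std_value)))
    if act.std_units is not None:
        g.add((uri, vocab.STANDARD_UNITS, Literal(act.std_units)))
    g.add((uri, vocab.STANDARD_RELATION, Literal(act.relation)))
    g.add((uri, vocab.ON_ASSAY, policy.assay_uri(act.assay_id)))
    g.add((uri, vocab.FOR_MOLECULE, policy.molecule_uri(act.chembl_id)))
    # every activity cites its source document resource; the sentinel
    # resource r-1 exists as a citation object but never as an Article
    g.add((uri, vocab.CITES, policy.document_uri(act.doc_id)))
    return g


def triplify_assay(
    assay: AssayRecord,
    assignments: list[TargetAssignment],
    policy: UriPolicy,
) -> Graph:
    """Assay instance plus one confidence construct per target assignment.

    Returns an empty graph when the assay type is undefined: triple
    generation requires a defined assay type, so such rows are skipped.
    """
    g = new_graph()
    if assay.assay_type is None:
        return g
    bad = [a for a in assignments if a.assay_id != assay.assay_id]
    if bad:
        raise ValueError(
            f"assignments for foreign assay passed to {assay.assay_id!r}: "
            f"{sorted({a.assay_id for a in bad})}"
        )
    uri = policy.assay_uri(assay.assay_id)
    g.add((uri, RDF.type, vocab.ASSAY_CLASS))
    g.add((uri, vocab.ASSAY_TYPE, Literal(assay.assay_type.value)))
    if assay.description is not None:
        g.add((uri, vocab.DESCRIPTION, Literal(assay.description)))
    g.add((uri, vocab.CITES, policy.document_uri(assay.doc_id)))
    for assignment in assignments:
        if not 0 <= assignment.confidence_score <= 9:
            raise ValueError(
                f"confidence score {assignment.confidence_score} outside 0-9"
            )
        construct = BNode()
        g.add((uri, vocab.HAS_TARGET_DESCRIPTION, construct))
        g.add((construct, vocab.HAS_TARGET,
               policy.target_uri(assignment.target_id)))
        g.add((construct, vocab.HAS_CONF_SCORE,
               Literal(assignment.confidence_score, datatype=XSD.integer)))
        if assignment.relationship_type is not None:
            g.add((construct, vocab.RELATIONSHIP_TYPE,
                   Literal(assignment.relationship_type)))
        if assignment.multi_flag:
            g.add((construct, vocab.MULTI_FLAG, Literal(True)))
        if assignment.complex_flag:
            g.add((construct, vocab.COMPLEX_FLAG, Literal(True)))
    return g


def triplify_target(target: TargetRecord, policy: UriPolicy) -> Graph:
    """Protein targets as classes; every other category as an explicit
    instance type (UNCHECKED/UNKNOWN included — a closed-world choice).
    All targets carry the common chembl:Target marker."""
    if not isinstance(target.target_type, TargetType):
        raise ValueError(f"unknown target_type: {target.target_type!r}")
    g = new_graph()
    uri = policy.target_uri(target.target_id)
    if target.target_type is TargetType.PROTEIN:
        g.add((uri, RDFS.subClassOf, vocab.PROTEIN_CLASS))
        g.add((uri, RDFS.subClassOf, vocab.TARGET_CLASS))
    else:
        g.add((uri, RDF.type, vocab.CHEMBL[target.target_type.value]))
        g.add((uri, RDF.type, vocab.TARGET_CLASS))
    g.add((uri, RDFS.label, Literal(target.label)))
    return g


def triplify_document(doc: DocumentRecord, policy: UriPolicy) -> Graph:
    """Bibliographic instance; the sentinel doc -1 (unpublished dataset)
    is not a valid article and yields no triples."""
    g = new_graph()
    if doc.doc_id == SENTINEL_DOC_ID:
        return g
    uri = policy.document_uri(doc.doc_id)
    g.add((uri, RDF.type, vocab.BIBO.Article))
    if doc.pmid is not None:
        g.add((uri, vocab.BIBO.pmid, Literal(str(doc.pmid))))
    if doc.doi is not None:
        g.add((uri, vocab.BIBO.doi, Literal(doc.doi)))
    if doc.title is not None:
        g.add((uri, vocab.DCTERMS.title, Literal(doc.title)))
    if doc.journal is not None:
        g.add((uri, vocab.JOURNAL, Literal(doc.journal)))
    if doc.year is not None:
        g.add((uri, vocab.DCTERMS.date, Literal(str(doc.year), datatype=XSD.gYear)))
    return g


def triplify_snapshot(snapshot: RelationalSnapshot, policy: UriPolicy) -> Graph:
    """Union of all per-record graphs, in table order then primary key."""
    snapshot.check_integrity()
    g = new_graph()
    assignments_by_assay: dict[str, list[TargetAssignment]] = {}
    for assignment in snapshot.assignments:
        assignments_by_assay.setdefault(assignment.assay_id, []).append(assignment)

    for mol in sorted(snapshot.molecules, key=lambda m: m.chembl_id):
        g += triplify_molecule(mol, policy)
        g += attach_drug_role(mol, policy)
        g += triplify_descriptors(mol, policy)
    for assay in sorted(snapshot.assays, key=lambda a: a.assay_id):
        g += triplify_assay(assay, assignments_by_assay.get(assay.assay_id, []), policy)
    for target in sorted(snapshot.targets, key=lambda t: t.target_id):
        g += triplify_target(target, policy)
    for act in sorted(snapshot.activities, key=lambda a: a.activity_id):
        g += triplify_activity(act, policy)
    for doc in sorted(snapshot.documents, key=lambda d: d.doc_id):
        g += triplify_document(doc, policy)
    vocab.bind_prefixes(g)
    return g
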