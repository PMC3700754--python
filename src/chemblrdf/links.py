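"""Cross-database link-outs with graded predicates.

Links into the Linked Open Data cloud carry one of four predicates of
increasing strength — ``rdfs:seeAlso`` < ``skos:exactMatch`` <
``owl:equivalentClass`` / ``owl:sameAs`` — chosen per target database:

* ChemSpider compound mappings: ``skos:exactMatch`` plus a CHEMINF
  descriptor node carrying the ChemSpider identifier (CSID).
* OpenMolecules RDF: ``owl:equivalentClass`` on the InChI-based IRI
  (compounds are classes, so class-level equivalence, not sameAs);
  created only when the encoded IRI respects the length cap.
* Bio2RDF: UniProt links for protein targets, PubMed links for
  documents; predicate configurable, default ``skos:exactMatch``.
* CrossRef: ``owl:sameAs`` on the ``dx.doi.org`` IRI.
"""

from __future__ import annotations

from dataclasses import dataclass

from rdflib import Graph, Literal, URIRef
from rdflib.namespace import OWL, SKOS, XSD

from . import vocab
from .records import DocumentRecord, MoleculeRecord, TargetRecord, TargetType
from .triplify import _descriptor_node, new_graph
from .uris import UriPolicy

GRADED_PREDICATES = (
    str(vocab.RDFS.seeAlso),
    str(SKOS.exactMatch),
    str(OWL.equivalentClass),
    str(OWL.sameAs),
)


@dataclass
class LinkRules:
    """IRI templates and the (configurable) Bio2RDF predicate."""

    chemspider_template: str = "http://rdf.chemspider.com/{csid}"
    bio2rdf_uniprot_template: str = "http://bio2rdf.org/uniprot:{accession}"
    bio2rdf_pubmed_template: str = "http://bio2rdf.org/pubmed:{pmid}"
    bio2rdf_predicate: URIRef = SKOS.exactMatch

    def __post_init__(self) -> None:
        if str(self.bio2rdf_predicate) not in GRADED_PREDICATES:
            raise ValueError(
                f"bio2rdf predicate must be one of the graded predicates, "
                f"got {self.bio2rdf_predicate}"
            )


DEFAULT_RULES = LinkRules()


def link_chemspider(
    mol: MoleculeRecord,
    csid: int,
    policy: UriPolicy,
    rules: LinkRules = DEFAULT_RULES,
) -> Graph:
    if csid <= 0:
        raise ValueError(f"invalid ChemSpider id {csid} for {mol.chembl_id}")
    g = new_graph()
    uri = policy.molecule_uri(mol.chembl_id)
    g.add((uri, SKOS.exactMatch,
           URIRef(rules.chemspider_template.format(csid=csid))))
    _descriptor_node(g, uri, vocab.CSID_DESCRIPTOR,
                     Literal(csid, datatype=XSD.integer))
    return g


def link_openmolecules(mol: MoleculeRecord, policy: UriPolicy) -> Graph:
    g = new_graph()
    if mol.inchi is None:
        return g
    inchi_iri = policy.inchi_uri(mol.inchi)
    if inchi_iri is None:  # overlong for the endpoint's URI limit
        return g
    g.add((policy.molecule_uri(mol.chembl_id), OWL.equivalentClass, inchi_iri))
    return g


def link_bio2rdf(
    entity: TargetRecord | DocumentRecord,
    policy: UriPolicy,
    rules: LinkRules = DEFAULT_RULES,
) -> Graph:
    g = new_graph()
    if isinstance(entity, TargetRecord):
        if entity.target_type is not TargetType.PROTEIN or entity.uniprot_accession is None:
            return g
        g.add((
            policy.target_uri(entity.target_id),
            rules.bio2rdf_predicate,
            URIRef(rules.bio2rdf_uniprot_template.format(
                accession=entity.uniprot_accession)),
        ))
    elif isinstance(entity, DocumentRecord):
        if entity.pmid is None:
            return g
        g.add((
            policy.document_uri(entity.doc_id),
            rules.bio2rdf_predicate,
            URIRef(rules.bio2rdf_pubmed_template.format(pmid=entity.pmid)),
        ))
    else:
        raise TypeError(f"cannot link entity of type {type(entity).__name__}")
    return g


def link_crossref(doc: DocumentRecord, policy: UriPolicy) -> Graph:
    g = new_graph()
    if doc.doi is None:
        return g
    g.add((policy.document_uri(doc.doc_id), OWL.sameAs, policy.doi_uri(doc.doi)))
    return g


def link_snapshot(
    snapshot,
    policy: UriPolicy,
    csid_mapping: dict[str, int] | None = None,
    rules: LinkRules = DEFAULT_RULES,
) -> Graph:
    """All link-outs for a snapshot; CSID mappings are an input table."""
    g = new_graph()
    csid_mapping = csid_mapping or {}
    for mol in snapshot.molecules:
        if mol.chembl_id in csid_mapping:
            g += link_chemspider(mol, csid_mapping[mol.chembl_id], policy, rules)
        g += link_openmolecules(mol, policy)
    for target in snapshot.targets:
        g += link_bio2rdf(target, policy, rules)
    for doc in snapshot.documents:
        g += link_bio2rdf(doc, policy, rules)
        g += link_crossref(doc, policy)
    vocab.bind_prefixes(g)
    return g
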