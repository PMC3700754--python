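"""Triple patterns: class/instance modelling, exclusions, conservation."""

import pytest
from rdflib import BNode, Literal, URIRef
from rdflib.compare import isomorphic
from rdflib.namespace import OWL, RDF, RDFS

from chemblrdf import (
    ActivityRecord,
    AssayRecord,
    AssayType,
    DocumentRecord,
    MoleculeRecord,
    MoleculeType,
    TargetAssignment,
    TargetRecord,
    TargetType,
    triplify_snapshot,
)
from chemblrdf import vocab
from chemblrdf.triplify import (
    attach_drug_role,
    triplify_activity,
    triplify_assay,
    triplify_descriptors,
    triplify_document,
    triplify_molecule,
    triplify_target,
)


def mol(**kwargs):
    defaults = dict(chembl_id="ChEMBL406142",
                    molecule_type=MoleculeType.SMALL_MOLECULE)
    defaults.update(kwargs)
    return MoleculeRecord(**defaults)


class TestMolecule:
    @pytest.mark.parametrize("mtype,superclass", [
        (MoleculeType.SMALL_MOLECULE, vocab.CHEMICAL_ENTITY),
        (MoleculeType.PROTEIN, vocab.PROTEIN_CLASS),
        (MoleculeType.PEPTIDE, vocab.PROTEIN_CLASS),
        (MoleculeType.ANTIBODY, vocab.PROTEIN_CLASS),
        (MoleculeType.OLIGOSACCHARIDE, vocab.OLIGOSACCHARIDE_CLASS),
        (MoleculeType.OLIGONUCLEOTIDE, vocab.OLIGONUCLEOTIDE_CLASS),
    ])
    def test_type_specific_superclass(self, policy, mtype, superclass):
        g = triplify_molecule(mol(molecule_type=mtype), policy)
        uri = policy.molecule_uri("ChEMBL406142")
        assert (uri, RDFS.subClassOf, superclass) in g

    @pytest.mark.parametrize("mtype", list(MoleculeType))
    def test_every_molecule_subclasses_material_entity(self, policy, mtype):
        g = triplify_molecule(mol(molecule_type=mtype), policy)
        uri = policy.molecule_uri("ChEMBL406142")
        assert (uri, RDFS.subClassOf, vocab.MATERIAL_ENTITY) in g

    def test_molecule_is_class_not_instance(self, policy):
        g = triplify_molecule(mol(), policy)
        uri = policy.molecule_uri("ChEMBL406142")
        assert (uri, RDF.type, vocab.CHEMICAL_ENTITY) not in g
        assert (uri, RDF.type, OWL.Class) in g

    def test_labels_from_name_and_synonyms(self, policy):
        g = triplify_molecule(mol(pref_name="Imatinib",
                                  synonyms=["STI-571", "Gleevec"]), policy)
        labels = set(g.objects(policy.molecule_uri("ChEMBL406142"), RDFS.label))
        assert labels == {Literal("Imatinib"), Literal("STI-571"),
                          Literal("Gleevec")}

    def test_unknown_molecule_type_is_error(self, policy):
        bad = mol()
        bad.molecule_type = "nanotube"
        with pytest.raises(ValueError, match="nanotube"):
            triplify_molecule(bad, policy)


class TestDrugRole:
    def test_not_approved_gives_empty_graph(self, policy):
        assert len(attach_drug_role(mol(approved_drug=False), policy)) == 0

    @pytest.mark.parametrize("mtype", [MoleculeType.SMALL_MOLECULE,
                                       MoleculeType.PROTEIN])
    def test_approved_gets_role_restriction(self, policy, mtype):
        g = attach_drug_role(mol(approved_drug=True, molecule_type=mtype),
                             policy)
        assert (None, OWL.someValuesFrom, vocab.DRUG_ROLE) in g
        assert (None, OWL.onProperty, vocab.HAS_ROLE) in g
        restriction = next(g.objects(policy.molecule_uri("ChEMBL406142"),
                                     RDFS.subClassOf))
        assert isinstance(restriction, BNode)


class TestDescriptors:
    def test_nothing_present_nothing_asserted(self, policy):
        assert len(triplify_descriptors(mol(), policy)) == 0

    def test_node_count_equals_present_field_count(self, policy):
        record = mol(smiles="CCO", inchi="InChI=1S/C2H6O/c1-2-3/h3H,2H2,1H3",
                     inchikey="LFQSCWFLJHTTHZ-UHFFFAOYSA-N",
                     properties={"alogp": (2.5, "ACD/Labs")})
        present = 4  # brute-force scan over the record's optional fields
        g = triplify_descriptors(record, policy)
        nodes = set(g.objects(policy.molecule_uri("ChEMBL406142"),
                              vocab.HAS_ATTRIBUTE))
        assert len(nodes) == present

    def test_each_identifier_gets_its_descriptor_class(self, policy):
        record = mol(inchi="InChI=1S/CH4/h1H4",
                     inchikey="VNWKTOKETHGBQD-UHFFFAOYSA-N")
        g = triplify_descriptors(record, policy)
        classes = {cls for node in g.objects(None, vocab.HAS_ATTRIBUTE)
                   for cls in g.objects(node, RDF.type)}
        assert classes == {vocab.INCHI_DESCRIPTOR, vocab.INCHIKEY_DESCRIPTOR}

    def test_property_value_with_software_provenance(self, policy):
        g = triplify_descriptors(mol(properties={"alogp": (2.5, "ACD/Labs")}),
                                 policy)
        node = next(g.objects(None, vocab.HAS_ATTRIBUTE))
        assert float(next(g.objects(node, vocab.HAS_VALUE))) == 2.5
        assert next(g.objects(node, vocab.HAS_SOURCE)) == Literal("ACD/Labs")

    def test_non_numeric_property_is_error(self, policy):
        with pytest.raises(ValueError, match="non-numeric"):
            triplify_descriptors(mol(properties={"alogp": ("high", None)}),
                                 policy)


class TestActivity:
    def make(self, **kwargs):
        defaults = dict(activity_id="a31863", assay_id="a1",
                        chembl_id="ChEMBL406142", activity_type="Potency",
                        std_value=12000.0, std_units="nM", relation="=",
                        doc_id=2032)
        defaults.update(kwargs)
        return ActivityRecord(**defaults)

    def test_core_pattern(self, policy):
        g = triplify_activity(self.make(), policy)
        uri = policy.activity_uri("a31863")
        assert (uri, RDF.type, vocab.ACTIVITY_CLASS) in g
        assert (uri, vocab.ACTIVITY_TYPE, Literal("Potency")) in g
        assert (uri, vocab.ON_ASSAY, policy.assay_uri("a1")) in g
        assert (uri, vocab.FOR_MOLECULE, policy.molecule_uri("ChEMBL406142")) in g
        assert (uri, vocab.CITES, policy.document_uri(2032)) in g

    def test_units_are_plain_string_literals(self, policy):
        g = triplify_activity(self.make(), policy)
        units = next(g.objects(None, vocab.STANDARD_UNITS))
        assert units == Literal("nM") and units.datatype is None

    def test_only_standardized_value_emitted(self, policy):
        # the source row also carries an original literature value; the
        # record type deliberately has no field for it, and the graph
        # carries exactly one value triple
        g = triplify_activity(self.make(std_value=42.0), policy)
        values = list(g.objects(None, vocab.STANDARD_VALUE))
        assert len(values) == 1 and float(values[0]) == 42.0


class TestAssay:
    def test_typeless_assay_skipped_entirely(self, policy):
        g = triplify_assay(AssayRecord("a1", None, "desc", 5), [], policy)
        assert len(g) == 0

    def test_two_targets_two_distinct_constructs(self, policy):
        assay = AssayRecord("a1", AssayType.BINDING, doc_id=5)
        assignments = [TargetAssignment("a1", "t1", 9),
                       TargetAssignment("a1", "t2", 4)]
        g = triplify_assay(assay, assignments, policy)
        constructs = list(g.objects(policy.assay_uri("a1"),
                                    vocab.HAS_TARGET_DESCRIPTION))
        assert len(set(constructs)) == 2
        # exhaustive traversal: each construct pairs one target, one score
        pairs = set()
        for node in constructs:
            targets = list(g.objects(node, vocab.HAS_TARGET))
            scores = list(g.objects(node, vocab.HAS_CONF_SCORE))
            assert len(targets) == 1 and len(scores) == 1
            pairs.add((str(targets[0]), int(scores[0])))
        assert pairs == {(str(policy.target_uri("t1")), 9),
                         (str(policy.target_uri("t2")), 4)}

    def test_zero_assignments_vacuous(self, policy):
        g = triplify_assay(AssayRecord("a1", AssayType.FUNCTIONAL, doc_id=5),
                           [], policy)
        assert (policy.assay_uri("a1"), RDF.type, vocab.ASSAY_CLASS) in g
        assert (None, vocab.HAS_TARGET_DESCRIPTION, None) not in g

    def test_assay_is_instance_not_class(self, policy):
        g = triplify_assay(AssayRecord("a1", AssayType.BINDING, doc_id=5),
                           [], policy)
        assert (policy.assay_uri("a1"), RDFS.subClassOf, None) not in g


class TestTarget:
    def test_protein_target_is_subclass_of_protein(self, policy):
        g = triplify_target(
            TargetRecord("t1", TargetType.PROTEIN, "CDK2", "P24941"), policy)
        uri = policy.target_uri("t1")
        assert (uri, RDFS.subClassOf, vocab.PROTEIN_CLASS) in g
        assert (uri, RDF.type, vocab.PROTEIN_CLASS) not in g

    @pytest.mark.parametrize("ttype,local", [
        (TargetType.UNKNOWN, "UNKNOWN"),
        (TargetType.UNCHECKED, "UNCHECKED"),
        (TargetType.ORGANISM, "ORGANISM"),
        (TargetType.CELL_LINE, "CELL-LINE"),
        (TargetType.NUCLEIC_ACID, "NUCLEIC-ACID"),
    ])
    def test_nonprotein_targets_are_explicitly_typed(self, policy, ttype, local):
        g = triplify_target(TargetRecord("t1", ttype, "x"), policy)
        assert (policy.target_uri("t1"), RDF.type, vocab.CHEMBL[local]) in g

    def test_all_targets_carry_common_target_marker(self, policy):
        for ttype in (TargetType.PROTEIN, TargetType.TISSUE):
            g = triplify_target(TargetRecord("t1", ttype, "x"), policy)
            uri = policy.target_uri("t1")
            assert (uri, RDF.type, vocab.TARGET_CLASS) in g or \
                   (uri, RDFS.subClassOf, vocab.TARGET_CLASS) in g


class TestDocument:
    def test_sentinel_doc_yields_no_triples(self, policy):
        assert len(triplify_document(DocumentRecord(doc_id=-1), policy)) == 0

    def test_pmid_and_doi_properties(self, policy):
        g = triplify_document(
            DocumentRecord(2032, pmid=8720442,
                           doi="10.1016/0960-894X(96)00111-4"), policy)
        uri = policy.document_uri(2032)
        assert (uri, RDF.type, vocab.BIBO.Article) in g
        assert (uri, vocab.BIBO.pmid, Literal("8720442")) in g
        assert (uri, vocab.BIBO.doi,
                Literal("10.1016/0960-894X(96)00111-4")) in g

    def test_identifierless_doc_still_typed(self, policy):
        g = triplify_document(DocumentRecord(7, title="No ids"), policy)
        uri = policy.document_uri(7)
        assert (uri, RDF.type, vocab.BIBO.Article) in g
        assert (uri, vocab.BIBO.pmid, None) not in g
        assert (uri, vocab.BIBO.doi, None) not in g


class TestSnapshotConversion:
    def test_empty_snapshot_empty_graph(self, policy):
        from chemblrdf import RelationalSnapshot
        assert len(triplify_snapshot(RelationalSnapshot(), policy)) == 0

    def test_counting_after_exclusion_rules(self, policy):
        from chemblrdf import RelationalSnapshot
        snapshot = RelationalSnapshot(
            molecules=[mol(chembl_id=f"ChEMBL{i}") for i in range(3)],
            assays=[AssayRecord("a1", AssayType.BINDING, doc_id=-1),
                    AssayRecord("a2", None, doc_id=-1)],
            documents=[DocumentRecord(-1), DocumentRecord(5)],
        )
        g = triplify_snapshot(snapshot, policy)
        assert len(set(g.subjects(RDF.type, OWL.Class))) == 3
        assert len(set(g.subjects(RDF.type, vocab.ASSAY_CLASS))) == 1
        assert len(set(g.subjects(RDF.type, vocab.BIBO.Article))) == 1

    def test_deterministic_up_to_blank_node_renaming(
            self, planted_snapshot, policy):
        g1 = triplify_snapshot(planted_snapshot, policy)
        g2 = triplify_snapshot(planted_snapshot, policy)
        assert isomorphic(g1, g2)

    def test_count_conservation(self, planted_snapshot, planted_graph, policy):
        mols = set(planted_graph.subjects(RDFS.subClassOf, vocab.MATERIAL_ENTITY))
        assert len(mols) == len(planted_snapshot.molecules)
        acts = set(planted_graph.subjects(RDF.type, vocab.ACTIVITY_CLASS))
        assert len(acts) == len(planted_snapshot.activities)
        assays = set(planted_graph.subjects(RDF.type, vocab.ASSAY_CLASS))
        assert len(assays) == (len(planted_snapshot.assays)
                               - planted_snapshot.typeless_assay_count)

    def test_every_subject_iri_is_minted_or_ontological(self, full_graph):
        from chemblrdf.uris import UriPolicy
        policy = UriPolicy()
        known_bases = tuple(str(ns) for ns in vocab.PREFIXES.values())
        for subject in full_graph.subjects(unique=True):
            if isinstance(subject, URIRef):
                assert str(subject).startswith(known_bases)

    def test_no_drug_role_for_non_approved(self, planted_snapshot,
                                           planted_graph, policy):
        role_subjects = {
            s for restriction in planted_graph.subjects(
                OWL.someValuesFrom, vocab.DRUG_ROLE)
            for s in planted_graph.subjects(RDFS.subClassOf, restriction)}
        approved = {str(policy.molecule_uri(m.chembl_id))
                    for m in planted_snapshot.molecules if m.approved_drug}
        assert {str(s) for s in role_subjects} == approved
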