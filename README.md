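# chemblrdf

Convert ChEMBL-schema relational bioactivity data into Linked Open Data
RDF, link it into the wider linked-data cloud, validate the conversion by
re-deriving release statistics with SPARQL-style counting, and query the
result for compound selectivity and literature-citation statistics.

## Who this is for

ChEMBL distributes curated bioactivity measurements (IC50, Ki, Potency,
…) for over a million compounds as a relational SQL dump. That format is
convenient for a single database server but awkward for data
integration: joining ChEMBL against UniProt, PubMed, ChemSpider or any
other resource means writing custom ETL for every pair of databases.
Publishing the same content as RDF triples — with shared ontologies and
dereferencable URIs — lets generic tooling (SPARQL engines, linked-data
browsers) traverse all of these resources at once. This package
implements that conversion for the ChEMBL 13 schema subset
(molecules, structures, calculated properties, assays, assay-to-target
assignments, targets, activities, documents), along with the
surrounding machinery a linked-data publisher needs.

## The conversion model

Entities are modelled with community ontologies where the semantics are
clear, and a small ad hoc `chembl:` vocabulary
(`http://rdf.farmbio.uu.se/chembl/onto/#`) where they are not:

* **Compounds are classes, not instances** (the CHEMINF convention).
  Small molecules subclass the CHEMINF chemical-entity class
  (`CHEMINF_000000`); proteins, peptides and antibodies subclass the
  PRotein Ontology protein class (`PR_000000001`); oligosaccharides and
  oligonucleotides subclass their ChEBI classes (`CHEBI_50699`,
  `CHEBI_7754`); everything additionally subclasses the BFO 1.1
  `MaterialEntity` root so a single query retrieves all entities with
  captured activities.
* **Approved drugs carry a role, not a type**: an existential
  restriction `has-role some CHEBI_23888` ("drug role") is attached to
  approved drugs only — a compound is a drug only in a therapeutic
  context.
* **Identifiers and properties use the CHEMINF/SIO descriptor pattern**:
  SMILES, InChI, InChIKey, logP etc. become typed descriptor nodes with
  a value and, where known, the software that computed it.
* **Activities carry only standardized values** (never the original
  literature value), with units and activity types as plain string
  literals; each activity cites its source document through CiTO.
* **Assay-to-target confidence** (0 = uncurated … 9 = direct single
  protein target) is attached per target via an intermediate construct
  node, since one assay can map to several targets with different
  confidence.
* **Documents** become `bibo:Article` resources with PMID/DOI
  properties. Two source-row classes never reach the graph: assays with
  an undefined assay type, and the sentinel "unpublished" document
  (`doc_id` −1).
* **Link-outs are graded by semantic strength**: ChemSpider mappings use
  `skos:exactMatch`, InChI-based OpenMolecules links use
  `owl:equivalentClass` (classes, not individuals), CrossRef DOI links
  use `owl:sameAs`, Bio2RDF UniProt/PubMed links default to
  `skos:exactMatch`. InChI-based IRIs are only minted when they fit a
  configurable URI length cap (default 2000 characters).

Validation re-derives five per-class counts from the emitted graph by
SPARQL and compares them with source row counts. The expected deltas
are part of the contract: assays lower by exactly the number of
typeless rows, articles lower by exactly one when the sentinel is
present, everything else conserved exactly. Against a full ChEMBL 13
conversion the expected graph counts are 8,845 targets; 1,143,682
material entities; 617,676 assays; 6,933,068 activities; 44,681
articles.

## Worked example

```bash
# 1. generate a synthetic snapshot: 100 assays of which 5 lack a type,
#    the sentinel document, and 7 planted CDK2-selective binders
chemblrdf make-fixture --out demo --seed 11 --molecules 40 --assays 100 \
    --activities 200 --fraction-missing-type 0.05 --plant-selectivity 7

# 2. convert to N-Triples (streaming, with link-outs)
chemblrdf convert --input demo --output demo.nt

# 3. validate the conversion against the source tables
chemblrdf validate --input demo --triples demo.nt
```

The validation step prints:

```
class                   source     graph   delta  expected
targets                     10        10       0         0
material_entities           40        40       0         0
assays                     100        95       5         5
activities                 200       200       0         0
articles                     8         7       1         1
result: PASS
```

meaning: all 40 molecules and 200 activities were conserved exactly, 5
assays were (correctly) skipped for having no assay type, and one
document row (the sentinel) produced no article.

```bash
# 4. which molecules bind CDK2 (IC50 < 50 nM) but not CDK4 (> 200 nM)?
chemblrdf query-selectivity --triples demo.nt \
    --target-a P24941 --target-b P11802
```

prints the 7 planted molecule IRIs, e.g.
`http://linkedchemistry.info/chembl/molecule/ChEMBL400003`, and
`7 selective molecules` on stderr.

```bash
# 5. serve dereferencable descriptions with content negotiation
chemblrdf serve --triples demo.nt --port 8080 &
curl -H "Accept: text/turtle" http://localhost:8080/molecule/ChEMBL400003
```

returns the molecule's bounded description (class axioms, labels,
descriptor nodes, link-outs) as Turtle; without the Accept header the
same URL renders an HTML triple table.

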