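# Methods

This note records how the conversion is defined, what the synthetic
data emulates, and the numerical and design choices a maintainer would
want to know about.

## Conversion rules

The converter consumes an in-memory image of the eight relational
tables it needs (`molecule_dictionary`, `compound_structures`,
`compound_properties`, `assays`, `assay2target`, `target_dictionary`,
`activities`, `docs`) and emits one small RDF graph per record; the
snapshot-level conversion is the union, so the output is deterministic
up to blank-node naming. Referential integrity is checked before any
triple is emitted and violations are fatal, naming the offending keys.
The `doc_id` −1 sentinel resolves even without a `docs` row, since it
denotes "unpublished" rather than a record.

Two rules remove source rows from the graph, and only these two:

* an assay whose `assay_type` is undefined produces no triples;
* the sentinel document produces no `bibo:Article`.

Everything else is conserved 1:1, which is what the count-based
validation asserts. Activities and assays still *cite* the sentinel
resource (`res:r-1`) so that every activity carries a citation edge;
the sentinel is simply never typed as an article.

Class/instance split: compounds and protein targets are OWL classes
(`rdfs:subClassOf` axioms to `CHEMINF_000000`, `PR_000000001`,
`CHEBI_50699`, `CHEBI_7754`); assays, activities and articles are
instances (`rdf:type`). Cell-type compounds have no community-ontology
match and subclass only the `MaterialEntity` root. Each compound gets a
*direct* `rdfs:subClassOf bfo:MaterialEntity` triple in addition to its
type-specific superclass: this keeps the material-entity count query a
single-pattern SPARQL match that returns exactly the converted
compounds, with no ontology-level classes or protein targets leaking
into the count.

Protein targets subclass both `PR_000000001` and `chembl:Target`;
non-protein targets get explicit `rdf:type` assertions to their
category (`chembl:ORGANISM`, `chembl:UNKNOWN`, …) and to
`chembl:Target`. The common `chembl:Target` marker is what makes a
single target count query possible; the target count query therefore
matches the union of the instance-style and class-style forms. The
PRotein Ontology protein class appears in upstream materials under two
spellings (`PR_000000001` and `PR_0000001`); this package uses the
canonical `PR_000000001` everywhere.

Predicates that have no community term (`chembl:onAssay`,
`chembl:forMolecule`, `chembl:hasTargetDescription`, `chembl:hasTarget`,
`chembl:hasConfScore`, …) live in one vocabulary module
(`chemblrdf.vocab`) under the ad hoc namespace, named after the
relational columns they reflect, so they can be swapped centrally. The
same applies to the CHEMINF descriptor class codes and the SIO
attribute/value/provenance properties (`SIO_000008`, `SIO_000300`,
`SIO_000253`): the codes shipped are documented defaults, not claims
about the one true modelling.

The citation property is `cito:citesAsDataSource` — the CiTO term for a
citation whose citing entity uses the cited work as a data source,
which is exactly the relation between a bioactivity record and the
paper it was extracted from.

## Numeric literals

Standardized activity values and calculated properties are emitted as
`xsd:decimal` typed literals built from the value's shortest `repr`.
`xsd:double` was considered and rejected: Turtle serializers normalize
double lexical forms through scientific notation with limited
precision, so values with more than seven significant digits would not
survive a serialization round trip, and loss-free round-tripping is a
hard requirement here (it is tested by graph isomorphism in both
Turtle and N-Triples). `xsd:decimal` preserves the printed precision
exactly and compares numerically in SPARQL filters just the same.
Confidence scores are `xsd:integer`; units, relations and activity
types are plain string literals by design — unit semantics
(nM vs µg/ml) are deliberately left unmodelled, so the selectivity
query requires an exact unit string match and raises an error when the
queried activity type appears under a different unit on the queried
targets, rather than silently dropping those measurements.

## URI policy

Data IRIs live under `http://linkedchemistry.info/chembl/` with path
namespaces `activity/`, `assay/`, `molecule/`, `resource/`, `target/`
(the `target/` namespace follows the same pattern as the documented
four; document resources are minted as `resource/r<doc_id>`). A legacy
mode substitutes the `data.kasabi.com/dataset/chembl-rdf/` root for
consumers of the older hosting pattern. Local ids are percent-encoded
per RFC 3986 (never truncated), which keeps minting injective.

InChI-based IRIs are `http://rdf.openmolecules.net/?` + the
percent-encoded InChI, keeping `= / ? , ( )` unencoded so the layer
structure stays readable. IRIs longer than `max_uri_length` (default
2000 characters — a conservative bound below common server limits, and
configurable) are not minted at all; a malformed InChI is an error, not
an absent link, so invalid input cannot masquerade as an overlong one.

The dereferencing proxy translation is bijective between canonical
IRIs and local URLs; the reverse direction additionally accepts
configured path aliases (by default `article/` resolves the
`activity/` namespace, reproducing the historical web-app layout).

## Synthetic snapshots

The generator is a pure function of its config (single integer seed
threaded through all tables). It emulates the features the conversion
and queries are sensitive to:

* compound-type mix dominated by small molecules (90%), with peptides,
  proteins, antibodies, oligosaccharides, oligonucleotides and cells in
  the tail; ~10% approved drugs by default;
* SMILES/InChI/InChIKey for structurally defined compounds, with a
  configurable fraction of InChIs padded past the URI length cap;
  calculated properties (logP, molecular weight) with software tags;
* assays with the five release assay-type codes and a configurable
  fraction with *no* type (exactly `ceil(fraction × n_assays)` rows);
* per-target confidence scores over the full 0–9 range;
* activity types drawn from the release's published shares (Potency
  43%, IC50 13%, MIC 4.6%, Inhibition 3.7%, Ki 3.6%), with named
  stand-ins for the long tail of minor types so the shares are true
  percentages; standardized values with string units;
* documents with PMIDs and DOIs, and optionally the sentinel row.

A selectivity scenario can be planted: k molecules get an IC50 of
10 nM on a synthetic CDK2 analogue (accession P24941) and 500 nM on a
CDK4 analogue (P11802), through dedicated confidence-9 binding assays.
The two planted targets are reserved — background assays never map to
them — so the planted set is provably the exact answer to the
corresponding query (< 50 nM on A, > 200 nM on B), which is what the
oracle-equivalence tests exploit. Boundary probes replace the planted
values with ones sitting exactly on a threshold to confirm the strict
inequalities.

What the generator does **not** emulate: real chemical structures
(InChIs are syntactically shaped but chemically meaningless), mixed
units for one activity type on one target, curation artifacts such as
duplicate near-identical measurements, and the full scale of a release
(tests run at tens-to-hundreds of rows; the acceptance script at 200
molecules / 2,000 activities). Passing tests therefore demonstrate the
correctness of the mapping, exclusion, counting and query logic — not
robustness against real-data curation noise, which only a full-dump
conversion exercises. The validation report prints the ChEMBL 13
reference counts as the expected outputs of such a full-scale run.

## Queries

The selectivity, citation-count and frequency queries are executed as
SPARQL over the in-memory graph, and the same query texts are exported
as parameterized templates for use against any endpoint hosting the
triples. The selectivity query uses existential semantics (any
qualifying measurement counts), strict threshold inequalities, and
returns distinct molecules (not measurement pairs). The confidence
filter is off by default — matching the documented use case, which
ignores it to maximize recall — and when set, constrains the
assay-to-target construct on both arms; raising it can only shrink the
result set. Target references may be given as IRI, local id, or
UniProt accession (resolved through the Bio2RDF link-out triples, so
accession-based queries need the link graph loaded).

## Serving

The dereferencing layer returns concise bounded descriptions: all
triples with the resource as subject, expanded transitively through
blank-node objects so confidence constructs and descriptor nodes are
delivered whole. Content negotiation maps RDF media types to Turtle or
N-Triples and everything else (including no header) to a plain HTML
triple table — deliberately not RDFa, which belongs to heavier
web-application layers out of scope here. N-Triples is the bulk dump
format (line-oriented, streamable record-at-a-time, diff-friendly);
Turtle serves human-facing output.

## Known limitations

* Activity types and units are strings; no BioAssay-Ontology or QUDT
  alignment, hence no reasoning across related endpoint types or unit
  conversion.
* The embedded-SQL dialect reads the eight-table subset with the
  package's own column layout; it does not parse the full MySQL DDL of
  a release dump.
* Blank-node-based constructs mean per-record graphs must be compared
  by isomorphism, not syntactic equality.
* The HTML rendering is a diagnostic view, not a styled report card.
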