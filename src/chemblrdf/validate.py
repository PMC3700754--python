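"""Release-statistics validation by SPARQL-style counting.

The conversion is validated by re-deriving per-class entity counts from
the emitted graph with SPARQL count queries and comparing them with row
counts of the relational source.  The counts must agree exactly, except
for two documented systematic deltas:

* assays: rows without a defined assay type are never converted, so the
  graph count is lower by exactly the number of typeless rows;
* articles: the sentinel "unpublished" document (doc_id -1) is not a
  valid article, so the graph count is lower by one when it is present.

Counting is done against the graph (distinct-subject SPARQL queries),
not by re-counting records, so it genuinely validates the conversion.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from rdflib import Graph

from .snapshot import RelationalSnapshot

#: printed release statistics of ChEMBL 13, as expected graph counts when
#: validating a conversion of the real dump (reference metadata)
CHEMBL13_REFERENCE_COUNTS = {
    "targets": 8_845,
    "material_entities": 1_143_682,
    "assays": 617_676,
    "activities": 6_933_068,
    "articles": 44_681,
}
#: relational row counts printed with the same release
CHEMBL13_SOURCE_COUNTS = {
    "targets": 8_845,
    "material_entities": 1_143_682,
    "assays": 617_681,
    "activities": 6_933_068,
    "articles": 44_682,
}


class ClassKind(enum.Enum):
    TARGET = "Target"
    MATERIAL_ENTITY = "MaterialEntity"
    ASSAY = "Assay"
    ACTIVITY = "Activity"
    ARTICLE = "Article"


_PREFIX_BLOCK = """\
PREFIX rdf: <http://www.w3.org/1999/02/22-rdf-syntax-ns#>
PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>
PREFIX chembl: <http://rdf.farmbio.uu.se/chembl/onto/#>
PREFIX bfo: <http://www.ifomis.org/bfo/1.1/snap#>
PREFIX bibo: <http://purl.org/ontology/bibo/>
"""

#: the count queries; targets are counted whether class-styled (protein
#: targets subclass chembl:Target) or instance-styled (all other kinds)
COUNT_QUERIES: dict[ClassKind, str] = {
    ClassKind.TARGET: _PREFIX_BLOCK + """
SELECT (COUNT(DISTINCT ?t) AS ?n) WHERE {
  { ?t rdf:type chembl:Target } UNION { ?t rdfs:subClassOf chembl:Target }
}""",
    ClassKind.MATERIAL_ENTITY: _PREFIX_BLOCK + """
SELECT (COUNT(DISTINCT ?m) AS ?n) WHERE {
  ?m rdfs:subClassOf bfo:MaterialEntity .
}""",
    ClassKind.ASSAY: _PREFIX_BLOCK + """
SELECT (COUNT(DISTINCT ?a) AS ?n) WHERE { ?a rdf:type chembl:Assay }""",
    ClassKind.ACTIVITY: _PREFIX_BLOCK + """
SELECT (COUNT(DISTINCT ?a) AS ?n) WHERE { ?a rdf:type chembl:Activity }""",
    ClassKind.ARTICLE: _PREFIX_BLOCK + """
SELECT (COUNT(DISTINCT ?d) AS ?n) WHERE { ?d rdf:type bibo:Article }""",
}

_KIND_KEYS = {
    ClassKind.TARGET: "targets",
    ClassKind.MATERIAL_ENTITY: "material_entities",
    ClassKind.ASSAY: "assays",
    ClassKind.ACTIVITY: "activities",
    ClassKind.ARTICLE: "articles",
}


def count_class(graph: Graph, class_kind: ClassKind) -> int:
    """Distinct resources of one class kind, via its SPARQL count query."""
    result = graph.query(COUNT_QUERIES[class_kind])
    (row,) = list(result)
    return int(row[0])


@dataclass
class ValidationReport:
    counts: dict[str, int]
    source_counts: dict[str, int]
    expected_deltas: dict[str, int]
    diagnostics: list[str] = field(default_factory=list)

    @property
    def deltas(self) -> dict[str, int]:
        return {k: self.source_counts[k] - self.counts[k] for k in self.counts}

    @property
    def passed(self) -> bool:
        return not self.diagnostics

    def to_dict(self) -> dict:
        return {
            "counts": self.counts,
            "source_counts": self.source_counts,
            "deltas": self.deltas,
            "expected_deltas": self.expected_deltas,
            "passed": self.passed,
            "diagnostics": self.diagnostics,
        }

    def to_text(self) -> str:
        lines = [
            f"{'class':<20}{'source':>10}{'graph':>10}{'delta':>8}{'expected':>10}"
        ]
        for key in self.counts:
            lines.append(
                f"{key:<20}{self.source_counts[key]:>10}{self.counts[key]:>10}"
                f"{self.deltas[key]:>8}{self.expected_deltas[key]:>10}"
            )
        lines.append("result: " + ("PASS" if self.passed else "FAIL"))
        lines.extend("  " + d for d in self.diagnostics)
        lines.append(
            "reference (full ChEMBL 13 conversion): "
            + ", ".join(f"{k}={v:,}" for k, v in CHEMBL13_REFERENCE_COUNTS.items())
        )
        return "\n".join(lines)


def validate(snapshot: RelationalSnapshot, graph: Graph) -> ValidationReport:
    """Compare graph counts with source row counts.

    PASS iff the deltas are exactly: 0 for targets, material entities and
    activities; the number of typeless assay rows for assays; and 1 for
    articles when the sentinel document is present (else 0).
    """
    source_counts = {
        "targets": len(snapshot.targets),
        "material_entities": len(snapshot.molecules),
        "assays": len(snapshot.assays),
        "activities": len(snapshot.activities),
        "articles": len(snapshot.documents),
    }
    counts = {
        _KIND_KEYS[kind]: count_class(graph, kind) for kind in ClassKind
    }
    expected_deltas = {
        "targets": 0,
        "material_entities": 0,
        "assays": snapshot.typeless_assay_count,
        "activities": 0,
        "articles": 1 if snapshot.has_sentinel_doc else 0,
    }
    diagnostics = [
        f"{key}: source {source_counts[key]} - graph {counts[key]} = "
        f"{source_counts[key] - counts[key]}, expected delta {expected}"
        for key, expected in expected_deltas.items()
        if source_counts[key] - counts[key] != expected
    ]
    return ValidationReport(counts, source_counts, expected_deltas, diagnostics)
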