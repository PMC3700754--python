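"""Application queries over a converted graph.

* ``selective_binders`` — molecules with high affinity against protein A
  (activity value strictly below a bound) and low affinity against
  protein B (strictly above a bound), for one activity type, optionally
  filtered by the assay-to-target confidence score (0 = uncurated,
  9 = direct single protein target).
* ``citation_count`` — how many distinct resources of any kind cite a
  document, the basis for database-citation statistics.
* ``activity_type_frequencies`` — the activity-type tally with
  percentage shares.

Each query is also exported as a parameterized SPARQL template so the
same logic can run against any endpoint hosting the triples.  Units are
matched as exact strings; there is deliberately no unit conversion, and
a unit mismatch between query and data is an error rather than a silent
miss.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from rdflib import Graph, Literal, URIRef

from . import vocab
from .uris import UriPolicy

_PREFIXES = """\
PREFIX rdf: <http://www.w3.org/1999/02/22-rdf-syntax-ns#>
PREFIX chembl: <http://rdf.farmbio.uu.se/chembl/onto/#>
PREFIX cito: <http://purl.org/spar/cito/>
PREFIX xsd: <http://www.w3.org/2001/XMLSchema#>
"""

#: one arm of the selectivity join: an activity of $type on an assay
#: mapped to the given target, with a value constraint
_SELECTIVITY_ARM = """
  ?assay{side} chembl:hasTargetDescription ?td{side} .
  ?td{side} chembl:hasTarget {target} .
  {confidence}
  ?act{side} chembl:onAssay ?assay{side} ;
             chembl:type {activity_type} ;
             chembl:standardUnits {units} ;
             chembl:standardValue ?value{side} ;
             chembl:forMolecule ?mol .
  FILTER (?value{side} {op} {bound})
"""

SELECTIVITY_SPARQL_TEMPLATE = (
    _PREFIXES
    + "SELECT DISTINCT ?mol WHERE {"
    + _SELECTIVITY_ARM.replace("{side}", "A").replace("{op}", "<")
    + _SELECTIVITY_ARM.replace("{side}", "B").replace("{op}", ">")
    + "}"
)

_CONFIDENCE_CLAUSE = (
    "?td{side} chembl:hasConfScore ?score{side} . "
    "FILTER (?score{side} >= {min_confidence})"
)

CITATION_COUNT_SPARQL_TEMPLATE = _PREFIXES + """
SELECT (COUNT(DISTINCT ?citer) AS ?n) WHERE {
  ?citer cito:citesAsDataSource {document} .
}"""

ACTIVITY_TYPE_SPARQL = _PREFIXES + """
SELECT ?type (COUNT(?act) AS ?n) WHERE {
  ?act rdf:type chembl:Activity ; chembl:type ?type .
} GROUP BY ?type ORDER BY DESC(?n) ?type"""

_UNITS_AUDIT_QUERY = _PREFIXES + """
SELECT DISTINCT ?units WHERE {
  ?assay chembl:hasTargetDescription ?td .
  ?td chembl:hasTarget {target} .
  ?act chembl:onAssay ?assay ;
       chembl:type {activity_type} ;
       chembl:standardUnits ?units .
}"""


class UnknownTargetError(ValueError):
    pass


class UnitMismatchError(ValueError):
    """Data holds the queried activity type in different units; comparing
    values across units without conversion would be meaningless."""


@dataclass
class SelectivityQuery:
    target_a: str  # IRI, target id, or UniProt accession
    target_b: str
    activity_type: str = "IC50"
    threshold_a: float = 50.0   # strict <, high-affinity bound on A
    threshold_b: float = 200.0  # strict >, low-affinity bound on B
    units: str = "nM"
    min_confidence: Optional[int] = None

    def __post_init__(self) -> None:
        if self.threshold_a <= 0 or self.threshold_b <= 0:
            raise ValueError("thresholds must be positive")
        if self.min_confidence is not None and not 0 <= self.min_confidence <= 9:
            raise ValueError("min_confidence must lie in 0-9 or be None")


def resolve_target(graph: Graph, ref: str, policy: UriPolicy) -> URIRef:
    """Resolve a target reference (IRI, local id, or UniProt accession
    via its link-out triple) to a target IRI present in the graph."""
    candidates: list[URIRef] = []
    if ref.startswith("http://") or ref.startswith("https://"):
        candidates.append(URIRef(ref))
    else:
        candidates.append(policy.target_uri(ref))
        # accession path: follow the Bio2RDF UniProt link-out backwards
        accession_iri = URIRef(f"http://bio2rdf.org/uniprot:{ref}")
        candidates.extend(
            s for s, _, _ in graph.triples((None, None, accession_iri))
        )
    for candidate in candidates:
        if (candidate, None, None) in graph or (None, None, candidate) in graph:
            return candidate
    raise UnknownTargetError(f"target {ref!r} not present in graph")


def _fill(template: str, **values: str) -> str:
    for key, value in values.items():
        template = template.replace("{" + key + "}", value)
    return template


def _audit_units(graph: Graph, target: URIRef, q: SelectivityQuery) -> None:
    query = _fill(
        _UNITS_AUDIT_QUERY,
        target=target.n3(),
        activity_type=Literal(q.activity_type).n3(),
    )
    found = {str(row[0]) for row in graph.query(query)}
    stray = found - {q.units}
    if stray:
        raise UnitMismatchError(
            f"activities of type {q.activity_type!r} against {target} use "
            f"units {sorted(stray)}; query expects {q.units!r} and no unit "
            "conversion is performed"
        )


def render_selectivity_sparql(
    q: SelectivityQuery, target_a: URIRef, target_b: URIRef
) -> str:
    if q.min_confidence is None:
        conf_a = conf_b = ""
    else:
        conf_a = _fill(_CONFIDENCE_CLAUSE.replace("{side}", "A"),
                       min_confidence=str(q.min_confidence))
        conf_b = _fill(_CONFIDENCE_CLAUSE.replace("{side}", "B"),
                       min_confidence=str(q.min_confidence))
    query = _fill(SELECTIVITY_SPARQL_TEMPLATE,
                  activity_type=Literal(q.activity_type).n3(),
                  units=Literal(q.units).n3())
    query = query.replace("{target}", target_a.n3(), 1)
    query = query.replace("{target}", target_b.n3(), 1)
    query = query.replace("{confidence}", conf_a, 1)
    query = query.replace("{confidence}", conf_b, 1)
    query = query.replace("{bound}", repr(float(q.threshold_a)), 1)
    query = query.replace("{bound}", repr(float(q.threshold_b)), 1)
    return query


def selective_binders(
    graph: Graph, q: SelectivityQuery, policy: UriPolicy | None = None
) -> set[URIRef]:
    """Distinct molecules selective for target A over target B."""
    policy = policy or UriPolicy()
    target_a = resolve_target(graph, q.target_a, policy)
    target_b = resolve_target(graph, q.target_b, policy)
    _audit_units(graph, target_a, q)
    _audit_units(graph, target_b, q)
    query = render_selectivity_sparql(q, target_a, target_b)
    return {row[0] for row in graph.query(query)}


def citation_count(graph: Graph, doc: URIRef | str) -> int:
    """Distinct resources of any kind citing the document."""
    query = _fill(CITATION_COUNT_SPARQL_TEMPLATE, document=URIRef(doc).n3())
    (row,) = list(graph.query(query))
    return int(row[0])


def activity_type_frequencies(graph: Graph) -> list[tuple[str, int, float]]:
    """(type, count, percentage) descending by count; percentages are
    reported to one decimal place."""
    tallies = [(str(row[0]), int(row[1])) for row in graph.query(ACTIVITY_TYPE_SPARQL)]
    total = sum(n for _, n in tallies)
    return [
        (type_, n, round(100.0 * n / total, 1)) for type_, n in tallies
    ]
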