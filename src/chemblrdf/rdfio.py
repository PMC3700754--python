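"""RDF serialization, parsing, bounded descriptions, content negotiation.

N-Triples is the bulk dump format (line-oriented, diff-friendly); Turtle
serves human-facing output.  Both are round-trip safe including literals
with quotes, newlines and non-ASCII text — serializer escaping is
delegated to rdflib rather than hand-rolled.
"""

from __future__ import annotations

import enum
import html as _html
from typing import Iterable

from rdflib import Graph, URIRef

from .vocab import bind_prefixes


class SerializationFormat(enum.Enum):
    TURTLE = "turtle"
    NTRIPLES = "nt"

    @property
    def media_type(self) -> str:
        return {
            SerializationFormat.TURTLE: "text/turtle",
            SerializationFormat.NTRIPLES: "application/n-triples",
        }[self]

    @property
    def extension(self) -> str:
        return {SerializationFormat.TURTLE: ".ttl",
                SerializationFormat.NTRIPLES: ".nt"}[self]


class HtmlFormat(enum.Enum):
    """Marker for a human-readable HTML rendering (not an RDF format)."""

    HTML = "html"

    @property
    def media_type(self) -> str:
        return "text/html"


class RdfSyntaxError(ValueError):
    """Input document is not well-formed RDF."""


def serialize(graph: Graph, fmt: SerializationFormat) -> bytes:
    bind_prefixes(graph)
    return graph.serialize(format=fmt.value, encoding="utf-8")


def parse(data: bytes | str, fmt: SerializationFormat) -> Graph:
    g = Graph()
    if isinstance(data, bytes):
        data = data.decode("utf-8")
    try:
        g.parse(data=data, format=fmt.value)
    except Exception as exc:  # rdflib raises format-specific errors
        raise RdfSyntaxError(f"{fmt.value} syntax error: {exc}") from exc
    bind_prefixes(g)
    return g


def describe_resource(graph: Graph, uri: URIRef | str) -> Graph:
    """Concise bounded description: all triples with the resource as
    subject, expanded transitively through blank-node objects so that
    confidence constructs and descriptor nodes come out whole.  Unknown
    resources yield an empty graph."""
    description = graph.cbd(URIRef(uri))
    bind_prefixes(description)
    return description


# -- content negotiation ---------------------------------------------------

_MEDIA_TYPES = {
    "text/turtle": SerializationFormat.TURTLE,
    "application/x-turtle": SerializationFormat.TURTLE,
    "application/turtle": SerializationFormat.TURTLE,
    "application/n-triples": SerializationFormat.NTRIPLES,
    "text/n-triples": SerializationFormat.NTRIPLES,
    # generic RDF requests get the human-facing RDF format
    "application/rdf+xml": SerializationFormat.TURTLE,
}


def _accept_entries(header: str) -> Iterable[tuple[float, str]]:
    for i, part in enumerate(header.split(",")):
        part = part.strip()
        if not part:
            continue
        media, *params = (p.strip() for p in part.split(";"))
        q = 1.0
        for param in params:
            if param.startswith("q="):
                try:
                    q = float(param[2:])
                except ValueError:
                    q = 0.0
        # stable order: quality desc, then position in the header
        yield (-q, i), media.lower()


def negotiate(accept_header: str | None) -> SerializationFormat | HtmlFormat:
    """Map an HTTP Accept header to a response format.

    RDF media types select the matching RDF serialization; anything else
    — including an absent header and unknown media types — defaults to
    the HTML rendering.
    """
    if not accept_header:
        return HtmlFormat.HTML
    for _, media in sorted(_accept_entries(accept_header)):
        if media in _MEDIA_TYPES:
            return _MEDIA_TYPES[media]
        if media in ("text/html", "application/xhtml+xml"):
            return HtmlFormat.HTML
    return HtmlFormat.HTML


def render_html(description: Graph, uri: str) -> bytes:
    """Plain triple table for browsers (no RDFa)."""
    rows = []
    for s, p, o in sorted(description):
        rows.append(
            "<tr><td>{}</td><td>{}</td><td>{}</td></tr>".format(
                _html.escape(str(s)), _html.escape(str(p)), _html.escape(str(o))
            )
        )
    body = (
        "<!DOCTYPE html><html><head><meta charset='utf-8'>"
        f"<title>{_html.escape(uri)}</title></head><body>"
        f"<h1>{_html.escape(uri)}</h1>"
        "<table border='1'><tr><th>subject</th><th>predicate</th>"
        "<th>object</th></tr>" + "".join(rows) + "</table></body></html>"
    )
    return body.encode("utf-8")
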