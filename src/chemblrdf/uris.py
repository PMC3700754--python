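"""IRI minting and translation policy.

All data resources live under one of five path namespaces
(``activity/``, ``assay/``, ``molecule/``, ``resource/``, ``target/``)
below a common data root.  Two roots are supported: the canonical
``linkedchemistry.info/chembl`` one, and a legacy root where that prefix
is replaced by ``data.kasabi.com/dataset/chembl-rdf`` (the URI pattern of
the retired Kasabi hosting platform, still used by the Uppsala SPARQL
endpoint).

InChI-based external IRIs are additionally subject to a length cap: some
triple-store software only supports URIs up to a certain length, so links
for molecules whose encoded InChI IRI exceeds the cap are simply not
minted.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from urllib.parse import quote, unquote

from rdflib import URIRef

from .vocab import CANONICAL_DATA_ROOT, LEGACY_DATA_ROOT, PREFIXES

#: characters beyond RFC 3986 unreserved that stay readable in InChI IRIs
_INCHI_SAFE = "=/?,()"
#: characters safe in a DOI when embedded in an http IRI path
_DOI_SAFE = "/()+:@;$!*,&'="


class UriMode(enum.Enum):
    CANONICAL = "canonical"
    LEGACY = "legacy"


class ResourceKind(enum.Enum):
    ACTIVITY = "activity"
    ASSAY = "assay"
    MOLECULE = "molecule"
    RESOURCE = "resource"
    TARGET = "target"


class UnregisteredNamespaceError(ValueError):
    """An IRI does not fall under any namespace known to the policy."""


def _default_namespaces() -> dict[str, str]:
    return {prefix: str(ns) for prefix, ns in PREFIXES.items()}


def _default_aliases() -> dict[str, ResourceKind]:
    aliases = {kind.value: kind for kind in ResourceKind}
    # legacy web-app path segment historically served activity resources
    aliases["article"] = ResourceKind.ACTIVITY
    return aliases


@dataclass
class UriPolicy:
    """Namespace table plus minting, InChI and proxy-translation rules."""

    namespaces: dict[str, str] = field(default_factory=_default_namespaces)
    mode: UriMode = UriMode.CANONICAL
    inchi_uri_base: str = "http://rdf.openmolecules.net/?"
    max_uri_length: int = 2000
    #: proxy path segment -> resource kind (extra aliases allowed backward)
    proxy_aliases: dict[str, ResourceKind] = field(default_factory=_default_aliases)

    def __post_init__(self) -> None:
        if self.max_uri_length <= 0:
            raise ValueError("max_uri_length must be positive")
        for prefix, base in self.namespaces.items():
            if not base.endswith(("/", "#")):
                raise ValueError(
                    f"namespace base for {prefix!r} must end in '/' or '#': {base}"
                )

    # -- minting -----------------------------------------------------------

    def base(self, kind: ResourceKind) -> str:
        base = CANONICAL_DATA_ROOT + kind.value + "/"
        if self.mode is UriMode.LEGACY:
            base = base.replace(CANONICAL_DATA_ROOT, LEGACY_DATA_ROOT)
        return base

    def mint_uri(self, kind: ResourceKind, local_id: str) -> URIRef:
        if not local_id or any(c.isspace() for c in local_id):
            raise ValueError(f"invalid local id {local_id!r}")
        return URIRef(self.base(kind) + quote(local_id, safe=""))

    def activity_uri(self, activity_id: str) -> URIRef:
        return self.mint_uri(ResourceKind.ACTIVITY, activity_id)

    def assay_uri(self, assay_id: str) -> URIRef:
        return self.mint_uri(ResourceKind.ASSAY, assay_id)

    def molecule_uri(self, chembl_id: str) -> URIRef:
        return self.mint_uri(ResourceKind.MOLECULE, chembl_id)

    def target_uri(self, target_id: str) -> URIRef:
        return self.mint_uri(ResourceKind.TARGET, target_id)

    def document_uri(self, doc_id: int) -> URIRef:
        return self.mint_uri(ResourceKind.RESOURCE, f"r{doc_id}")

    # -- InChI link IRIs ----------------------------------------------------

    def inchi_uri(self, inchi: str) -> URIRef | None:
        """InChI-based IRI, or ``None`` when it would exceed the length cap."""
        if not inchi.startswith("InChI="):
            raise ValueError(f"not an InChI string: {inchi[:30]!r}")
        iri = self.inchi_uri_base + quote(inchi, safe=_INCHI_SAFE)
        if len(iri) > self.max_uri_length:
            return None
        return URIRef(iri)

    def doi_uri(self, doi: str) -> URIRef:
        return URIRef("http://dx.doi.org/" + quote(doi, safe=_DOI_SAFE))

    # -- proxy translation --------------------------------------------------

    def split(self, uri: str) -> tuple[ResourceKind, str]:
        """Resolve an IRI to (kind, local id); error if unregistered."""
        for root in (CANONICAL_DATA_ROOT, LEGACY_DATA_ROOT):
            for kind in ResourceKind:
                base = root + kind.value + "/"
                if uri.startswith(base):
                    return kind, uri[len(base):]
        raise UnregisteredNamespaceError(
            f"IRI outside all registered namespaces: {uri}"
        )

    def translate_for_proxy(self, uri: str, local_base: str) -> str:
        """Canonical IRI -> URL rooted at a local dereferencing proxy."""
        kind, local_id = self.split(uri)
        if not local_base.endswith("/"):
            local_base += "/"
        return local_base + kind.value + "/" + local_id

    def translate_from_proxy(self, url: str, local_base: str) -> str:
        """Inverse of :meth:`translate_for_proxy` (accepts path aliases)."""
        if not local_base.endswith("/"):
            local_base += "/"
        if not url.startswith(local_base):
            raise UnregisteredNamespaceError(
                f"URL not under proxy base {local_base}: {url}"
            )
        rest = url[len(local_base):]
        segment, _, local_id = rest.partition("/")
        if not local_id or segment not in self.proxy_aliases:
            raise UnregisteredNamespaceError(
                f"no namespace registered for proxy path {rest!r}"
            )
        kind = self.proxy_aliases[segment]
        return self.base(kind) + local_id

    # -- config file --------------------------------------------------------

    @classmethod
    def from_file(cls, path: str | Path, **kwargs) -> "UriPolicy":
        """Load prefix/base pairs from a plain-text file (tab separated,
        ``#`` comments); unlisted prefixes keep their defaults."""
        namespaces = _default_namespaces()
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            prefix, _, base = line.partition("\t")
            if not base:
                raise ValueError(f"malformed policy line: {line!r}")
            namespaces[prefix.strip()] = base.strip()
        return cls(namespaces=namespaces, **kwargs)


def decode_inchi_uri(iri: str, base: str = "http://rdf.openmolecules.net/?") -> str:
    """Recover the InChI string from an InChI-based IRI."""
    if not iri.startswith(base):
        raise ValueError(f"IRI not under InChI base {base}: {iri}")
    return unquote(iri[len(base):])
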