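"""Minimal Linked Data dereferencing layer.

Serves bounded descriptions of converted resources over HTTP with
content negotiation: RDF media types in the Accept header get Turtle or
N-Triples, anything else gets a plain HTML triple table.  Request paths
follow the proxy layout ``/<segment>/<local id>`` where the segment is
resolved through the URI policy's alias table (so e.g. a legacy
``article/`` path can serve the ``activity/`` namespace).
"""

from __future__ import annotations

from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer

from rdflib import Graph

from .rdfio import (
    HtmlFormat,
    SerializationFormat,
    describe_resource,
    negotiate,
    render_html,
    serialize,
)
from .uris import UnregisteredNamespaceError, UriPolicy


def make_handler(graph: Graph, policy: UriPolicy):
    class DereferenceHandler(BaseHTTPRequestHandler):
        server_version = "chemblrdf-ld/0.1"

        def log_message(self, fmt, *args):  # quiet by default
            pass

        def do_GET(self) -> None:
            try:
                uri = policy.translate_from_proxy("/" + self.path.lstrip("/"), "/")
            except UnregisteredNamespaceError:
                self._send_error(404, "no such resource namespace")
                return
            description = describe_resource(graph, uri)
            if len(description) == 0:
                self._send_error(404, f"unknown resource {uri}")
                return
            fmt = negotiate(self.headers.get("Accept"))
            if isinstance(fmt, SerializationFormat):
                payload = serialize(description, fmt)
            else:
                payload = render_html(description, uri)
            self.send_response(200)
            self.send_header("Content-Type", fmt.media_type + "; charset=utf-8")
            self.send_header("Content-Length", str(len(payload)))
            self.end_headers()
            self.wfile.write(payload)

        def _send_error(self, code: int, message: str) -> None:
            payload = message.encode("utf-8")
            self.send_response(code)
            self.send_header("Content-Type", "text/plain; charset=utf-8")
            self.send_header("Content-Length", str(len(payload)))
            self.end_headers()
            self.wfile.write(payload)

    return DereferenceHandler


def make_server(
    graph: Graph, policy: UriPolicy, host: str = "127.0.0.1", port: int = 8080
) -> ThreadingHTTPServer:
    return ThreadingHTTPServer((host, port), make_handler(graph, policy))
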