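"""SPARQL clients with exact request accounting.

Source selection must be auditable: every SELECT or ASK a client sends
increments exactly one counter and is appended to a request log, so
tests (and ``--metrics``) can assert how many probes were issued and
that no request ever names an unauthorised graph.

Two implementations share the contract:

* :class:`InMemoryClient` evaluates against a local quad store — the
  graph scoping of a query is enforced structurally because the store
  holds named graphs only (no default graph union).
* :class:`HTTPClient` speaks the SPARQL 1.1 Protocol over HTTP; graph
  scoping is carried by the rewritten query itself and the endpoint is
  trusted to honour it.
"""

from __future__ import annotations

import abc
import json
import urllib.error
import urllib.parse
import urllib.request
from typing import Union

from rdflib import Literal, URIRef, Variable

from .errors import ConnectionError, InputError
from .model import Dataset

#: One solution row: variable -> bound term.
Row = dict[Variable, Union[URIRef, Literal]]


class EndpointClient(abc.ABC):
    """A SPARQL endpoint for one dataset, with request counters."""

    def __init__(self) -> None:
        self.select_count = 0
        self.ask_count = 0
        self.log: list[str] = []

    def select(self, query: str) -> list[Row]:
        self.select_count += 1
        self.log.append(query)
        return self._select(query)

    def ask(self, query: str) -> bool:
        self.ask_count += 1
        self.log.append(query)
        return self._ask(query)

    @abc.abstractmethod
    def _select(self, query: str) -> list[Row]: ...

    @abc.abstractmethod
    def _ask(self, query: str) -> bool: ...


class InMemoryClient(EndpointClient):
    """Evaluates queries over a locally loaded dataset."""

    def __init__(self, dataset: Dataset) -> None:
        super().__init__()
        self.dataset = dataset

    def _select(self, query: str) -> list[Row]:
        result = self.dataset.to_rdflib().query(query)
        rows: list[Row] = []
        for binding in result:
            rows.append(
                {
                    v: t
                    for v, t in zip(result.vars, binding)
                    if t is not None
                }
            )
        return rows

    def _ask(self, query: str) -> bool:
        return bool(self.dataset.to_rdflib().query(query))


def _term_from_json(node: dict) -> Union[URIRef, Literal]:
    kind = node.get("type")
    if kind == "uri":
        return URIRef(node["value"])
    if kind in ("literal", "typed-literal"):
        return Literal(
            node["value"],
            lang=node.get("xml:lang"),
            datatype=URIRef(node["datatype"]) if node.get("datatype") else None,
        )
    if kind == "bnode":
        raise InputError("endpoint returned a blank node; unsupported in this setting")
    raise InputError(f"malformed SPARQL results term: {node!r}")


class HTTPClient(EndpointClient):
    """SPARQL 1.1 Protocol client (query via POST, JSON results)."""

    def __init__(self, endpoint_url: str, timeout: float = 300.0) -> None:
        super().__init__()
        self.endpoint_url = endpoint_url
        self.timeout = timeout

    def _request(self, query: str) -> dict:
        body = urllib.parse.urlencode({"query": query}).encode()
        req = urllib.request.Request(
            self.endpoint_url,
            data=body,
            headers={
                "Content-Type": "application/x-www-form-urlencoded",
                "Accept": "application/sparql-results+json",
            },
        )
        try:
            with urllib.request.urlopen(req, timeout=self.timeout) as resp:
                return json.loads(resp.read().decode("utf-8"))
        except (urllib.error.URLError, OSError) as exc:
            raise ConnectionError(
                f"endpoint {self.endpoint_url} unreachable: {exc}"
            ) from exc

    def _select(self, query: str) -> list[Row]:
        doc = self._request(query)
        try:
            bindings = doc["results"]["bindings"]
        except KeyError:
            raise InputError(
                f"endpoint {self.endpoint_url}: response is not a SELECT result"
            )
        return [
            {Variable(name): _term_from_json(node) for name, node in row.items()}
            for row in bindings
        ]

    def _ask(self, query: str) -> bool:
        doc = self._request(query)
        if "boolean" not in doc:
            raise InputError(
                f"endpoint {self.endpoint_url}: response is not an ASK result"
            )
        return bool(doc["boolean"])


def clients_for(federation) -> dict[str, EndpointClient]:
    """One client per dataset: in-memory if loaded, HTTP if remote."""
    out: dict[str, EndpointClient] = {}
    for ds in federation.datasets:
        out[ds.id] = HTTPClient(ds.location) if ds.remote else InMemoryClient(ds)
    return out
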