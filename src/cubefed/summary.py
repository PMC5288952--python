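"""Data summaries: the instance-free index behind source selection.

For each dataset the summary records only (i) the endpoint URL, (ii) the
names of its graphs (one cube per graph), and (iii) a map from each
predicate IRI to the graphs in which it occurs.  No subjects, objects or
counts are stored: the summary cannot leak instance data, and its size
depends on the schema, not on the number of observations.

From a collection of summaries, :func:`derive_indexes` computes the
lookup structures used during selection:

* ``preds(D)`` — all predicates of dataset ``D``;
* ``upreds(u, D)`` — predicates occurring in exactly one graph ``u`` of
  ``D`` (uniqueness is judged *within* the dataset);
* ``unames(D)`` — the graphs of ``D`` with at least one unique
  predicate.

A subject group mentioning a predicate unique to graph ``u`` can, under
subject locality, only be answered by ``u``; a group mentioning
predicates unique to two different graphs of one dataset can not be
answered by that dataset at all.

``rdf:type`` and the QB structural predicates (``qb:dataSet`` etc.) are
indexed exactly like domain predicates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Union

import rdflib
from rdflib import Literal, URIRef

from .clients import EndpointClient
from .errors import InputError
from .model import Dataset
from .namespaces import LMDS

_SUMMARY_NS = "urn:cubefed:summary:"


@dataclass(frozen=True)
class DataSummary:
    """Per-dataset predicate/graph index; holds no instance data."""

    dataset_id: str
    endpoint_url: str
    graph_names: frozenset[URIRef]
    pred_to_graphs: dict[URIRef, frozenset[URIRef]]

    def __post_init__(self) -> None:
        stray = {
            g for gs in self.pred_to_graphs.values() for g in gs
        } - set(self.graph_names)
        if stray:
            raise InputError(
                f"summary for {self.dataset_id!r} maps predicates to unknown "
                f"graphs: {sorted(map(str, stray))}"
            )

    @property
    def preds(self) -> frozenset[URIRef]:
        return frozenset(self.pred_to_graphs)

    def graph_preds(self, graph: URIRef) -> frozenset[URIRef]:
        return frozenset(
            p for p, gs in self.pred_to_graphs.items() if graph in gs
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, DataSummary):
            return NotImplemented
        return (
            self.dataset_id == other.dataset_id
            and self.endpoint_url == other.endpoint_url
            and self.graph_names == other.graph_names
            and self.pred_to_graphs == other.pred_to_graphs
        )

    def __hash__(self) -> int:
        return hash((self.dataset_id, self.endpoint_url, self.graph_names))


def build_summary(ds: Dataset) -> DataSummary:
    """Scan an in-memory dataset into its summary.

    Deterministic for a given dataset; an empty dataset yields a valid
    summary with empty maps.
    """
    pred_to_graphs: dict[URIRef, set[URIRef]] = {}
    for g in ds.graphs.values():
        for p in g.predicates():
            pred_to_graphs.setdefault(p, set()).add(g.name)
    return DataSummary(
        dataset_id=ds.id,
        endpoint_url=ds.location,
        graph_names=ds.graph_names(),
        pred_to_graphs={p: frozenset(gs) for p, gs in pred_to_graphs.items()},
    )


def build_summary_remote(
    ds: Dataset, client: EndpointClient
) -> DataSummary:
    """Build a summary by interrogating a remote endpoint.

    A single ``SELECT DISTINCT ?g ?p`` round trip enumerates the
    (graph, predicate) pairs; no instance data is transferred.
    """
    rows = client.select(
        "SELECT DISTINCT ?g ?p WHERE { GRAPH ?g { ?s ?p ?o } }"
    )
    pred_to_graphs: dict[URIRef, set[URIRef]] = {}
    graph_names: set[URIRef] = set()
    for row in rows:
        g = row[rdflib.Variable("g")]
        p = row[rdflib.Variable("p")]
        graph_names.add(URIRef(g))
        pred_to_graphs.setdefault(URIRef(p), set()).add(URIRef(g))
    return DataSummary(
        dataset_id=ds.id,
        endpoint_url=ds.location,
        graph_names=frozenset(graph_names),
        pred_to_graphs={p: frozenset(gs) for p, gs in pred_to_graphs.items()},
    )


@dataclass(frozen=True)
class SummaryIndex:
    """Derived lookups over a set of summaries (see module docstring)."""

    summaries: dict[str, DataSummary]
    preds: dict[str, frozenset[URIRef]]
    upreds: dict[str, dict[URIRef, frozenset[URIRef]]]
    unames: dict[str, frozenset[URIRef]]

    def dataset_ids(self) -> list[str]:
        return sorted(self.summaries)


def derive_indexes(summaries: Iterable[DataSummary]) -> SummaryIndex:
    """Compute preds / upreds / unames per dataset.

    Idempotent and independent of iteration order.
    """
    by_id = {s.dataset_id: s for s in summaries}
    preds: dict[str, frozenset[URIRef]] = {}
    upreds: dict[str, dict[URIRef, frozenset[URIRef]]] = {}
    unames: dict[str, frozenset[URIRef]] = {}
    for ds_id, s in by_id.items():
        preds[ds_id] = s.preds
        per_graph: dict[URIRef, set[URIRef]] = {g: set() for g in s.graph_names}
        for p, gs in s.pred_to_graphs.items():
            if len(gs) == 1:
                (only,) = gs
                per_graph[only].add(p)
        upreds[ds_id] = {
            g: frozenset(ps) for g, ps in per_graph.items() if ps
        }
        unames[ds_id] = frozenset(upreds[ds_id])
    return SummaryIndex(
        summaries=by_id, preds=preds, upreds=upreds, unames=unames
    )


# --------------------------------------------------------------------------
# serialisation: JSON (canonical) and RDF (interchange)

def summary_to_json(s: DataSummary) -> str:
    doc = {
        "dataset_id": s.dataset_id,
        "endpoint_url": s.endpoint_url,
        "graph_names": sorted(str(g) for g in s.graph_names),
        "pred_to_graphs": {
            str(p): sorted(str(g) for g in gs)
            for p, gs in sorted(s.pred_to_graphs.items())
        },
    }
    return json.dumps(doc, indent=2, sort_keys=True)


def summary_from_json(document: str) -> DataSummary:
    try:
        doc = json.loads(document)
        return DataSummary(
            dataset_id=doc["dataset_id"],
            endpoint_url=doc["endpoint_url"],
            graph_names=frozenset(URIRef(g) for g in doc["graph_names"]),
            pred_to_graphs={
                URIRef(p): frozenset(URIRef(g) for g in gs)
                for p, gs in doc["pred_to_graphs"].items()
            },
        )
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise InputError(f"malformed JSON summary document: {exc}") from exc


def summary_to_rdf(s: DataSummary) -> rdflib.Graph:
    """RDF form of one summary.

    Shape: one node per dataset with an ``lmds:endpointUrl`` literal and
    one ``lmds:cube`` node per graph; each cube node carries
    ``lmds:graph`` (the graph IRI) and repeated ``lmds:cubeProperties``
    (the predicate IRIs occurring in that graph).
    """
    g = rdflib.Graph()
    g.bind("lmds", LMDS)
    node = URIRef(_SUMMARY_NS + s.dataset_id)
    g.add((node, LMDS.endpointUrl, Literal(s.endpoint_url)))
    for graph_name in s.graph_names:
        cube = URIRef(f"{_SUMMARY_NS}{s.dataset_id}:cube:{graph_name}")
        g.add((node, LMDS.cube, cube))
        g.add((cube, LMDS.graph, graph_name))
        for p in s.graph_preds(graph_name):
            g.add((cube, LMDS.cubeProperties, p))
    return g


def summaries_to_rdf(summaries: Iterable[DataSummary]) -> rdflib.Graph:
    g = rdflib.Graph()
    g.bind("lmds", LMDS)
    for s in summaries:
        g += summary_to_rdf(s)
    return g


def summaries_from_rdf(
    document: Union[str, rdflib.Graph],
) -> list[DataSummary]:
    """Parse one or more summaries from their RDF (Turtle) form."""
    if isinstance(document, rdflib.Graph):
        g = document
    else:
        g = rdflib.Graph()
        try:
            g.parse(data=document, format="turtle")
        except Exception as exc:
            raise InputError(f"malformed RDF summary document: {exc}") from exc
    out = []
    for node in sorted(set(g.subjects(LMDS.endpointUrl, None))):
        if not str(node).startswith(_SUMMARY_NS):
            raise InputError(f"summary node {node.n3()} has unexpected IRI shape")
        ds_id = str(node)[len(_SUMMARY_NS):]
        url = g.value(node, LMDS.endpointUrl)
        if url is None:
            raise InputError(f"summary node {node.n3()} lacks lmds:endpointUrl")
        graph_names: set[URIRef] = set()
        pred_to_graphs: dict[URIRef, set[URIRef]] = {}
        for cube in g.objects(node, LMDS.cube):
            name = g.value(cube, LMDS.graph)
            if name is None:
                raise InputError(f"cube node {cube.n3()} lacks lmds:graph")
            graph_names.add(URIRef(name))
            for p in g.objects(cube, LMDS.cubeProperties):
                pred_to_graphs.setdefault(URIRef(p), set()).add(URIRef(name))
        out.append(
            DataSummary(
                dataset_id=ds_id,
                endpoint_url=str(url),
                graph_names=frozenset(graph_names),
                pred_to_graphs={
                    p: frozenset(gs) for p, gs in pred_to_graphs.items()
                },
            )
        )
    return out
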