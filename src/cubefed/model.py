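"""Data model for a federation of named-graph RDF sources.

A :class:`Federation` is a set of :class:`Dataset` objects; each dataset
is a set of :class:`NamedGraph` objects, and every named graph holds one
RDF data cube.  There is deliberately *no* default graph: all triples
live in some named graph, which is the unit of both source selection and
access control.

Two structural assumptions are enforced at load time rather than merely
documented, because the completeness argument of the selection algorithm
depends on them:

* no blank nodes anywhere in the data (blank nodes break completeness in
  federated settings, and skolemising would silently change the data);
* graph names are globally unique across datasets.

A third assumption — *subject locality*, i.e. no subject IRI occurs in
two distinct named graphs anywhere in the federation — is checkable via
:func:`validate_locality` but not enforced, since real deployments may
prefer to assert it contractually.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import rdflib
import yaml
from rdflib import BNode, Literal, URIRef

from .errors import (
    ConfigurationError,
    InputError,
    UnsupportedOperationError,
    ValidationError,
)

#: A stored triple: subject and predicate are IRIs, object an IRI or literal.
Triple = tuple[URIRef, URIRef, Union[URIRef, Literal]]

_QUAD_FORMATS = {".trig": "trig", ".nq": "nquads", ".nquads": "nquads"}


@dataclass(frozen=True)
class NamedGraph:
    """A named RDF graph: an IRI name plus a set of triples."""

    name: URIRef
    triples: frozenset[Triple]

    def __post_init__(self) -> None:
        if not str(self.name):
            raise ValidationError("named graph requires a non-empty IRI name")

    def predicates(self) -> frozenset[URIRef]:
        return frozenset(p for _, p, _ in self.triples)

    def subjects(self) -> frozenset[URIRef]:
        return frozenset(s for s, _, _ in self.triples)

    def __len__(self) -> int:
        return len(self.triples)


@dataclass
class Dataset:
    """One federation member: a set of named graphs behind one endpoint.

    ``location`` is the endpoint URL under which the dataset is
    published.  In-memory datasets carry their graphs directly; remote
    datasets (``remote=True``) have an empty ``graphs`` map and are only
    reachable through a SPARQL client.
    """

    id: str
    location: str
    graphs: dict[URIRef, NamedGraph] = field(default_factory=dict)
    remote: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ConfigurationError("dataset requires a non-empty id")
        self._store: Optional[rdflib.Dataset] = None

    def graph_names(self) -> frozenset[URIRef]:
        return frozenset(self.graphs)

    def predicates(self) -> frozenset[URIRef]:
        out: set[URIRef] = set()
        for g in self.graphs.values():
            out |= g.predicates()
        return frozenset(out)

    def add_graph(self, graph: NamedGraph) -> None:
        if graph.name in self.graphs:
            raise ValidationError(
                f"duplicate graph name {graph.name} in dataset {self.id!r}"
            )
        self.graphs[graph.name] = graph
        self._store = None

    def to_rdflib(self) -> rdflib.Dataset:
        """Quad store over this dataset (cached; named graphs only)."""
        if self.remote:
            raise UnsupportedOperationError(
                f"dataset {self.id!r} is remote; no local triples available"
            )
        if self._store is None:
            store = rdflib.Dataset(default_union=False)
            for g in self.graphs.values():
                target = store.graph(g.name)
                for t in g.triples:
                    target.add(t)
            self._store = store
        return self._store

    def __len__(self) -> int:
        return sum(len(g) for g in self.graphs.values())


@dataclass
class Federation:
    """A set of datasets with globally unique graph names."""

    datasets: list[Dataset] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._check_unique_graph_names()

    def _check_unique_graph_names(self) -> None:
        seen: dict[URIRef, str] = {}
        for ds in self.datasets:
            for name in ds.graphs:
                if name in seen and seen[name] != ds.id:
                    raise ValidationError(
                        f"graph name {name} appears in datasets "
                        f"{seen[name]!r} and {ds.id!r}"
                    )
                seen[name] = ds.id

    def dataset(self, dataset_id: str) -> Dataset:
        for ds in self.datasets:
            if ds.id == dataset_id:
                return ds
        raise ConfigurationError(f"no dataset with id {dataset_id!r}")

    @property
    def remote(self) -> bool:
        return any(ds.remote for ds in self.datasets)

    def all_graphs(self) -> Iterable[tuple[Dataset, NamedGraph]]:
        for ds in self.datasets:
            for g in ds.graphs.values():
                yield ds, g

    def merged_graph(
        self, graph_names: Optional[Iterable[URIRef]] = None
    ) -> rdflib.Graph:
        """Union of all (or the given) named graphs as one rdflib Graph.

        This is the global merged dataset used by the brute-force
        evaluation oracle; it is never used in federated execution.
        """
        if self.remote:
            raise UnsupportedOperationError(
                "merging requires full local data access (in-memory mode)"
            )
        allowed = None if graph_names is None else set(graph_names)
        merged = rdflib.Graph()
        for _, g in self.all_graphs():
            if allowed is not None and g.name not in allowed:
                continue
            for t in g.triples:
                merged.add(t)
        return merged


@dataclass(frozen=True)
class LocalityViolation:
    """A subject IRI found in more than one named graph."""

    subject: URIRef
    graph_names: frozenset[URIRef]


def validate_locality(fed: Federation) -> list[LocalityViolation]:
    """Check the subject-locality assumption across the whole federation.

    Returns one violation per subject IRI that occurs in two or more
    distinct named graphs (across *all* datasets).  An empty list means
    the federation satisfies the assumption under which join-aware
    selection is complete.
    """
    if fed.remote:
        raise UnsupportedOperationError(
            "locality validation requires full data access (in-memory mode)"
        )
    owner: dict[URIRef, set[URIRef]] = {}
    for _, g in fed.all_graphs():
        for s in g.subjects():
            owner.setdefault(s, set()).add(g.name)
    return [
        LocalityViolation(subject=s, graph_names=frozenset(names))
        for s, names in sorted(owner.items())
        if len(names) > 1
    ]


def _check_term(term, *, filename: str, role: str) -> None:
    if isinstance(term, BNode):
        raise ValidationError(
            f"{filename}: blank node in {role} position is not supported "
            "(blank nodes break completeness of federated selection)"
        )


def _graphs_from_quads(path: Path) -> dict[URIRef, NamedGraph]:
    fmt = _QUAD_FORMATS.get(path.suffix.lower())
    if fmt is None:
        raise InputError(
            f"{path}: unknown quad format (expected .trig, .nq or .nquads)"
        )
    store = rdflib.Dataset(default_union=False)
    try:
        store.parse(location=str(path), format=fmt)
    except FileNotFoundError:
        raise InputError(f"{path}: file not found") from None
    except Exception as exc:  # rdflib's syntax errors carry line info
        raise InputError(f"{path}: parse failure: {exc}") from exc

    graphs: dict[URIRef, NamedGraph] = {}
    for ctx in store.graphs():
        triples = list(ctx)
        if not triples:
            continue
        if ctx.identifier == store.default_graph.identifier:
            s, p, o = triples[0]
            raise ValidationError(
                f"{path}: triple ({s.n3()} {p.n3()} {o.n3()}) in the default "
                "graph; all data must live in named graphs"
            )
        _check_term(ctx.identifier, filename=str(path), role="graph-name")
        for s, p, o in triples:
            _check_term(s, filename=str(path), role="subject")
            _check_term(o, filename=str(path), role="object")
        graphs[URIRef(ctx.identifier)] = NamedGraph(
            name=URIRef(ctx.identifier), triples=frozenset(triples)
        )
    return graphs


def load_federation(
    config: Union[str, Path, Mapping], base_dir: Optional[Path] = None
) -> Federation:
    """Load a federation from a YAML/JSON description.

    The description lists datasets, each with an ``id``, a ``location``
    (endpoint URL), and either ``files`` (TriG / N-Quads, loaded
    in-memory) or ``endpoint: true`` (remote; data stays at the source).

    Raises :class:`InputError` for unparseable files,
    :class:`ValidationError` for blank nodes, default-graph triples or
    duplicate graph names, and :class:`ConfigurationError` for malformed
    descriptions.
    """
    if isinstance(config, (str, Path)):
        cfg_path = Path(config)
        base_dir = base_dir or cfg_path.parent
        try:
            with open(cfg_path) as fh:
                config = yaml.safe_load(fh)
        except FileNotFoundError:
            raise ConfigurationError(f"{cfg_path}: configuration file not found")
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"{cfg_path}: invalid YAML: {exc}") from exc
    base_dir = Path(base_dir) if base_dir is not None else Path(".")

    if not isinstance(config, Mapping) or "datasets" not in config:
        raise ConfigurationError("federation description requires a 'datasets' list")

    datasets: list[Dataset] = []
    for entry in config["datasets"]:
        if "id" not in entry or "location" not in entry:
            raise ConfigurationError(
                f"dataset entry {entry!r} requires 'id' and 'location'"
            )
        ds = Dataset(
            id=str(entry["id"]),
            location=str(entry["location"]),
            remote=bool(entry.get("endpoint", False)),
        )
        if ds.remote and entry.get("files"):
            raise ConfigurationError(
                f"dataset {ds.id!r}: 'endpoint: true' and 'files' are exclusive"
            )
        for fname in entry.get("files", []):
            fpath = Path(fname)
            if not fpath.is_absolute():
                fpath = base_dir / fpath
            for name, graph in _graphs_from_quads(fpath).items():
                ds.add_graph(graph)
        datasets.append(ds)
    return Federation(datasets=datasets)


def dataset_to_trig(ds: Dataset) -> str:
    """Serialise an in-memory dataset back to TriG (named graphs only)."""
    return ds.to_rdflib().serialize(format="trig")


def federation_from_graphs(
    named: Mapping[str, tuple[str, Iterable[NamedGraph]]]
) -> Federation:
    """Build a federation from in-memory graphs.

    ``named`` maps dataset id to ``(endpoint_url, graphs)``.
    """
    datasets = []
    for ds_id, (location, graphs) in named.items():
        ds = Dataset(id=ds_id, location=location)
        for g in graphs:
            ds.add_graph(g)
        datasets.append(ds)
    return Federation(datasets=datasets)


def write_federation(fed: Federation, out_dir: Union[str, Path]) -> Path:
    """Write TriG files plus a federation config; returns the config path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for ds in fed.datasets:
        fname = f"{ds.id}.trig"
        with io.open(out / fname, "w") as fh:
            fh.write(dataset_to_trig(ds))
        entries.append({"id": ds.id, "location": ds.location, "files": [fname]})
    cfg = out / "federation.yaml"
    with open(cfg, "w") as fh:
        yaml.safe_dump({"datasets": entries}, fh, sort_keys=False)
    return cfg
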