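"""Deterministic generators for data-cube federations.

Two kinds of fixtures:

* :func:`running_example` — a small clinical federation of three
  datasets (CHUV, CING, ZEINCRO) holding four cubes of adverse-event
  counts, together with a graph-level access policy and example
  queries.  The cube schemas, the unique-predicate structure, the
  26-cases observation in ``:CHUV-S1`` and the grants of user ``:James``
  are fixed; the remaining cell values are constructed, deterministic
  fill values.
* :func:`random_federation` — seeded random federations of QB cubes
  whose observation subjects are generated with graph-scoped IRI
  prefixes, so subject locality holds *by construction*.  Predicate
  overlap across graphs is configurable, which makes all three branches
  of the join-aware selection (unique-graph pinning, conflict discard,
  all-graphs fallback) reachable.

Dimension values are plain integer literals (0/1 for binary clinical
dimensions); measures are non-negative integer counts.  SDMX annotation
and ``qb:Slice`` structures are not generated — the selection and
execution machinery never consults them.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

from rdflib import Literal, URIRef

from .errors import ValidationError
from .model import Dataset, Federation, NamedGraph, Triple
from .namespaces import EX, QB, RDF, SEHR
from .policy import AccessPolicy, UserProfile


@dataclass(frozen=True)
class CubeSpec:
    """Shape of one generated data cube (one named graph)."""

    graph_name: URIRef
    dataset_id: str
    dimension_preds: tuple[URIRef, ...]
    measure_pred: URIRef
    n_observations: int = 0
    value_domain: tuple[tuple[int, ...], ...] = ()  # per-dimension values
    measure_range: tuple[int, int] = (0, 100)
    rows: Optional[tuple[tuple[int, ...], ...]] = None  # pinned table

    def __post_init__(self) -> None:
        if self.n_observations < 0:
            raise ValidationError("n_observations must be >= 0")
        if self.rows is None and self.value_domain and len(
            self.value_domain
        ) != len(self.dimension_preds):
            raise ValidationError(
                "value_domain must list one value set per dimension"
            )
        if self.rows is not None:
            for row in self.rows:
                if len(row) != len(self.dimension_preds) + 1:
                    raise ValidationError(
                        "each pinned row needs one value per dimension "
                        "plus the measure"
                    )


def generate_cube(spec: CubeSpec, seed: int = 0) -> NamedGraph:
    """Emit one cube graph; deterministic for fixed (spec, seed).

    The graph holds one ``qb:DataSet`` node plus, per observation, a
    type triple, a ``qb:dataSet`` link, one triple per dimension and one
    measure triple.  Observation IRIs are prefixed by the graph IRI so
    locality is structural, not merely checked.
    """
    rng = random.Random(seed)
    base = str(spec.graph_name)
    cube_node = URIRef(f"{base}/dataset")
    triples: set[Triple] = {(cube_node, RDF.type, QB.DataSet)}
    if spec.rows is not None:
        table = spec.rows
    else:
        domains = spec.value_domain or tuple(
            (0, 1) for _ in spec.dimension_preds
        )
        table = tuple(
            tuple(rng.choice(dom) for dom in domains)
            + (rng.randint(*spec.measure_range),)
            for _ in range(spec.n_observations)
        )
    for k, row in enumerate(table):
        obs = URIRef(f"{base}/obs_{k}")
        triples.add((obs, RDF.type, QB.Observation))
        triples.add((obs, QB.dataSet, cube_node))
        for dim, value in zip(spec.dimension_preds, row[:-1]):
            triples.add((obs, dim, Literal(int(value))))
        triples.add((obs, spec.measure_pred, Literal(int(row[-1]))))
    return NamedGraph(name=spec.graph_name, triples=frozenset(triples))


# --------------------------------------------------------------------------
# running example

_CLINICAL = (SEHR.Diabetes, SEHR.BMI_Abnormal, SEHR.Hypertension)

#: Full 2^3 tables per cube, rows ordered by binary dimension tuple.
#: The (1, 0, 1) row of CHUV-S1 — diabetic, normal BMI, hypertensive —
#: carries the 26-cases count; the other cell values are constructed.
_CHUV_S1_ROWS = (
    (0, 0, 0, 57), (0, 0, 1, 33), (0, 1, 0, 21), (0, 1, 1, 18),
    (1, 0, 0, 40), (1, 0, 1, 26), (1, 1, 0, 15), (1, 1, 1, 12),
)
_CHUV_S4_ROWS = (
    (0, 0, 0, 44), (0, 0, 1, 29), (0, 1, 0, 31), (0, 1, 1, 22),
    (1, 0, 0, 35), (1, 0, 1, 27), (1, 1, 0, 16), (1, 1, 1, 9),
)
_CING_S2_ROWS = (
    (0, 0, 0, 62), (0, 0, 1, 28), (0, 1, 0, 24), (0, 1, 1, 16),
    (1, 0, 0, 38), (1, 0, 1, 31), (1, 1, 0, 19), (1, 1, 1, 8),
)
_ZEINCRO_S3_ROWS = (
    (0, 0, 0, 51), (0, 0, 1, 30), (0, 1, 0, 27), (0, 1, 1, 12),
    (1, 0, 0, 33), (1, 0, 1, 14), (1, 1, 0, 17), (1, 1, 1, 6),
)

_PREFIXES = """\
PREFIX rdf: <http://www.w3.org/1999/02/22-rdf-syntax-ns#>
PREFIX qb: <http://purl.org/linked-data/cube#>
PREFIX sehr: <http://example.org/sehr#>
"""

#: Subject-selection criteria: counts of cases by combination of
#: diabetes, abnormal BMI and hypertension (7 patterns, 2 subject groups).
SUBJECT_SELECTION_QUERY = _PREFIXES + """
SELECT ?dataset ?observation ?diabetes ?bmi ?hypertension ?cases WHERE {
  ?dataset rdf:type qb:DataSet .
  ?observation qb:dataSet ?dataset .
  ?observation rdf:type qb:Observation .
  ?observation sehr:Diabetes ?diabetes .
  ?observation sehr:BMI_Abnormal ?bmi .
  ?observation sehr:Hypertension ?hypertension .
  ?observation sehr:Cases ?cases .
}
"""

#: Same criteria restricted to diabetic, hypertensive, normal-BMI cases.
RESTRICTED_QUERY = _PREFIXES + """
SELECT ?dataset ?cases WHERE {
  ?dataset rdf:type qb:DataSet .
  ?observation qb:dataSet ?dataset .
  ?observation rdf:type qb:Observation .
  ?observation sehr:Diabetes ?diabetes .
  ?observation sehr:BMI_Abnormal ?bmi .
  ?observation sehr:Hypertension ?hypertension .
  ?observation sehr:Cases ?cases .
  FILTER(?diabetes = 1 && ?hypertension = 1 && ?bmi = 0)
}
"""


@dataclass
class RunningExample:
    federation: Federation
    policy: AccessPolicy
    user: URIRef
    queries: dict[str, str] = field(default_factory=dict)


def running_example() -> RunningExample:
    """The clinical example federation, policy and queries.

    Three datasets: CHUV holds ``:CHUV-S1`` (dimensions Diabetes,
    BMI_Abnormal, Hypertension) and ``:CHUV-S4`` (Smoking, Gender,
    Diabetes); CING holds ``:CING-S2`` and ZEINCRO ``:ZEINCRO-S3``, both
    with the three clinical dimensions.  All cubes measure ``Cases``.
    User ``:James`` may read ``:CHUV-S1`` and ``:CING-S2`` only.
    """
    specs = {
        "CHUV": [
            CubeSpec(
                graph_name=EX["CHUV-S1"],
                dataset_id="CHUV",
                dimension_preds=_CLINICAL,
                measure_pred=SEHR.Cases,
                rows=_CHUV_S1_ROWS,
            ),
            CubeSpec(
                graph_name=EX["CHUV-S4"],
                dataset_id="CHUV",
                dimension_preds=(SEHR.Smoking, SEHR.Gender, SEHR.Diabetes),
                measure_pred=SEHR.Cases,
                rows=_CHUV_S4_ROWS,
            ),
        ],
        "CING": [
            CubeSpec(
                graph_name=EX["CING-S2"],
                dataset_id="CING",
                dimension_preds=_CLINICAL,
                measure_pred=SEHR.Cases,
                rows=_CING_S2_ROWS,
            ),
        ],
        "ZEINCRO": [
            CubeSpec(
                graph_name=EX["ZEINCRO-S3"],
                dataset_id="ZEINCRO",
                dimension_preds=_CLINICAL,
                measure_pred=SEHR.Cases,
                rows=_ZEINCRO_S3_ROWS,
            ),
        ],
    }
    datasets = []
    for ds_id, cube_specs in specs.items():
        ds = Dataset(
            id=ds_id, location=f"http://example.org/{ds_id.lower()}/sparql"
        )
        for cs in cube_specs:
            ds.add_graph(generate_cube(cs))
        datasets.append(ds)
    james = EX.James
    policy = AccessPolicy.of(
        (james, EX["CHUV-S1"], "read"),
        (james, EX["CING-S2"], "read"),
        profiles=[
            UserProfile.make(
                james,
                activity="clinical research",
                location="Galway",
                organisation="NUIG",
                position="researcher",
                role="data analyst",
            )
        ],
    )
    return RunningExample(
        federation=Federation(datasets=datasets),
        policy=policy,
        user=james,
        queries={
            "subject-selection": SUBJECT_SELECTION_QUERY,
            "restricted": RESTRICTED_QUERY,
        },
    )


# --------------------------------------------------------------------------
# random federations

@dataclass(frozen=True)
class FederationSpec:
    """Shape of a random federation: per-dataset cube specs plus seed."""

    datasets: tuple[tuple[str, tuple[CubeSpec, ...]], ...]
    seed: int = 0


def generate_federation(fspec: FederationSpec) -> Federation:
    """Materialise a federation spec; locality holds by construction."""
    datasets = []
    for ds_id, cube_specs in fspec.datasets:
        ds = Dataset(
            id=ds_id, location=f"http://example.org/{ds_id}/sparql"
        )
        for i, cs in enumerate(cube_specs):
            ds.add_graph(generate_cube(cs, seed=fspec.seed + 7919 * i))
        datasets.append(ds)
    return Federation(datasets=datasets)


_DIM = "http://example.org/dim#"


def random_federation_spec(
    seed: int,
    n_datasets: tuple[int, int] = (2, 5),
    n_graphs: tuple[int, int] = (1, 4),
    n_shared_preds: tuple[int, int] = (3, 8),
    n_observations: tuple[int, int] = (5, 60),
    unique_prob: float = 0.5,
) -> FederationSpec:
    """Draw a random federation shape.

    ``unique_prob`` is the chance that a graph gains a predicate of its
    own on top of the shared dimension pool; at 0 every predicate is
    shared across graphs of a dataset, at 1 every graph is pinnable.
    """
    rng = random.Random(seed)
    pool_size = rng.randint(*n_shared_preds)
    pool = [URIRef(f"{_DIM}D{i}") for i in range(pool_size)]
    measures = [URIRef(f"{_DIM}M{i}") for i in range(2)]
    datasets = []
    for d in range(rng.randint(*n_datasets)):
        ds_id = f"DS{d}"
        cubes = []
        for g in range(rng.randint(*n_graphs)):
            dims = rng.sample(pool, k=rng.randint(1, min(4, pool_size)))
            if rng.random() < unique_prob:
                dims.append(URIRef(f"{_DIM}U_{ds_id}_G{g}"))
            cubes.append(
                CubeSpec(
                    graph_name=URIRef(f"http://example.org/{ds_id}/G{g}"),
                    dataset_id=ds_id,
                    dimension_preds=tuple(dims),
                    measure_pred=rng.choice(measures),
                    n_observations=rng.randint(*n_observations),
                    value_domain=tuple((0, 1) for _ in dims),
                    measure_range=(0, 99),
                )
            )
        datasets.append((ds_id, tuple(cubes)))
    return FederationSpec(datasets=tuple(datasets), seed=seed)


def random_federation(seed: int, **kwargs) -> Federation:
    """Convenience: draw a spec and materialise it."""
    return generate_federation(random_federation_spec(seed, **kwargs))


def random_conjunctive_query(fed: Federation, rng: random.Random) -> str:
    """Draw a conjunctive SELECT query exercising the selection branches.

    Groups are anchored on a randomly chosen cube so most queries have
    answers; with some probability a predicate from a *different* graph
    is mixed in (exercising conflict discard and empty selections), an
    object is bound to a value from the data, an unbound-predicate
    pattern is added (exercising restriction inheritance), or a second
    subject group joins through ``qb:dataSet``.
    """
    graphs = [g for _, g in fed.all_graphs()]
    target = rng.choice(graphs)
    preds = sorted(
        target.predicates() - {RDF.type, QB.dataSet}, key=str
    )
    lines = []
    var_i = 0
    chosen = rng.sample(preds, k=rng.randint(1, min(3, len(preds))))
    if rng.random() < 0.25:
        other = rng.choice(graphs)
        other_preds = sorted(
            other.predicates() - {RDF.type, QB.dataSet}, key=str
        )
        if other_preds:
            chosen.append(rng.choice(other_preds))
    if rng.random() < 0.4:
        lines.append("?s rdf:type qb:Observation .")
    for p in chosen:
        if rng.random() < 0.25:
            values = sorted(
                (o for s, pp, o in target.triples if pp == p),
                key=str,
            )
            obj = values[rng.randrange(len(values))].n3() if values else '"none"'
        else:
            obj = f"?v{var_i}"
            var_i += 1
        lines.append(f"?s <{p}> {obj} .")
    if rng.random() < 0.15:
        lines.append("?s ?pv ?ov .")
    if rng.random() < 0.35:
        lines.append("?s qb:dataSet ?ds .")
        lines.append("?ds rdf:type qb:DataSet .")
    body = "\n  ".join(lines)
    return (
        "PREFIX rdf: <http://www.w3.org/1999/02/22-rdf-syntax-ns#>\n"
        "PREFIX qb: <http://purl.org/linked-data/cube#>\n"
        f"SELECT * WHERE {{\n  {body}\n}}"
    )


def random_policy(
    fed: Federation, rng: random.Random, user: URIRef = EX.Someone
) -> AccessPolicy:
    """Grant the user read access to a random subset of graphs."""
    names = sorted((g.name for _, g in fed.all_graphs()), key=str)
    k = rng.randint(0, len(names))
    granted = rng.sample(names, k=k)
    return AccessPolicy.of(*((user, g, "read") for g in granted))
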