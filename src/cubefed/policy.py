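"""Graph-level access control: user profiles, read grants, default deny.

A policy is a set of ``(user, graph, right)`` grants; absence of a grant
means denial.  Profiles carry descriptive attributes (activity,
location, organisation, position, role) but these are not evaluated as
conditions here — attribute-based authorisation is the concern of the
surrounding platform, while the query engine enforces the graph-level
grants it is handed.

Policies integrate with selection *before* execution:
:func:`filter_selection` removes every (dataset, graph) pair whose graph
the user may not read, so no sub-query is ever dispatched to an
unauthorised graph (rather than having the request rejected remotely).

Policies are stored as RDF (``lmds:hasAccessPolicy`` linking a user to a
policy node with ``lmds:user`` / ``lmds:graph`` / ``lmds:right``) or as
JSON; both forms round-trip.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import rdflib
from rdflib import Literal, URIRef

from .errors import InputError
from .namespaces import LMDS
from .selection import SelectionResult

READ = "read"
WRITE = "write"
_RIGHTS = {READ, WRITE}

Grant = tuple[URIRef, URIRef, str]


@dataclass(frozen=True)
class UserProfile:
    """Descriptive profile of a user (attributes are not conditions)."""

    id: URIRef
    attributes: tuple[tuple[str, str], ...] = ()

    @classmethod
    def make(cls, id: Union[str, URIRef], **attributes: str) -> "UserProfile":
        return cls(id=URIRef(id), attributes=tuple(sorted(attributes.items())))


@dataclass(frozen=True)
class AccessPolicy:
    """A set of graph-level grants; anything not granted is denied."""

    grants: frozenset[Grant] = frozenset()
    profiles: tuple[UserProfile, ...] = ()

    @classmethod
    def of(cls, *grants: tuple, profiles: Iterable[UserProfile] = ()) -> "AccessPolicy":
        norm = []
        for user, graph, right in grants:
            if right not in _RIGHTS:
                raise InputError(f"unknown access right {right!r}")
            norm.append((URIRef(user), URIRef(graph), right))
        return cls(grants=frozenset(norm), profiles=tuple(profiles))

    def users(self) -> frozenset[URIRef]:
        return frozenset(u for u, _, _ in self.grants)

    def readable_graphs(self, user: URIRef) -> frozenset[URIRef]:
        return frozenset(
            g for u, g, r in self.grants if u == user and r == READ
        )


def authorised(
    user: Union[str, URIRef],
    graph: Union[str, URIRef],
    right: str,
    policy: AccessPolicy,
) -> bool:
    """True iff the policy grants ``right`` on ``graph`` to ``user``.

    Unknown users, graphs or rights simply yield False (default deny).
    """
    return (URIRef(user), URIRef(graph), right) in policy.grants


def filter_selection(
    sel: SelectionResult, policy: AccessPolicy, user: Union[str, URIRef]
) -> SelectionResult:
    """Remove every selected pair whose graph the user may not read.

    Idempotent and anti-monotone: the result is pattern-wise a subset of
    the input, and filtering twice equals filtering once.
    """
    user = URIRef(user)
    allowed = policy.readable_graphs(user)
    per_bgp = [
        {
            t: frozenset((d, g) for d, g in pairs if g in allowed)
            for t, pairs in bgp.items()
        }
        for bgp in sel.per_bgp
    ]
    return SelectionResult(
        per_bgp=per_bgp,
        ask_count=sel.ask_count,
        skipped_datasets=list(sel.skipped_datasets),
    )


# --------------------------------------------------------------------------
# serialisation

def policy_to_json(policy: AccessPolicy) -> str:
    doc = {
        "grants": [
            {"user": str(u), "graph": str(g), "right": r}
            for u, g, r in sorted(policy.grants)
        ],
        "profiles": [
            {"id": str(p.id), "attributes": dict(p.attributes)}
            for p in policy.profiles
        ],
    }
    return json.dumps(doc, indent=2, sort_keys=True)


def policy_from_json(document: str) -> AccessPolicy:
    try:
        doc = json.loads(document)
        grants = [
            (URIRef(g["user"]), URIRef(g["graph"]), g["right"])
            for g in doc.get("grants", [])
        ]
        profiles = [
            UserProfile(
                id=URIRef(p["id"]),
                attributes=tuple(sorted(p.get("attributes", {}).items())),
            )
            for p in doc.get("profiles", [])
        ]
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise InputError(f"malformed JSON policy document: {exc}") from exc
    return AccessPolicy.of(*grants, profiles=profiles)


def policy_to_rdf(policy: AccessPolicy) -> rdflib.Graph:
    g = rdflib.Graph()
    g.bind("lmds", LMDS)
    for i, (user, graph, right) in enumerate(sorted(policy.grants)):
        node = URIRef(f"urn:cubefed:grant:{i}")
        g.add((user, LMDS.hasAccessPolicy, node))
        g.add((node, LMDS.user, user))
        g.add((node, LMDS.graph, graph))
        g.add((node, LMDS.right, Literal(right)))
    for p in policy.profiles:
        for key, value in p.attributes:
            g.add((p.id, LMDS[key], Literal(value)))
    return g


def policy_from_rdf(document: Union[str, rdflib.Graph]) -> AccessPolicy:
    if isinstance(document, rdflib.Graph):
        g = document
    else:
        g = rdflib.Graph()
        try:
            g.parse(data=document, format="turtle")
        except Exception as exc:
            raise InputError(f"malformed RDF policy document: {exc}") from exc
    grants = []
    for node in set(g.objects(None, LMDS.hasAccessPolicy)):
        user = g.value(node, LMDS.user)
        graph = g.value(node, LMDS.graph)
        right = g.value(node, LMDS.right)
        if user is None or graph is None or right is None:
            raise InputError(
                f"policy node {node.n3()} lacks lmds:user/lmds:graph/lmds:right"
            )
        grants.append((URIRef(user), URIRef(graph), str(right)))
    return AccessPolicy.of(*grants)


def load_policy(path: Union[str, Path]) -> AccessPolicy:
    """Load a policy file; format chosen by extension (.json or RDF)."""
    path = Path(path)
    try:
        text = path.read_text()
    except FileNotFoundError:
        raise InputError(f"{path}: policy file not found")
    if path.suffix.lower() == ".json":
        return policy_from_json(text)
    return policy_from_rdf(text)
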