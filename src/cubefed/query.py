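"""Query decomposition: BGPs, triple patterns and subject groups.

Queries are parsed with rdflib's SPARQL 1.1 parser and the resulting
algebra is flattened into a :class:`QueryPlan`:

* every UNION branch becomes its own conjunctive branch;
* every OPTIONAL block becomes an :class:`OptionalBlock` attached to its
  branch (combined later by left join);
* FILTER expressions are collected per branch (grouping for source
  selection ignores filter placement: a subject group spans the whole
  BGP);
* DISTINCT / ORDER BY / LIMIT / OFFSET are recorded as solution
  modifiers.

The supported fragment is plain SELECT with BGPs, FILTER (including
REGEX), UNION, OPTIONAL and the modifiers above.  Aggregates, property
paths, subqueries, BIND, VALUES, MINUS, GRAPH and SERVICE clauses raise
:class:`UnsupportedFeatureError`.

The unit that drives source selection is the *subject group*: the set
of triple patterns of one BGP sharing an identical subject term (an
s-s join).  Under subject locality such a join is confined to a single
named graph, which is what makes join-aware pruning sound.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Union

from rdflib import BNode, Literal, URIRef, Variable
from rdflib.plugins.sparql import prepareQuery

from .errors import QueryParseError, UnsupportedFeatureError

QueryTerm = Union[URIRef, Literal, Variable]


@dataclass(frozen=True)
class TriplePattern:
    """One triple pattern; ``index`` is its position within its BGP."""

    s: QueryTerm
    p: QueryTerm
    o: QueryTerm
    index: int = -1

    @property
    def predicate_bound(self) -> bool:
        return isinstance(self.p, URIRef)

    def variables(self) -> frozenset[Variable]:
        return frozenset(
            t for t in (self.s, self.p, self.o) if isinstance(t, Variable)
        )

    def __str__(self) -> str:
        return f"{self.s.n3()} {self.p.n3()} {self.o.n3()} ."


@dataclass
class SubjectGroup:
    """All patterns of one BGP sharing one subject term (s-s join)."""

    subject: QueryTerm
    patterns: list[TriplePattern]

    @property
    def bound_preds(self) -> frozenset[URIRef]:
        return frozenset(
            t.p for t in self.patterns if t.predicate_bound
        )

    def variables(self) -> frozenset[Variable]:
        out: set[Variable] = set()
        for t in self.patterns:
            out |= t.variables()
        return frozenset(out)


@dataclass
class OptionalBlock:
    """An OPTIONAL BGP plus the filter expressions scoped to it."""

    patterns: list[TriplePattern]
    exprs: list = field(default_factory=list)


@dataclass
class Branch:
    """One conjunctive branch (one per UNION arm)."""

    patterns: list[TriplePattern]
    optionals: list[OptionalBlock] = field(default_factory=list)
    filters: list = field(default_factory=list)


@dataclass
class QueryPlan:
    """Flattened query: branches plus solution modifiers."""

    branches: list[Branch]
    projection: list[Variable]
    distinct: bool = False
    order_by: list[tuple] = field(default_factory=list)  # (expr, descending)
    limit: Optional[int] = None
    offset: int = 0
    text: str = ""

    @property
    def bgps(self) -> list[list[TriplePattern]]:
        """All BGPs of the plan: each branch's required patterns, then
        each optional block; every pattern appears in exactly one."""
        out = [b.patterns for b in self.branches]
        for b in self.branches:
            out.extend(ob.patterns for ob in b.optionals)
        return out

    def variables(self) -> frozenset[Variable]:
        out: set[Variable] = set()
        for bgp in self.bgps:
            for t in bgp:
                out |= t.variables()
        return frozenset(out)


def _mk_pattern(triple) -> TriplePattern:
    s, p, o = triple
    for role, term in (("subject", s), ("predicate", p), ("object", o)):
        if isinstance(term, BNode):
            raise UnsupportedFeatureError(
                "blank nodes in query patterns are not supported"
            )
    if not isinstance(p, (URIRef, Variable)):
        raise UnsupportedFeatureError(
            f"property paths are not supported (predicate {p!r})"
        )
    return TriplePattern(s=s, p=p, o=o)


def _merge_branches(left: list[Branch], right: list[Branch]) -> list[Branch]:
    out = []
    for a in left:
        for b in right:
            out.append(
                Branch(
                    patterns=a.patterns + b.patterns,
                    optionals=a.optionals + b.optionals,
                    filters=a.filters + b.filters,
                )
            )
    return out


def _walk(node) -> list[Branch]:
    name = getattr(node, "name", None)
    if name == "BGP":
        return [Branch(patterns=[_mk_pattern(t) for t in node.triples])]
    if name == "Filter":
        branches = _walk(node.p)
        for b in branches:
            b.filters.append(node.expr)
        return branches
    if name == "Join":
        return _merge_branches(_walk(node.p1), _walk(node.p2))
    if name == "Union":
        return _walk(node.p1) + _walk(node.p2)
    if name == "LeftJoin":
        left = _walk(node.p1)
        right = _walk(node.p2)
        if len(right) != 1 or right[0].optionals:
            raise UnsupportedFeatureError(
                "nested UNION/OPTIONAL inside OPTIONAL is not supported"
            )
        exprs = list(right[0].filters)
        expr = node.get("expr")
        if expr is not None and getattr(expr, "name", None) != "TrueFilter":
            exprs.append(expr)
        block = OptionalBlock(patterns=right[0].patterns, exprs=exprs)
        for b in left:
            b.optionals.append(block)
        return left
    raise UnsupportedFeatureError(
        f"unsupported query feature: {name or type(node).__name__}"
    )


def parse_query(text: str) -> QueryPlan:
    """Parse a SPARQL SELECT query into a :class:`QueryPlan`.

    Raises :class:`QueryParseError` on syntax errors (with position
    information from the parser) and :class:`UnsupportedFeatureError`
    for queries outside the supported fragment.
    """
    try:
        prepared = prepareQuery(text)
    except UnsupportedFeatureError:
        raise
    except Exception as exc:
        raise QueryParseError(f"SPARQL syntax error: {exc}") from exc

    node = prepared.algebra
    if node.name != "SelectQuery":
        raise UnsupportedFeatureError(
            f"only SELECT queries are supported, got {node.name}"
        )
    projection = list(node.PV)
    node = node.p

    limit: Optional[int] = None
    offset = 0
    if node.name == "Slice":
        offset = node.start or 0
        limit = node.length
        node = node.p
    distinct = False
    if node.name == "Distinct":
        distinct = True
        node = node.p
    if node.name == "Reduced":  # REDUCED may drop duplicates; we keep them
        node = node.p
    if node.name != "Project":
        raise UnsupportedFeatureError(
            f"unsupported query feature: {node.name}"
        )
    node = node.p
    order_by: list[tuple] = []
    if node.name == "OrderBy":
        for cond in node.expr:
            descending = getattr(cond, "order", None) == "DESC"
            order_by.append((cond.expr, descending))
        node = node.p

    branches = _walk(node)
    for branch in branches:
        branch.patterns = [
            dataclasses.replace(t, index=i)
            for i, t in enumerate(branch.patterns)
        ]
        for ob in branch.optionals:
            ob.patterns = [
                dataclasses.replace(t, index=i)
                for i, t in enumerate(ob.patterns)
            ]
    return QueryPlan(
        branches=branches,
        projection=projection,
        distinct=distinct,
        order_by=order_by,
        limit=limit,
        offset=offset,
        text=text,
    )


def group_by_subject(bgp: list[TriplePattern]) -> list[SubjectGroup]:
    """Partition a BGP into subject groups.

    The grouping key is exact term equality of the subject (two distinct
    variables never merge); groups are ordered by first appearance and
    each keeps its patterns in query order.
    """
    groups: dict[QueryTerm, SubjectGroup] = {}
    for t in bgp:
        if t.s in groups:
            groups[t.s].patterns.append(t)
        else:
            groups[t.s] = SubjectGroup(subject=t.s, patterns=[t])
    return list(groups.values())
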