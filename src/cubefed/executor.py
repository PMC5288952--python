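"""Graph-restricted federated execution.

Execution pushes each *subject group* of each BGP as a single sub-query
to every dataset selected for it, restricted to the selected graphs via
``GRAPH ?__g`` plus an inline ``VALUES`` clause (one request per dataset
regardless of graph count).  Under subject locality a group never joins
across graphs, so unioning per-dataset answers is exact.  Cross-group
joins are local hash joins, smallest intermediate result first; UNION
branches are concatenated, OPTIONAL blocks are combined by left join,
and FILTER / projection / DISTINCT / ORDER BY / LIMIT are applied
locally.

:func:`evaluate_merged` is the brute-force correctness oracle: it
evaluates the full query with rdflib's SPARQL engine over the union of
all triples of all named graphs (optionally only the authorised ones).
The engine is correct when, for every supported query over every
locality-respecting federation, ``execute`` and ``evaluate_merged``
return the same multiset of rows.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

from rdflib import Literal, URIRef, Variable
from rdflib.plugins.sparql.evalutils import _ebv
from rdflib.plugins.sparql.sparql import QueryContext, FrozenBindings, SPARQLError

from .clients import EndpointClient, Row, clients_for
from .errors import ConfigurationError
from .model import Federation
from .policy import AccessPolicy, filter_selection
from .query import QueryPlan, SubjectGroup, TriplePattern, group_by_subject, parse_query
from .selection import SelectionResult, SourcePair, select_sources
from .summary import SummaryIndex, build_summary, derive_indexes

_GRAPH_VAR = Variable("__g")


@dataclass
class ExecutionMetrics:
    """Counters recorded during one execution."""

    ask_requests: int = 0
    select_subqueries: int = 0
    pattern_sources: int = 0
    selected_pairs: int = 0


@dataclass
class ResultSet:
    """Solution multiset; ordered only under ORDER BY."""

    rows: list[Row]
    variables: list[Variable]
    ordered: bool = False
    metrics: Optional[ExecutionMetrics] = None
    selection: Optional[SelectionResult] = None

    def as_multiset(self) -> Counter:
        return Counter(frozenset(r.items()) for r in self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ResultSet):
            return NotImplemented
        if self.ordered and other.ordered:
            return [sorted(r.items()) for r in self.rows] == [
                sorted(r.items()) for r in other.rows
            ]
        return self.as_multiset() == other.as_multiset()


# --------------------------------------------------------------------------
# sub-query rewriting and group evaluation

def rewrite_subquery(g: SubjectGroup, graphs: Iterable[URIRef]) -> str:
    """Rewrite one subject group as a graph-restricted sub-query.

    The ``VALUES`` clause enumerates exactly the permitted graph IRIs;
    output is reproducible for fixed input (graphs sorted, variables in
    order of first appearance).
    """
    graphs = sorted(set(graphs), key=str)
    if not graphs:
        raise ValueError("rewrite_subquery requires at least one graph")
    seen: list[Variable] = []
    for t in g.patterns:
        for term in (t.s, t.p, t.o):
            if isinstance(term, Variable) and term not in seen:
                seen.append(term)
    projection = " ".join(v.n3() for v in seen) if seen else "*"
    values = " ".join(u.n3() for u in graphs)
    body = "\n    ".join(str(t) for t in g.patterns)
    return (
        f"SELECT {projection} WHERE {{\n"
        f"  VALUES {_GRAPH_VAR.n3()} {{ {values} }}\n"
        f"  GRAPH {_GRAPH_VAR.n3()} {{\n    {body}\n  }}\n"
        f"}}"
    )


def _group_dataset_graphs(
    group: SubjectGroup,
    bgp_selection: Mapping[TriplePattern, frozenset[SourcePair]],
) -> dict[str, frozenset[URIRef]]:
    """Per-dataset graph sets able to answer the whole group: the
    intersection over the group's patterns of their selected graphs."""
    per_dataset: Optional[dict[str, set[URIRef]]] = None
    for t in group.patterns:
        pairs = bgp_selection.get(t, frozenset())
        this: dict[str, set[URIRef]] = {}
        for ds_id, u in pairs:
            this.setdefault(ds_id, set()).add(u)
        if per_dataset is None:
            per_dataset = this
        else:
            per_dataset = {
                ds_id: per_dataset[ds_id] & graphs
                for ds_id, graphs in this.items()
                if ds_id in per_dataset
            }
    if per_dataset is None:
        return {}
    return {
        ds_id: frozenset(graphs)
        for ds_id, graphs in per_dataset.items()
        if graphs
    }


def evaluate_group(
    g: SubjectGroup,
    dataset_graphs: Mapping[str, frozenset[URIRef]],
    clients: Mapping[str, EndpointClient],
) -> list[Row]:
    """Union of the group's sub-query answers over its selected sources."""
    rows: list[Row] = []
    for ds_id in sorted(dataset_graphs):
        query = rewrite_subquery(g, dataset_graphs[ds_id])
        for row in clients[ds_id].select(query):
            row.pop(_GRAPH_VAR, None)
            rows.append(row)
    return rows


# --------------------------------------------------------------------------
# local join machinery

def _compatible_merge(a: Row, b: Row) -> Optional[Row]:
    for v, t in b.items():
        if v in a and a[v] != t:
            return None
    merged = dict(a)
    merged.update(b)
    return merged


def _hash_join(left: list[Row], right: list[Row], shared: frozenset[Variable]) -> list[Row]:
    if not shared:
        return [m for a in left for b in right if (m := _compatible_merge(a, b))]
    table: dict[tuple, list[Row]] = {}
    for b in right:
        key = tuple(b.get(v) for v in sorted(shared))
        table.setdefault(key, []).append(b)
    out: list[Row] = []
    for a in left:
        key = tuple(a.get(v) for v in sorted(shared))
        for b in table.get(key, []):
            merged = _compatible_merge(a, b)
            if merged is not None:
                out.append(merged)
    return out


def join_groups(
    results: Sequence[tuple[list[Row], frozenset[Variable]]],
) -> list[Row]:
    """Natural join of per-group result multisets.

    Joined smallest-first (observed cardinality, ties by given order);
    disjoint variable sets degenerate to a cross product.
    """
    if not results:
        return [{}]
    order = sorted(range(len(results)), key=lambda i: (len(results[i][0]), i))
    rows, bound = results[order[0]]
    rows = list(rows)
    for i in order[1:]:
        other_rows, other_vars = results[i]
        rows = _hash_join(rows, other_rows, bound & other_vars)
        bound = bound | other_vars
        if not rows:
            break
    return rows


_EBV_CTX = QueryContext(initBindings={})


def _filter_passes(exprs: Iterable, row: Row) -> bool:
    frozen = FrozenBindings(_EBV_CTX, row)
    for expr in exprs:
        try:
            if not _ebv(expr, frozen):
                return False
        except (SPARQLError, TypeError):
            return False  # type errors in a FILTER eliminate the row
    return True


def _left_join(left: list[Row], right: list[Row], exprs: list) -> list[Row]:
    out: list[Row] = []
    for a in left:
        matched = False
        for b in right:
            merged = _compatible_merge(a, b)
            if merged is not None and _filter_passes(exprs, merged):
                out.append(merged)
                matched = True
        if not matched:
            out.append(dict(a))
    return out


# --------------------------------------------------------------------------
# solution modifiers

def _order_key(term) -> tuple:
    # SPARQL ordering: unbound < IRIs < literals; numeric literals
    # compare by value, others lexically by (datatype, form).
    if term is None:
        return (0, "", 0.0, "")
    if isinstance(term, URIRef):
        return (1, str(term), 0.0, "")
    if isinstance(term, Literal):
        try:
            return (2, "", float(term.toPython()), str(term))
        except (ValueError, TypeError):
            return (3, str(term.datatype or ""), 0.0, str(term))
    return (4, str(term), 0.0, "")


def _apply_order(rows: list[Row], order_by: list[tuple]) -> list[Row]:
    for expr, descending in reversed(order_by):
        def key(row: Row):
            if isinstance(expr, Variable):
                term = row.get(expr)
            else:
                try:
                    term = expr.eval(FrozenBindings(_EBV_CTX, row))
                except (SPARQLError, TypeError):
                    term = None
            return _order_key(term)

        rows = sorted(rows, key=key, reverse=descending)
    return rows


def _apply_modifiers(rows: list[Row], plan: QueryPlan) -> list[Row]:
    rows = [
        {v: t for v, t in row.items() if v in plan.projection}
        for row in rows
    ]
    if plan.distinct:
        seen = set()
        unique = []
        for row in rows:
            key = frozenset(row.items())
            if key not in seen:
                seen.add(key)
                unique.append(row)
        rows = unique
    if plan.order_by:
        rows = _apply_order(rows, plan.order_by)
    if plan.offset:
        rows = rows[plan.offset:]
    if plan.limit is not None:
        rows = rows[: plan.limit]
    return rows


# --------------------------------------------------------------------------
# end-to-end pipeline

def evaluate_plan(
    plan: QueryPlan,
    sel: SelectionResult,
    clients: Mapping[str, EndpointClient],
) -> ResultSet:
    """Evaluate a parsed plan against an already-computed selection.

    Exposed separately so a selection can be inspected or perturbed
    (e.g. force-adding a pruned source) before execution.
    """
    n_branches = len(plan.branches)
    opt_index = n_branches  # optional BGPs follow the branch BGPs in plan.bgps
    all_rows: list[Row] = []
    for i, branch in enumerate(plan.branches):
        bgp_sel = sel.per_bgp[i]
        group_results: list[tuple[list[Row], frozenset[Variable]]] = []
        for group in group_by_subject(branch.patterns):
            dataset_graphs = _group_dataset_graphs(group, bgp_sel)
            rows = evaluate_group(group, dataset_graphs, clients)
            group_results.append((rows, group.variables()))
        branch_rows = join_groups(group_results)
        for block in branch.optionals:
            block_sel = sel.per_bgp[opt_index]
            opt_index += 1
            block_results = []
            for group in group_by_subject(block.patterns):
                dataset_graphs = _group_dataset_graphs(group, block_sel)
                rows = evaluate_group(group, dataset_graphs, clients)
                block_results.append((rows, group.variables()))
            branch_rows = _left_join(
                branch_rows, join_groups(block_results), block.exprs
            )
        if branch.filters:
            branch_rows = [
                r for r in branch_rows if _filter_passes(branch.filters, r)
            ]
        all_rows.extend(branch_rows)
    rows = _apply_modifiers(all_rows, plan)
    return ResultSet(
        rows=rows,
        variables=list(plan.projection),
        ordered=bool(plan.order_by),
        selection=sel,
    )


def execute(
    query: str,
    fed: Federation,
    index: Optional[SummaryIndex] = None,
    policy: Optional[AccessPolicy] = None,
    user: Optional[Union[str, URIRef]] = None,
    clients: Optional[Mapping[str, EndpointClient]] = None,
) -> ResultSet:
    """End-to-end pipeline: parse, select, policy-filter, evaluate, join.

    Summaries are built on the fly when no index is given (in-memory
    federations only).  With a policy, ``user`` is required and no
    sub-query is dispatched to a graph the user may not read.
    """
    if policy is not None and user is None:
        raise ConfigurationError("a policy requires a user IRI")
    if index is None:
        index = derive_indexes(build_summary(ds) for ds in fed.datasets)
    missing = [ds.id for ds in fed.datasets if ds.id not in index.summaries]
    if missing:
        raise ConfigurationError(f"no summary for datasets: {missing}")
    if clients is None:
        clients = clients_for(fed)
    before_select = sum(c.select_count for c in clients.values())

    plan = parse_query(query)
    sel = select_sources(plan, index, clients)
    if policy is not None:
        sel = filter_selection(sel, policy, URIRef(user))
    result = evaluate_plan(plan, sel, clients)
    result.metrics = ExecutionMetrics(
        ask_requests=sel.ask_count,
        select_subqueries=sum(c.select_count for c in clients.values())
        - before_select,
        pattern_sources=sel.total_pattern_sources(),
        selected_pairs=len(sel.all_pairs()),
    )
    return result


def evaluate_merged(
    query: str,
    fed: Federation,
    graph_names: Optional[Iterable[URIRef]] = None,
) -> ResultSet:
    """Brute-force oracle: evaluate the query over the merged federation.

    All triples of all named graphs (or only the given graphs, for the
    policy-restricted oracle) are merged into one local graph and the
    query is evaluated by rdflib's SPARQL engine.  Ignores policies and
    summaries entirely; used to check federated execution, never as part
    of it.
    """
    merged = fed.merged_graph(graph_names)
    res = merged.query(query)
    rows: list[Row] = []
    for binding in res:
        rows.append(
            {v: t for v, t in zip(res.vars, binding) if t is not None}
        )
    plan = parse_query(query)
    return ResultSet(
        rows=rows,
        variables=list(res.vars),
        ordered=bool(plan.order_by),
    )
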