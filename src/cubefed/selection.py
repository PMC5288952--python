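"""Two-level, join-aware source selection.

Selection maps every triple pattern of every BGP to the set of
``(dataset_id, graph)`` pairs that can contribute answers.  It works at
two levels: first datasets (endpoints), then named graphs within a
dataset — the granularity required for graph-level access control.

The join-aware step exploits subject locality of data cubes.  For each
subject group (s-s join) of a BGP:

1. A dataset is a candidate only if it contains *all* bound predicates
   of the group — under locality the whole group must be answered inside
   one graph of one dataset.
2. Within a candidate dataset, predicates unique to a single graph pin
   the group: if the group mentions a predicate unique to graph ``u``,
   only ``u`` can be relevant; if it mentions predicates unique to two
   *different* graphs, no graph of that dataset can answer the group and
   the dataset is discarded; otherwise all graphs remain.
3. Each pattern's final set is the group restriction intersected with
   the graphs actually containing the pattern's predicate (a strictly
   tightening step: predicate presence is necessary to match).

Patterns with an unbound predicate inherit their subject group's
restriction when the group has bound predicates.  Otherwise, when the
subject or object is bound, one single-triple-pattern ASK probe per
dataset decides relevance (all graphs of an affirming dataset are
added); with nothing bound, probing is uninformative and all graphs of
all datasets are selected without any ASK.

Selection is computed per BGP: the same pattern may select different
sources in different UNION/OPTIONAL branches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

from rdflib import URIRef, Variable

from .clients import EndpointClient
from .query import QueryPlan, QueryTerm, SubjectGroup, TriplePattern, group_by_subject
from .summary import SummaryIndex

#: A selected source: (dataset id, graph IRI).
SourcePair = tuple[str, URIRef]


@dataclass(frozen=True)
class SkippedDataset:
    """Diagnostic record: why a dataset was discarded for a group."""

    subject: QueryTerm
    dataset_id: str
    reason: str


@dataclass
class SelectionResult:
    """Per-BGP map from triple pattern to selected source pairs."""

    per_bgp: list[dict[TriplePattern, frozenset[SourcePair]]]
    ask_count: int = 0
    skipped_datasets: list[SkippedDataset] = field(default_factory=list)

    def pairs(self, bgp_index: int, pattern: TriplePattern) -> frozenset[SourcePair]:
        return self.per_bgp[bgp_index].get(pattern, frozenset())

    def all_pairs(self) -> frozenset[SourcePair]:
        out: set[SourcePair] = set()
        for bgp in self.per_bgp:
            for pairs in bgp.values():
                out |= pairs
        return frozenset(out)

    def selected_graphs(self) -> frozenset[URIRef]:
        return frozenset(g for _, g in self.all_pairs())

    def selected_datasets(self) -> frozenset[str]:
        return frozenset(d for d, _ in self.all_pairs())

    def total_pattern_sources(self) -> int:
        """Triple-pattern-wise count of selected datasets, summed over
        patterns (the comparable granularity across engines)."""
        return sum(
            len({d for d, _ in pairs})
            for bgp in self.per_bgp
            for pairs in bgp.values()
        )


@dataclass
class GroupSelection:
    """Outcome of selecting sources for one subject group."""

    group: SubjectGroup
    candidates: dict[str, frozenset[URIRef]]  # dataset -> graph restriction
    per_pattern: dict[TriplePattern, frozenset[SourcePair]]
    skipped: list[SkippedDataset]


def select_for_group(g: SubjectGroup, index: SummaryIndex) -> GroupSelection:
    """Join-aware selection for one subject group with bound predicates.

    See the module docstring for the dataset-candidacy and
    unique-predicate pinning rules.
    """
    bound = g.bound_preds
    candidates: dict[str, frozenset[URIRef]] = {}
    skipped: list[SkippedDataset] = []
    per_pattern: dict[TriplePattern, set[SourcePair]] = {
        t: set() for t in g.patterns if t.predicate_bound
    }
    for ds_id in index.dataset_ids():
        summary = index.summaries[ds_id]
        if not bound <= index.preds[ds_id]:
            missing = sorted(str(p) for p in bound - index.preds[ds_id])
            skipped.append(
                SkippedDataset(g.subject, ds_id, f"missing predicates: {missing}")
            )
            continue
        pinned = {
            u
            for u, unique in index.upreds.get(ds_id, {}).items()
            if unique & bound
        }
        if len(pinned) > 1:
            skipped.append(
                SkippedDataset(
                    g.subject,
                    ds_id,
                    "predicates unique to different graphs: "
                    + ", ".join(sorted(str(u) for u in pinned)),
                )
            )
            continue
        if len(pinned) == 1:
            restriction = frozenset(pinned)
        else:
            restriction = summary.graph_names
        candidates[ds_id] = restriction
        for t in per_pattern:
            per_pattern[t] |= {
                (ds_id, u)
                for u in restriction & summary.pred_to_graphs.get(t.p, frozenset())
            }
    return GroupSelection(
        group=g,
        candidates=candidates,
        per_pattern={t: frozenset(p) for t, p in per_pattern.items()},
        skipped=skipped,
    )


def _ask_probe(pattern: TriplePattern) -> str:
    s = pattern.s.n3() if not isinstance(pattern.s, Variable) else "?__s"
    o = pattern.o.n3() if not isinstance(pattern.o, Variable) else "?__o"
    return f"ASK {{ GRAPH ?__g {{ {s} ?__p {o} }} }}"


def resolve_unbound(
    pattern: TriplePattern,
    group_restriction: Optional[dict[str, frozenset[URIRef]]],
    index: SummaryIndex,
    clients: Optional[Mapping[str, EndpointClient]] = None,
) -> tuple[frozenset[SourcePair], int]:
    """Select sources for a pattern whose predicate is a variable.

    Returns the selected pairs and the number of ASK probes issued.
    """
    if group_restriction is not None:
        pairs = frozenset(
            (ds_id, u)
            for ds_id, graphs in group_restriction.items()
            for u in graphs
        )
        return pairs, 0
    s_bound = not isinstance(pattern.s, Variable)
    o_bound = not isinstance(pattern.o, Variable)
    if not (s_bound or o_bound):
        pairs = frozenset(
            (ds_id, u)
            for ds_id, summary in index.summaries.items()
            for u in summary.graph_names
        )
        return pairs, 0
    if clients is None:
        raise ValueError(
            "ASK probing requires endpoint clients (pattern "
            f"{pattern} has an unbound predicate and a bound subject/object)"
        )
    probe = _ask_probe(pattern)
    pairs: set[SourcePair] = set()
    asks = 0
    for ds_id in index.dataset_ids():
        asks += 1
        if clients[ds_id].ask(probe):
            pairs |= {(ds_id, u) for u in index.summaries[ds_id].graph_names}
    return frozenset(pairs), asks


def select_sources(
    plan: QueryPlan,
    index: SummaryIndex,
    clients: Optional[Mapping[str, EndpointClient]] = None,
) -> SelectionResult:
    """Run source selection for every BGP of the plan.

    ``clients`` is only consulted for ASK probes; a fully
    predicate-bound query never contacts any endpoint.
    """
    per_bgp: list[dict[TriplePattern, frozenset[SourcePair]]] = []
    ask_count = 0
    skipped: list[SkippedDataset] = []
    for bgp in plan.bgps:
        result: dict[TriplePattern, frozenset[SourcePair]] = {}
        for group in group_by_subject(bgp):
            restriction: Optional[dict[str, frozenset[URIRef]]] = None
            if group.bound_preds:
                gsel = select_for_group(group, index)
                result.update(gsel.per_pattern)
                skipped.extend(gsel.skipped)
                restriction = gsel.candidates
            for t in group.patterns:
                if t.predicate_bound:
                    continue
                pairs, asks = resolve_unbound(t, restriction, index, clients)
                ask_count += asks
                result[t] = pairs
        per_bgp.append(result)
    return SelectionResult(
        per_bgp=per_bgp, ask_count=ask_count, skipped_datasets=skipped
    )


def naive_selection(plan: QueryPlan, index: SummaryIndex) -> SelectionResult:
    """Baseline: triple-pattern-wise predicate matching, no join
    awareness.  Every pattern is matched independently against the
    summaries; unbound-predicate patterns match everything.  Used as the
    granularity reference: join-aware selection never touches a dataset
    this baseline does not."""
    per_bgp = []
    for bgp in plan.bgps:
        result = {}
        for t in bgp:
            pairs: set[SourcePair] = set()
            for ds_id, summary in index.summaries.items():
                if t.predicate_bound:
                    pairs |= {
                        (ds_id, u)
                        for u in summary.pred_to_graphs.get(t.p, frozenset())
                    }
                else:
                    pairs |= {(ds_id, u) for u in summary.graph_names}
            result[t] = frozenset(pairs)
        per_bgp.append(result)
    return SelectionResult(per_bgp=per_bgp)
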