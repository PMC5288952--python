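"""Join-aware two-level source selection."""

import random

import pytest
from rdflib import Variable

from cubefed import (
    evaluate_merged,
    execute,
    naive_selection,
    parse_query,
    random_conjunctive_query,
    random_federation,
    build_summary,
    derive_indexes,
    resolve_unbound,
    select_for_group,
    select_sources,
    group_by_subject,
)
from cubefed.clients import clients_for
from cubefed.fixtures import SUBJECT_SELECTION_QUERY, _PREFIXES
from cubefed.namespaces import EX, QB, RDF, SEHR

THREE_PAIRS = frozenset(
    {
        ("CHUV", EX["CHUV-S1"]),
        ("CING", EX["CING-S2"]),
        ("ZEINCRO", EX["ZEINCRO-S3"]),
    }
)
ALL_PAIRS = THREE_PAIRS | {("CHUV", EX["CHUV-S4"])}


def _group(plan, subject):
    return next(
        g
        for g in group_by_subject(plan.bgps[0])
        if g.subject == Variable(subject)
    )


def test_worked_example_selection(example_index):
    """The observation group selects exactly three dataset-graph pairs;
    the dataset-typing pattern matches all four graphs; no ASKs."""
    plan = parse_query(SUBJECT_SELECTION_QUERY)
    sel = select_sources(plan, example_index)
    groups = {g.subject: g for g in group_by_subject(plan.bgps[0])}
    for t in groups[Variable("observation")].patterns:
        assert sel.pairs(0, t) == THREE_PAIRS
    (dataset_pattern,) = groups[Variable("dataset")].patterns
    assert sel.pairs(0, dataset_pattern) == ALL_PAIRS
    assert sel.ask_count == 0


def test_unique_predicates_pin_chuv_to_s1(example_index):
    """CHUV-S4 is excluded even for patterns (Diabetes, Cases) it could
    match on its own: the group's BMI/Hypertension patterns pin CHUV to
    CHUV-S1."""
    plan = parse_query(SUBJECT_SELECTION_QUERY)
    gsel = select_for_group(_group(plan, "observation"), example_index)
    assert gsel.candidates["CHUV"] == frozenset({EX["CHUV-S1"]})
    diabetes = next(
        t
        for t in gsel.per_pattern
        if t.p == SEHR.Diabetes
    )
    assert ("CHUV", EX["CHUV-S4"]) not in gsel.per_pattern[diabetes]


def test_conflicting_unique_predicates_discard_dataset(example, example_index):
    """Smoking is unique to CHUV-S4, Hypertension to CHUV-S1: no CHUV
    graph can answer a group joining both, so CHUV is discarded — and
    the query is indeed empty everywhere."""
    query = _PREFIXES + (
        "SELECT * WHERE { ?o sehr:Smoking ?s . ?o sehr:Hypertension ?h }"
    )
    plan = parse_query(query)
    sel = select_sources(plan, example_index)
    assert sel.all_pairs() == frozenset()
    assert any(
        s.dataset_id == "CHUV" and "unique" in s.reason
        for s in sel.skipped_datasets
    )
    assert len(evaluate_merged(query, example.federation).rows) == 0


def test_absent_predicate_empty_selection(example_index):
    query = _PREFIXES + "SELECT * WHERE { ?o sehr:HIV ?v }"
    sel = select_sources(parse_query(query), example_index)
    assert sel.all_pairs() == frozenset()


def test_unbound_predicate_inherits_group_restriction(example_index):
    """An unbound-predicate pattern in a group with bound predicates
    inherits the group's graph restriction without any ASK."""
    query = _PREFIXES + (
        "SELECT * WHERE { ?o sehr:BMI_Abnormal ?b . ?o ?p ?v }"
    )
    plan = parse_query(query)
    sel = select_sources(plan, example_index)
    unbound = next(t for t in plan.bgps[0] if not t.predicate_bound)
    assert sel.pairs(0, unbound) == THREE_PAIRS
    assert sel.ask_count == 0


def test_bound_subject_unbound_predicate_probes_each_dataset(
    example, example_index, example_clients
):
    """A singleton group with a constant subject issues one ASK per
    dataset; only the graph-owning dataset answers true."""
    subject = EX["CHUV-S1"] + "/obs_7"
    query = f"SELECT * WHERE {{ <{subject}> ?p ?o }}"
    plan = parse_query(query)
    sel = select_sources(plan, example_index, example_clients)
    assert sel.ask_count == 3
    assert sum(c.ask_count for c in example_clients.values()) == 3
    (pattern,) = plan.bgps[0]
    assert sel.pairs(0, pattern) == frozenset(
        {("CHUV", EX["CHUV-S1"]), ("CHUV", EX["CHUV-S4"])}
    )


def test_fully_unbound_singleton_selects_everything(example_index):
    plan = parse_query("SELECT * WHERE { ?s ?p ?o }")
    sel = select_sources(plan, example_index)
    (pattern,) = plan.bgps[0]
    assert sel.pairs(0, pattern) == ALL_PAIRS
    assert sel.ask_count == 0


def test_resolve_unbound_requires_clients_for_probing(example_index):
    plan = parse_query(f"SELECT * WHERE {{ <{EX['CHUV-S1']}/obs_0> ?p ?o }}")
    (pattern,) = plan.bgps[0]
    with pytest.raises(ValueError, match="ASK"):
        resolve_unbound(pattern, None, example_index, clients=None)


def test_per_bgp_selection_kept_separate(example_index):
    """UNION branches select independently: a pattern shape restricted
    by its group in one branch may match more graphs in another."""
    query = _PREFIXES + (
        "SELECT * WHERE { "
        "{ ?o sehr:Diabetes ?d . ?o sehr:Smoking ?s } "
        "UNION { ?o sehr:Diabetes ?d } }"
    )
    plan = parse_query(query)
    sel = select_sources(plan, example_index)
    diabetes_b0 = next(t for t in plan.bgps[0] if t.p == SEHR.Diabetes)
    diabetes_b1 = next(t for t in plan.bgps[1] if t.p == SEHR.Diabetes)
    assert sel.pairs(0, diabetes_b0) == frozenset({("CHUV", EX["CHUV-S4"])})
    assert sel.pairs(1, diabetes_b1) == ALL_PAIRS


def test_ask_count_zero_for_predicate_bound_queries():
    rng = random.Random(11)
    for seed in range(5):
        fed = random_federation(seed)
        idx = derive_indexes(build_summary(ds) for ds in fed.datasets)
        for _ in range(4):
            query = random_conjunctive_query(fed, rng)
            plan = parse_query(query)
            clients = clients_for(fed)
            sel = select_sources(plan, idx, clients)
            if all(t.predicate_bound for bgp in plan.bgps for t in bgp):
                assert sel.ask_count == 0
                assert sum(c.ask_count for c in clients.values()) == 0


def test_join_aware_selection_is_granularity_monotone():
    """Datasets touched by join-aware selection are a subset of those a
    naive per-pattern predicate match selects."""
    rng = random.Random(23)
    for seed in range(8):
        fed = random_federation(seed)
        idx = derive_indexes(build_summary(ds) for ds in fed.datasets)
        for _ in range(4):
            plan = parse_query(random_conjunctive_query(fed, rng))
            clients = clients_for(fed)
            safe = select_sources(plan, idx, clients)
            naive = naive_selection(plan, idx)
            assert safe.selected_datasets() <= naive.selected_datasets()
            for bgp_i in range(len(plan.bgps)):
                for t in plan.bgps[bgp_i]:
                    if t.predicate_bound:
                        assert safe.pairs(bgp_i, t) <= naive.pairs(bgp_i, t)
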