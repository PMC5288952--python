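"""Federated execution against the merged-dataset oracle."""

import random

import pytest
from rdflib import Literal, URIRef, Variable

from cubefed import (
    build_summary,
    clients_for,
    derive_indexes,
    evaluate_merged,
    execute,
    group_by_subject,
    join_groups,
    parse_query,
    random_conjunctive_query,
    random_federation,
    random_policy,
    rewrite_subquery,
)
from cubefed.errors import ConfigurationError
from cubefed.fixtures import _PREFIXES
from cubefed.namespaces import EX, SEHR


def _obs_group(plan):
    return next(
        g
        for g in group_by_subject(plan.bgps[0])
        if g.subject == Variable("observation")
    )


class TestRewriteSubquery:
    def test_values_lists_exactly_the_graphs(self, example):
        plan = parse_query(example.queries["subject-selection"])
        group = _obs_group(plan)
        q = rewrite_subquery(group, [EX["CHUV-S1"]])
        assert q.count(EX["CHUV-S1"].n3()) == 1
        assert "VALUES" in q and "GRAPH ?__g" in q
        q2 = rewrite_subquery(group, [EX["CHUV-S1"], EX["CHUV-S4"]])
        assert EX["CHUV-S1"].n3() in q2 and EX["CHUV-S4"].n3() in q2

    def test_reproducible_regardless_of_graph_order(self, example):
        plan = parse_query(example.queries["subject-selection"])
        group = _obs_group(plan)
        a = rewrite_subquery(group, [EX["CHUV-S1"], EX["CHUV-S4"]])
        b = rewrite_subquery(group, [EX["CHUV-S4"], EX["CHUV-S1"]])
        assert a == b

    def test_zero_graphs_rejected(self, example):
        plan = parse_query(example.queries["subject-selection"])
        with pytest.raises(ValueError):
            rewrite_subquery(_obs_group(plan), [])


class TestJoinGroups:
    A, B, C = Variable("a"), Variable("b"), Variable("c")

    def test_shared_variable_natural_join(self):
        left = [{self.A: Literal(1), self.B: Literal(1)},
                {self.A: Literal(2), self.B: Literal(2)}]
        right = [{self.B: Literal(1), self.C: Literal(9)}]
        out = join_groups(
            [(left, frozenset({self.A, self.B})),
             (right, frozenset({self.B, self.C}))]
        )
        assert out == [
            {self.A: Literal(1), self.B: Literal(1), self.C: Literal(9)}
        ]

    def test_disjoint_variables_cross_product(self):
        left = [{self.A: Literal(1)}, {self.A: Literal(2)}]
        right = [{self.B: Literal(3)}, {self.B: Literal(4)}]
        out = join_groups(
            [(left, frozenset({self.A})), (right, frozenset({self.B}))]
        )
        assert len(out) == 4

    def test_empty_input_yields_unit(self):
        assert join_groups([]) == [{}]


def test_restricted_query_returns_26_cases(example):
    """Diabetes=1, Hypertension=1, BMI_Abnormal=0 returns the 26-cases
    observation of CHUV-S1 plus one row per other contributing cube."""
    result = execute(example.queries["restricted"], example.federation)
    assert len(result.rows) == 3
    by_dataset = {
        str(row[Variable("dataset")]): row[Variable("cases")].toPython()
        for row in result.rows
    }
    assert by_dataset[str(EX["CHUV-S1"]) + "/dataset"] == 26
    assert result == evaluate_merged(
        example.queries["restricted"], example.federation
    )


def test_policy_restricts_results_to_authorised_cubes(example):
    result = execute(
        example.queries["restricted"],
        example.federation,
        policy=example.policy,
        user=example.user,
    )
    datasets = {str(row[Variable("dataset")]) for row in result.rows}
    assert datasets == {
        str(EX["CHUV-S1"]) + "/dataset",
        str(EX["CING-S2"]) + "/dataset",
    }
    oracle = evaluate_merged(
        example.queries["restricted"],
        example.federation,
        graph_names=example.policy.readable_graphs(example.user),
    )
    assert result == oracle


def test_policy_without_user_is_an_error(example):
    with pytest.raises(ConfigurationError):
        execute(
            example.queries["restricted"],
            example.federation,
            policy=example.policy,
        )


def test_unauthorised_user_gets_empty_result_without_subqueries(example):
    from cubefed import AccessPolicy

    clients = clients_for(example.federation)
    result = execute(
        example.queries["restricted"],
        example.federation,
        policy=AccessPolicy.of(),
        user=EX.Nobody,
        clients=clients,
    )
    assert result.rows == []
    assert result.metrics.select_subqueries == 0
    assert all(c.select_count == 0 for c in clients.values())


def test_execution_is_deterministic(example):
    a = execute(example.queries["subject-selection"], example.federation)
    b = execute(example.queries["subject-selection"], example.federation)
    assert a.rows == b.rows


def test_missing_summary_is_a_configuration_error(example):
    partial = derive_indexes(
        [build_summary(example.federation.dataset("CHUV"))]
    )
    with pytest.raises(ConfigurationError, match="no summary"):
        execute(
            example.queries["restricted"], example.federation, index=partial
        )


@pytest.mark.parametrize(
    "query",
    [
        # UNION of two dimension restrictions
        _PREFIXES + """
        SELECT ?o ?v WHERE {
          { ?o sehr:Smoking ?v } UNION { ?o sehr:Hypertension ?v }
        }""",
        # OPTIONAL: smoking data exists only in CHUV-S4
        _PREFIXES + """
        SELECT ?o ?d ?s WHERE {
          ?o sehr:Diabetes ?d
          OPTIONAL { ?o sehr:Smoking ?s }
        }""",
        # FILTER with a comparison and REGEX over a stringified IRI
        _PREFIXES + """
        SELECT ?o ?c WHERE {
          ?o sehr:Cases ?c .
          FILTER(?c > 30 && regex(str(?o), "CING"))
        }""",
        # DISTINCT + ORDER BY + LIMIT/OFFSET
        _PREFIXES + """
        SELECT DISTINCT ?c WHERE { ?o sehr:Cases ?c }
        ORDER BY DESC(?c) LIMIT 5 OFFSET 2""",
        # cross-group join through the cube node
        _PREFIXES + """
        SELECT ?ds ?c WHERE {
          ?ds rdf:type qb:DataSet .
          ?o qb:dataSet ?ds .
          ?o sehr:Cases ?c .
          FILTER(?c = 26)
        }""",
    ],
    ids=["union", "optional", "filter-regex", "modifiers", "cross-group"],
)
def test_supported_fragment_matches_oracle(example, query):
    assert execute(query, example.federation) == evaluate_merged(
        query, example.federation
    )


def test_random_suite_small_sweep():
    """Spot-check: federated execution equals the merged oracle on a
    handful of random federations and conjunctive queries (the full
    sweep runs in the acceptance suite)."""
    rng = random.Random(99)
    for seed in range(8):
        fed = random_federation(seed)
        idx = derive_indexes(build_summary(ds) for ds in fed.datasets)
        for _ in range(3):
            query = random_conjunctive_query(fed, rng)
            assert execute(query, fed, index=idx) == evaluate_merged(query, fed)
        policy = random_policy(fed, rng)
        if policy.users():
            (user,) = policy.users()
            query = random_conjunctive_query(fed, rng)
            assert execute(
                query, fed, index=idx, policy=policy, user=user
            ) == evaluate_merged(
                query, fed, graph_names=policy.readable_graphs(user)
            )


def test_ask_probe_counters_are_exact(example, example_index):
    clients = clients_for(example.federation)
    subject = EX["CING-S2"] + "/obs_3"
    result = execute(
        f"SELECT * WHERE {{ <{subject}> ?p ?o }}",
        example.federation,
        index=example_index,
        clients=clients,
    )
    assert result.metrics.ask_requests == 3
    assert sum(c.ask_count for c in clients.values()) == 3
    # every row is sourced from the one graph owning the subject
    assert len(result.rows) == 6
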