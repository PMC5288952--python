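# cubefed

Policy-aware federated SPARQL querying over collections of RDF data
cubes held in named graphs across multiple sources.

## The problem

Clinical and other statistical organisations publish aggregated data as
RDF data cubes (W3C QB vocabulary): each cube is a `qb:DataSet` whose
`qb:Observation` instances carry dimension values (e.g. *Diabetes = 1*,
*Hypertension = 1*) and a measure (e.g. a patient count). Each cube
lives in its own named graph behind its owner's SPARQL endpoint, and
access is tightly controlled: a researcher may read some cubes and not
others, with grants expressed at the granularity of named graphs.

Answering a cross-site query ("how many cases combine diabetes and
hypertension without abnormal BMI, per site?") therefore needs a
federation engine whose *source selection* works at the level of
graphs, not endpoints — both so that access control can be enforced
before any request leaves the client, and because the structure of data
cubes makes much sharper selection possible.

## The method

**Instance-free data summaries.** For each dataset `D` the engine
indexes only the endpoint URL `loc(D)`, the graph names, and a map from
each predicate to the graphs containing it. No subjects, objects or
counts are stored, so the summary cannot leak instance data and its
size is independent of the number of observations. Derived indexes:
`preds(D)` (all predicates of `D`), `upreds(u, D)` (predicates occurring
in exactly one graph `u` of `D`) and `unames(D)` (graphs with at least
one unique predicate).

**Join-aware two-level selection.** Cubes are self-contained: a subject
(an observation) occurs in at most one named graph federation-wide
(the *locality* assumption). Hence all triple patterns of a BGP sharing
a subject — a subject group, an s–s join — must be answered inside one
graph. For each subject group with bound predicate set `P`:

* dataset `D` is a candidate iff `P ⊆ preds(D)`;
* inside a candidate, if `P` meets `upreds(u, D)` for exactly one graph
  `u`, the group is pinned to `u`; if it meets unique predicates of two
  different graphs, `D` is discarded entirely; otherwise all graphs of
  `D` remain;
* each pattern's final sources are the group restriction intersected
  with the graphs containing its predicate.

Patterns with unbound predicates inherit their group's restriction;
only an isolated pattern with a bound subject or object triggers one
ASK probe per dataset. A fully predicate-bound query sends **zero**
ASK queries.

**Policy filtering.** An access policy is a set of
`(user, graph, right)` grants with default deny. Every selected
`(dataset, graph)` pair whose graph the user may not read is removed
*before* execution, so no sub-query ever names an unauthorised graph.

**Execution.** Each subject group is pushed as one sub-query per
selected dataset, restricted to its graphs with `GRAPH ?__g` plus an
inline `VALUES` clause; results are unioned per group and joined
locally (hash join, smallest intermediate first), then OPTIONAL /
UNION / FILTER / DISTINCT / ORDER BY / LIMIT are applied. A
brute-force oracle evaluates the same query over the merge of all
named graphs; the engine is correct when

```
[[𝔇]]_bgp = [[R(t₁)]]_t₁ ⋈ … ⋈ [[R(tₙ)]]_tₙ
```

holds for every BGP — checked as multiset equality of the two result
sets on seeded random federations.

## Worked example

The bundled clinical federation has three datasets — CHUV with cubes
`:CHUV-S1` (Diabetes, BMI_Abnormal, Hypertension / Cases) and
`:CHUV-S4` (Smoking, Gender, Diabetes / Cases), CING with `:CING-S2`
and ZEINCRO with `:ZEINCRO-S3` (both Diabetes, BMI_Abnormal,
Hypertension / Cases). User `:James` may read `:CHUV-S1` and
`:CING-S2` only.

```bash
cubefed generate --out demo --example
cubefed index  --config demo/federation.yaml --out demo/summaries
cubefed select demo/queries/subject-selection.rq \
    --config demo/federation.yaml --summaries demo/summaries
```

The subject-selection query (7 triple patterns, 2 subject groups) asks
for cases by combination of the three clinical dimensions. Because
`sehr:BMI_Abnormal` and `sehr:Hypertension` are unique to `:CHUV-S1`
within CHUV, the observation group is pinned there — `:CHUV-S4` is
never selected even though it holds Diabetes and Cases triples — and
the report ends:

```
totals: 21 pattern-wise sources, 4 dataset-graph pairs, 0 ASK requests
```

Executing the variant restricted to Diabetes=1, Hypertension=1,
BMI_Abnormal=0:

```bash
cubefed query demo/queries/restricted.rq --config demo/federation.yaml --format tsv
```

```
?dataset	?cases
<http://example.org/l2s#CHUV-S1/dataset>	"26"^^<http://www.w3.org/2001/XMLSchema#integer>
<http://example.org/l2s#CING-S2/dataset>	"31"^^<http://www.w3.org/2001/XMLSchema#integer>
<http://example.org/l2s#ZEINCRO-S3/dataset>	"14"^^<http://www.w3.org/2001/XMLSchema#integer>
```

one count per contributing cube — 26 cases at CHUV site S1. Adding
`--policy demo/policy.ttl --user http://example.org/l2s#James` drops
the ZEINCRO row and no request to ZEINCRO is ever issued.

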