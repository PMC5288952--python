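# Methods

## Setting and assumptions

A federation is a set of RDF datasets, each a set of named graphs
behind one SPARQL endpoint; every named graph holds one RDF data cube
(QB vocabulary). Three structural assumptions underpin the engine:

1. **No default graph.** All triples live in named graphs; graph names
   are globally unique. Both are enforced at load time: a default-graph
   triple or a duplicate graph name is an error, never a silent drop,
   so fixtures cannot accidentally hide data from selection.
2. **No blank nodes.** Blank nodes are a known obstacle to completeness
   in federated evaluation. Loading data containing them is an error;
   we deliberately do not skolemise, which would silently change the
   data.
3. **Subject locality.** A subject IRI occurs in at most one named
   graph anywhere in the federation. This reflects cubes being
   self-contained: observations, cube nodes and slices are not split
   across graphs. Locality is *assumed*, not enforced: real deployments
   may only be able to assert it contractually, so `validate_locality`
   is offered as an optional in-memory check rather than a load-time
   gate. Dimension values and predicates are of course shared across
   graphs — locality applies to subjects only.

## Data summaries

Per dataset: endpoint URL, graph names, and predicate → graphs map.
Nothing else — no VoID triple counts, no capability hashes, no instance
data. Consequences: the summary's size depends only on the schema
(tested by inflating observation counts 10× and comparing serialised
bytes), it cannot leak observations, and it is cheap to recompute from
scratch when a source changes (there is deliberately no incremental
maintenance).

`rdf:type` and QB structural predicates (`qb:dataSet`, …) are indexed
exactly like domain predicates: a `?x rdf:type qb:DataSet` pattern
should match every graph containing such a triple, and uniqueness of a
structural predicate within a dataset is as informative as uniqueness
of a clinical one.

Derived indexes (`preds`, `upreds`, `unames`) are computed per dataset;
uniqueness is judged *within* a dataset, since the selection rule that
consumes it ("this group can only live in graph `u` of `D`") is a
within-dataset argument. Remote summaries are built with a single
`SELECT DISTINCT ?g ?p { GRAPH ?g { ?s ?p ?o } }` round trip.

The RDF form uses `lmds:endpointUrl`, `lmds:cube`, `lmds:graph` and
`lmds:cubeProperties` with one cube node per graph. The exact nesting
is this package's own choice (documented here, claimed as nothing
more); JSON is the canonical format and the one the tests pin.

## Source selection

Selection is computed per BGP — the same pattern may legitimately map
to different sources in different UNION/OPTIONAL branches. Within a
BGP, patterns are grouped by exact subject-term equality (constants
group exactly like variables; two distinct variables never merge).
Grouping spans the whole BGP regardless of FILTER placement in the
source text. Hash grouping replaces any sort-based formulation; the
observable partition is identical.

For a group with bound predicates the candidacy / pinning / conflict
rules are as in the README. Two refinements deserve note:

* **Per-pattern intersection.** Once a dataset's graph restriction is
  known, each pattern's selected set is additionally intersected with
  the graphs containing that pattern's predicate. Predicate presence is
  necessary for a pattern to match, so this only removes graphs that
  cannot contribute — it tightens selection without affecting
  completeness, and the pruning-invariance suite exercises exactly this
  claim.
* **Conflict discard is per (group, dataset).** A dataset discarded for
  one subject group may still serve another group of the same BGP.

Unbound-predicate patterns: if the pattern's subject group has bound
predicates, it inherits the group restriction (0 probes) — under
locality, all triples of the group's subjects live in the graphs the
bound patterns allow. Otherwise, if subject or object is bound, one
single-triple-pattern ASK (`ASK { GRAPH ?g { <s> ?p <o> } }`) is sent
per dataset and an affirming dataset contributes all its graphs. A
group consisting solely of unbound-predicate patterns is probed
pattern-by-pattern (whether the original formulation batches such
probes is unspecified; per-pattern probing is the conservative
reading). With nothing bound, probing is uninformative and all graphs
are selected without any ASK. Every probe increments exactly one
client counter, so reported ASK counts are exact.

## Access control

Grants are `(user, graph, right)` triples, default deny; only `read`
gates querying (`write` is modelled but unused). Profile attributes
(activity, location, organisation, position, role) are carried for
description but never evaluated as conditions — attribute-based
decisions, certificates, encryption and auditing belong to the
surrounding platform, not the query engine. Filtering happens after
selection and before execution; it is idempotent, pattern-wise
anti-monotone, and the instrumented clients let tests assert that no
request after filtering ever names an unauthorised graph.

## Execution

Whole subject groups are pushed as single sub-queries per dataset
("exclusive groups"): valid because locality confines s–s joins to one
graph, and cheaper than per-pattern bind joins. Graph restriction uses
`GRAPH ?__g` + inline `VALUES` — one request per dataset regardless of
graph count. The per-dataset graph set for a group is the intersection
over its patterns of their selected graphs: any graph able to produce a
full group match must be selected for every pattern of the group.

Cross-group joins are local hash joins ordered by ascending *observed*
cardinality (ties by query order) — actual sizes, not estimates, which
is acceptable at the scale this engine targets. OPTIONAL blocks are
evaluated as independent BGPs and combined by left join with their
scoped filter expressions; UNION branches are evaluated independently
and concatenated; branch-level FILTERs are applied after joins (a
filter placed inside an OPTIONAL stays scoped to it). Bag semantics
throughout; DISTINCT collapses; ORDER BY sorts with unbound < IRIs <
literals and numeric literals by value; LIMIT/OFFSET apply last.
FILTER and ORDER expressions are evaluated with rdflib's SPARQL
expression evaluator over frozen bindings; a type error in a FILTER
eliminates the row, per SPARQL's effective-boolean-value rules.

One quirk inherited from the parser: rdflib's algebra translation
normalises triple order inside a BGP, so pattern indexes and group
order follow the parsed algebra, not source-text order. Group
*membership* — the only thing selection and execution depend on — is
unaffected.

The supported fragment is plain SELECT with BGPs, FILTER (incl.
REGEX), UNION, OPTIONAL, DISTINCT, ORDER BY, LIMIT/OFFSET. Aggregates,
property paths, subqueries, BIND, VALUES (in the source query), MINUS,
GRAPH and SERVICE raise an unsupported-feature error rather than
returning wrong answers.

## Correctness oracle

`evaluate_merged` merges all triples of all named graphs (optionally
only the authorised ones) into a single local graph and evaluates the
original query with rdflib's SPARQL engine. It shares no code path
with federated execution beyond the parser — selection, rewriting,
sub-queries and local joins are all bypassed — which is what makes the
`execute == evaluate_merged` comparison meaningful. The correctness
condition is multiset equality of rows (order-sensitive only under
ORDER BY).

## Synthetic federations

Random federations draw 2–5 datasets with 1–4 graphs each, a shared
pool of 3–8 binary dimension predicates, and 5–60 observations per
cube; each graph gains a private predicate with probability 0.5. The
bounds keep all selection branches reachable — shared predicates keep
datasets candidates, private predicates make pinning and conflicts
occur — while keeping a 100-federation oracle sweep fast on one CPU.
Observation IRIs are prefixed by their graph IRI, so locality holds by
construction rather than by filtering. Dimension values are plain
integer literals (0/1), measures integer counts; SDMX annotations and
`qb:Slice` structures are not generated because no part of the engine
consults them.

The running example pins the schema and unique-predicate structure of
the four clinical cubes and the full 2³ dimension tables; the
(Diabetes=1, BMI=0, Hypertension=1) row of `:CHUV-S1` carries 26
cases, and the remaining cell values are constructed constants
documented in `fixtures.py`.

Random conjunctive queries anchor a subject group on a real cube (so
most queries have answers) and, with fixed probabilities, mix in a
predicate from another graph (conflict/empty selections), bind an
object to a data value, add an unbound-predicate pattern (restriction
inheritance), or join a second group through `qb:dataSet`.

What passing these suites does *not* show: behaviour on federations
that violate locality (the engine may then miss cross-graph joins — by
design), on SPARQL features outside the fragment, or at the data and
network scales of a production deployment (no timeouts, retries or
streaming are exercised; remote mode is tested against a loopback
endpoint only).

## Numerical and procedural choices

* Problem sizes: the oracle suite runs 100 federations × 5 queries
  (plus one policy check each) in the test suite and 60 × 5 in the
  acceptance script; pruning invariance samples 2 pruned pairs per
  subject group over 25 (tests) / 20 (script) federations. These sizes
  make every selection branch occur many times while keeping a full
  run in tens of seconds.
* All randomness flows through explicit seeds; derived seeds stay
  below 2³¹.
* Sub-query text is deterministic: graphs sorted lexically, variables
  in order of first appearance.
* Remote mode trusts the endpoint to honour the graph scoping carried
  by the rewritten query; in-memory mode enforces it structurally (the
  local store has no default-graph union).
* Timeouts: the HTTP client defaults to 300 s per request,
  configurable per client.

## Known limitations

* Locality is assumed for *all* subjects; there is no per-predicate
  relaxation for resources legitimately described in several graphs.
* s–o joins through `qb:dataSet` are not exploited for pruning, only
  s–s joins.
* No caching of ASK results or summaries across queries; no
  cardinality-based source ranking; no streaming or adaptive joins.
* OPTIONAL-scoped filters referencing only outer variables follow the
  simple left-join reading, which can diverge from SPARQL's
  substitution semantics in contrived cases.
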