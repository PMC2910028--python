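# Methods

## The network model

The engine's target object is a **directed attributed multigraph**.
Nodes are keyed by a non-empty text identifier (compared exactly,
case-sensitive; identifier normalization is deliberately out of scope).
Edges are keyed by the triple `(source, target, type)` — the familiar
`source (type) target` convention of interactive network tools — so two
interactions of different type between the same pair coexist, while
re-mapping the same triple *merges* attributes (new values overwrite
old, with a logged warning) instead of stacking parallel edges. Merge
rather than error is a deliberate choice: it makes every enrichment and
expansion idempotent for a static database, so pipelines can be re-run
safely.

Attribute values are the scalar kinds a typical attribute browser
understands — integer, real, text, boolean — or a non-empty homogeneous
list of one of those. Database values are converted by the declared
column class (`integer`/`real`/`text`/`boolean`), with unknown classes
degrading to their text rendering so conversion is total; SQL `NULL`
never sets an attribute and never clears an existing one.

Internally the graph is a `networkx.MultiDiGraph` with the edge type as
the multiedge key, so referential integrity (no dangling edges; node
removal removes incident edges) is inherited from networkx rather than
re-implemented, and the graph is directly available for analysis.

## Query validation and execution

Validation is **lexical**, not a full SQL parse, which keeps it portable
across database dialects: a quote- and comment-aware scan blanks string
literals (`'…'` with `''` escapes, `"…"`, backticks) and comments
(`--`, `/* */`), then requires the leading keyword to be `SELECT` (or
`WITH`, since common-table-expression queries are SELECTs in practice),
rejects any unquoted `;` followed by more text, and counts `?`
placeholders in the blanked text. Bind values are always passed to the
driver as typed positional parameters — never interpolated — and the
embedded engine opens its database file in read-only mode, so no
operation sequence can modify the source tables.

Result tables carry a declared class per column, inferred from the
returned values (sqlite reports no declared types through its cursor);
all-null or empty columns are `unknown`, which downstream conversion
treats as text.

Query history is a bounded most-recent-first list (default bound 50,
configurable) that skips consecutive duplicates; favorites are a named
map. Both persist in one YAML document next to the profile store.

## The four modes

* **Create.** Each row yields a source node; when a target-id column is
  present and non-null, a target node and an edge whose type comes from
  the edge-type column (default `"interaction"`). Rows with a null
  source id are skipped with a warning. Role maps are validated before
  any row is touched: exactly one source-id column, at most one
  target-id and edge-type, and target/edge attribute roles require a
  target-id column.
* **Node / edge enrichment.** One execution per processed element — the
  semantic contract, observable through the connection handle's query
  counter. A single-row result yields scalar attributes; a multi-row
  result yields one list per column in row order (the alternative,
  last-row-wins, silently discards data); a zero-row result leaves the
  element untouched. Nulls are dropped from lists; an all-null column
  sets nothing. Elements missing a bound field are skipped with a
  warning, not failed.
* **Expansion.** Per seed node, each returned row names a neighbor (the
  role map's single source-id column), which is wired seed→neighbor by
  default; a flag flips the direction. Edge-attribute columns land on
  the new edge, source-attribute columns on the neighbor. Because every
  new edge has the seed as an endpoint by construction, expansion is
  local to the selection.

**Echo columns.** A per-element query usually returns the join key it
was filtered by (e.g. the protein id). Storing it would duplicate the
node identifier as an attribute, so by default a returned column is
treated as a join echo and dropped when its name equals a bound field
reference *or* all its returned values for that element equal one of
the bound values. The value test is needed because the bound reference
is typically `ID` while the echoed column bears the table's own column
name. A flag (`store_echo`) disables the suppression.

**Bind resolution on edges.** `SOURCE`, `TARGET` and `TYPE` resolve to
the edge key; a bare attribute name resolves to the edge attribute and
falls back to the source endpoint's node attribute if the edge lacks
it; `source.<name>` / `target.<name>` address an endpoint explicitly.
Resolving bare names to the source endpoint (not the target) is a
documented tie-break.

Enrichment and expansion require at least one placeholder;
zero-placeholder bulk enrichment is out of scope.

## Serialization

Writers are deterministic — nodes sorted by id, edges by key — so two
writes of one network are byte-identical and pipeline outputs diff
cleanly.

* **SIF** is the tab-delimited dialect, one edge per line, isolated
  nodes as bare lines; multi-target and legacy space-delimited lines
  are accepted on read. SIF carries structure only.
* **GraphML** declares one `<key>` per (attribute name, value kind)
  pair, so an attribute that is a scalar on one element and a list on
  another (a normal enrichment outcome: one matching row here, three
  there) round-trips exactly. Lists are `|`-delimited text (`\|`
  escapes a literal bar, `\\` a backslash) with the element kind and
  delimiter declared in the key's `<desc>`. Unknown types on read
  degrade to text with a warning. The edge type travels in a reserved
  `__edge_type__` key.
* **Attribute tables** are TSV keyed by `ID` (nodes) or
  `SOURCE`/`TYPE`/`TARGET` (edges; the composite `source (type) target`
  key is accepted on read). Headers declare types as `name:kind`. In a
  list-typed column, list cells are prefixed with the delimiter
  (`|a|b`), scalar cells are not, so mixed scalar/list columns
  round-trip exactly. Unmatched keys are skipped and counted.

Two representable-but-lossy corners are documented rather than papered
over: an empty-string text attribute writes as an empty table cell,
which reads back as "absent"; and an attribute whose *base* kind
differs across elements (integer here, text there) degrades to a text
column. GraphML has neither limitation and is the lossless format of
record.

## Synthetic fixtures

The fixture builders stand in for the live molecular databases a real
deployment queries; their values are synthetic by construction and make
no claim of biological realism. Each builder threads a single seeded
generator (no global randomness) and returns the exact inserted rows,
so every assertion about mapped networks is computable from that record
alone — the independent oracle for the whole test suite. Equal specs
yield byte-identical database files.

Defaults for the toy schema: 20 proteins, 40 interactions, confirmed
fraction 0.5 (applied exactly: `round(n·f)` rows are `'Y'`, positions
shuffled), 30 predictions. Self-interactions and duplicate pairs are
drawn at 5% probability each — deliberately, to exercise the mapper's
merge path — and about half the predictions re-use existing interaction
pairs so edge enrichment and expansion have hits. Masses are uniform on
8–250 kDa, isoelectric points on 3.5–11.5, scores on [0, 1]: plausible
ranges, nothing more. The term builder grows, per ontology, a random
rooted tree with bounded branching (every non-root term gets one parent
among nodes with spare capacity), which guarantees exactly one weakly
connected, acyclic component per ontology.

What the fixtures do **not** emulate: real identifier schemes and their
cross-database mismatches, schema drift, server-engine dialects and
latency, large result sets, and malformed data. Passing tests therefore
demonstrate the mapping semantics, not robustness against messy
production databases.

## Problem sizes

The test suite and the acceptance script run the full pipeline (all
four modes plus the three serialization round-trips) over 100 networks
derived from 25 randomized fixture databases of 6–10 proteins and 10–34
interactions, alongside the default 20-protein toy database. These
sizes give every code path multiple hits — merges, self-loops,
multi-row enrichments, empty results — while the whole suite stays in
the seconds range; the mapping semantics being verified are
size-independent.

## Known limitations

* Server engines (MySQL-like, PostgreSQL-like) are representable in
  connection profiles, and profiles round-trip through the store, but
  opening them requires a driver this package does not ship; the
  embedded engine is the reference implementation.
* Read-only enforcement combines lexical validation with the embedded
  engine's read-only open; on a server engine the lexical layer would
  be the only guard, and a user with write credentials should prefer a
  read-only database account.
* Per-element execution is O(elements) round trips by design (it is the
  semantic contract); no batched rewrite is implemented.
* Selections are explicit id lists or files — there is no interactive
  picking, as the engine is headless.
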