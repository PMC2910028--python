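# netquery

**netquery** maps SQL query result sets onto attributed interaction
networks. It is a headless engine for the everyday systems-biology
situation where molecular interactions and their annotations live in a
relational database — an in-house LIMS, a local mirror of a proteome or
pathway resource, a data warehouse — and the analysis needs them as a
graph: nodes, edges, and typed attributes, ready for tools that speak
SIF or GraphML.

Instead of exporting tables to text and importing them by hand (and
re-doing it whenever the database changes), you write a `SELECT`
statement and tell the engine what each result column *means*:

| column role | network meaning |
|---|---|
| `source` / `target` | node identifiers (an edge when both present) |
| `edgetype` | the edge's interaction type (the edge key is `(source, target, type)`) |
| `sourceattr` / `targetattr` / `edgeattr` | a typed attribute of that element |

Four **modes of operation** cover the life cycle of a network:

1. **create** — one query, one new network: each row maps to nodes, an
   edge, and attributes.
2. **node attributes** — a query with `?` bind variables is run once per
   (selected) node, the placeholders instantiated with that node's
   fields; returned columns become node attributes.
3. **edge attributes** — the same, once per edge, with binds drawn from
   edge fields (`SOURCE`, `TARGET`, `TYPE`, attributes) or endpoint
   attributes (`source.x` / `target.x`).
4. **expand** — per seed node, returned rows add neighbor nodes and
   seed→neighbor edges.

Only single `SELECT` (or `WITH … SELECT`) statements are accepted; bind
values are passed as typed parameters, never spliced into the text, and
connections are opened read-only. Named connection profiles persist in a
YAML store so a session can hop between databases.

## Worked example

```python
import netquery as nq

nq.build_toy_db(nq.FixtureSpec(seed=1), "toy.db")   # synthetic test database
profile = nq.ConnectionProfile(name="toy", engine="sqlite", location="toy.db")

query = nq.validate_select(
    "SELECT protn1, protn2, intType, confirmed FROM interactions WHERE confirmed = 'Y'")
roles = nq.ColumnRoleMap.parse(["source", "target", "edgetype", "edgeattr"])

with nq.open_connection(profile) as conn:
    net = nq.create_network(nq.execute(conn, query), roles)
    enrich = nq.validate_select("SELECT protein, mass, pI FROM features WHERE protein = ?")
    net = nq.load_node_attributes(conn, enrich, nq.BindSpec(("ID",)), net)

print(net)                        # <Network nodes=18 edges=20>
print(net.node_attrs("P1"))       # {'mass': 33.27, 'pI': 8.83}
```

The 20 confirmed interaction rows collapse onto 18 proteins and 20
distinct `(source, target, type)` edges (duplicate triples merge); the
enrichment query then runs once per node — 18 executions — and attaches
each protein's mass (kDa) and isoelectric point from the `features`
table as typed node attributes.

The `examples/` directory has one short script per capability (the four
modes, a bipartite protein–domain join, molecule–reaction enrichment,
ontology term hierarchies); each prints the numbers it computes and what
they mean.

## Command line

```sh
netquery --config profiles.yaml profiles add toy --location toy.db
netquery --config profiles.yaml preview toy "SELECT * FROM features" --limit 5
netquery --config profiles.yaml run manifest.yaml --summary run.json
netquery fixtures toy toy.db --seed 1 --ground-truth gt.json
```

A manifest bundles profile, mode, query, roles, binds, selection and
outputs into one YAML file, so a network build is reproducible and
versionable. Exit codes distinguish usage (2), connection (3), query
(4), mapping (5) and I/O (6) failures.

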