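"""Ontology term hierarchies as a network.

A single query over the term-relationship table maps child→parent links
into a directed network; terms from different ontologies form separate
components, and each component is a rooted, acyclic hierarchy.
"""

import tempfile
from pathlib import Path

import networkx as nx

import netquery as nq

tmp = Path(tempfile.mkdtemp())
spec = nq.FixtureSpec(seed=2, n_terms=15, n_ontologies=4, branching=3)
nq.build_term_db(spec, tmp / "terms.db")
profile = nq.ConnectionProfile(name="terms", engine="sqlite", location=str(tmp / "terms.db"))

with nq.open_connection(profile) as conn:
    net = nq.create_network(
        nq.execute(conn, nq.validate_select(
            "SELECT child, parent, relType FROM termRelationships")),
        nq.ColumnRoleMap.parse(["source", "target", "edgetype"]))

g = net.graph
comps = list(nx.weakly_connected_components(g))
print(f"{net.node_count} terms, {net.edge_count} is_a links, {len(comps)} components")
for comp in sorted(comps, key=min):
    root = [n for n in comp if g.out_degree(n) == 0][0]
    print(f"  component rooted at {root}: {len(comp)} terms, "
          f"acyclic={nx.is_directed_acyclic_graph(g.subgraph(comp))}")
# One component per ontology: terms only relate to terms of their own
# vocabulary, and parent links never loop.
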