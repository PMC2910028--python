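"""Molecule-reaction network plus description enrichment.

One query creates the bipartite molecule/reaction network (edge type
'substrate' or 'product'); a second, parameterized query then loads a
description for every node in a single pass -- no table export/import.
"""

import tempfile
from pathlib import Path

import netquery as nq

tmp = Path(tempfile.mkdtemp())
nq.build_reaction_db(nq.FixtureSpec(seed=5), tmp / "rx.db")
profile = nq.ConnectionProfile(name="rx", engine="sqlite", location=str(tmp / "rx.db"))

with nq.open_connection(profile) as conn:
    net = nq.create_network(
        nq.execute(conn, nq.validate_select(
            "SELECT molecule, reaction, role FROM participation")),
        nq.ColumnRoleMap.parse(["source", "target", "edgetype"]))
    print(f"network: {net.node_count} nodes, {net.edge_count} participation edges")

    describe = nq.validate_select(
        "SELECT id, kind, description FROM descriptions WHERE id = ?")
    net = nq.load_node_attributes(conn, describe, nq.BindSpec(("ID",)), net)

n = sorted(net.node_ids())[0]
print(f"node {n}: {net.node_attrs(n)}")
with_desc = sum(1 for n in net.node_ids() if "description" in net.node_attrs(n))
print(f"{with_desc}/{net.node_count} nodes described")
# 'kind' tells molecules from reactions; the description text comes from
# the database row matched by each node's own identifier.
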