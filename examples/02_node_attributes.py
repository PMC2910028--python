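"""Load node attributes with a per-node bind variable (mode 2).

The features query carries one '?' placeholder; it is instantiated with
each node's identifier and run once per node, attaching the returned
mass and isoelectric point as typed node attributes.
"""

import tempfile
from pathlib import Path

import netquery as nq

tmp = Path(tempfile.mkdtemp())
nq.build_toy_db(nq.FixtureSpec(seed=1), tmp / "toy.db")
profile = nq.ConnectionProfile(name="toy", engine="sqlite", location=str(tmp / "toy.db"))

with nq.open_connection(profile) as conn:
    net = nq.create_network(
        nq.execute(conn, nq.validate_select(
            "SELECT protn1, protn2, intType, confirmed FROM interactions WHERE confirmed = 'Y'")),
        nq.ColumnRoleMap.parse(["source", "target", "edgetype", "edgeattr"]))

    enrich = nq.validate_select("SELECT protein, mass, pI FROM features WHERE protein = ?")
    before = conn.query_count
    net = nq.load_node_attributes(conn, enrich, nq.BindSpec(("ID",)), net)
    print(f"queries issued: {conn.query_count - before} (one per node, {net.node_count} nodes)")

node = sorted(net.node_ids())[0]
print(f"node {node}: {net.node_attrs(node)}")
# mass (kDa) and pI come straight from the features table; the echoed
# 'protein' column is recognized as the join key and not stored.
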