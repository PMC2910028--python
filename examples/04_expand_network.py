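"""Expand a network around seed nodes (mode 4).

For every seed node, the query returns predicted partners; each row adds
a neighbor node and a seed→neighbor edge typed by the predicted
interaction type and scored by the prediction.
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
    seeds = set(net.node_ids())
    before = (net.node_count, net.edge_count)

    expand = nq.validate_select(
        "SELECT protn2, intType, score FROM predictedInteractions WHERE protn1 = ?")
    net = nq.expand_network(conn, expand, nq.BindSpec(("ID",)),
                            nq.ColumnRoleMap.parse(["source", "edgetype", "edgeattr"]), net)

print(f"before expansion: {before[0]} nodes, {before[1]} edges")
print(f"after expansion:  {net.node_count} nodes, {net.edge_count} edges")
new_edges = [k for k in net.edge_keys() if k[0] in seeds and "score" in net.edge_attrs(k)]
print(f"every new edge originates at a seed node: "
      f"{all(k[0] in seeds for k in new_edges)}")
# Re-running the same expansion adds nothing: duplicate edge keys merge,
# so the operation is idempotent for a static database.
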