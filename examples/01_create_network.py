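"""Create a network from a single SELECT statement (mode 1).

Builds a toy protein-interaction database, queries the confirmed
interactions, and maps each result row to a pair of nodes joined by a
typed edge carrying the 'confirmed' flag as an attribute.
"""

import tempfile
from pathlib import Path

import netquery as nq

tmp = Path(tempfile.mkdtemp())
nq.build_toy_db(nq.FixtureSpec(seed=1), tmp / "toy.db")

profile = nq.ConnectionProfile(name="toy", engine="sqlite", location=str(tmp / "toy.db"))
query = nq.validate_select(
    "SELECT protn1, protn2, intType, confirmed FROM interactions WHERE confirmed = 'Y'")
roles = nq.ColumnRoleMap.parse(["source", "target", "edgetype", "edgeattr"])

with nq.open_connection(profile) as conn:
    result = nq.execute(conn, query)
    net = nq.create_network(result, roles)

print(f"result rows: {len(result)}")
print(f"network: {net.node_count} nodes, {net.edge_count} edges")
some_edge = sorted(net.edge_keys())[0]
print(f"example edge {some_edge}: attrs {net.edge_attrs(some_edge)}")

# The row count exceeds the edge count when the same (protn1, protn2,
# intType) triple appears twice: duplicate keys merge rather than stack.
nq.write_sif(net, tmp / "confirmed.sif")
print(f"wrote {tmp / 'confirmed.sif'}")
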