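"""Load edge attributes with two bind variables (mode 3).

The prediction query has two '?' placeholders, instantiated with the
source and target identifiers of each edge; edges with a matching
predicted interaction gain its type and score as attributes.
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

    predict = nq.validate_select(
        "SELECT protn1, protn2, intType, score FROM predictedInteractions "
        "WHERE protn1 = ? AND protn2 = ?")
    net = nq.load_edge_attributes(conn, predict, nq.BindSpec(("SOURCE", "TARGET")), net)

scored = [k for k in net.edge_keys() if "score" in net.edge_attrs(k)]
print(f"{len(scored)} of {net.edge_count} edges have a predicted score")
if scored:
    k = sorted(scored)[0]
    print(f"edge {k}: {net.edge_attrs(k)}")
# An edge matched by several prediction rows carries its scores as a
# list, in row order; unmatched edges are left untouched.
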