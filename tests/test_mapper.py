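import pytest

import netquery as nq
from netquery.errors import MappingError

from conftest import MODE2_QUERY, MODE3_QUERY, MODE4_QUERY


def confirmed_truth(gt):
    """Independent oracle: endpoint union and distinct edge triples over
    confirmed interaction rows, straight from the inserted rows."""
    rows = [r for r in gt.rows("interactions") if r[3] == "Y"]
    nodes = {r[0] for r in rows} | {r[1] for r in rows}
    triples = {(r[0], r[1], r[2]) for r in rows}
    return nodes, triples


class TestColumnRoleMap:
    def test_create_requires_exactly_one_source_id(self):
        roles = nq.ColumnRoleMap.parse(["edgeattr", "target"])
        with pytest.raises(MappingError, match="source"):
            roles.validate_create(2)

    def test_role_count_must_match_columns(self):
        roles = nq.ColumnRoleMap.parse(["source", "target"])
        with pytest.raises(MappingError):
            roles.validate_create(3)

    def test_edge_roles_require_target(self):
        roles = nq.ColumnRoleMap.parse(["source", "edgeattr"])
        with pytest.raises(MappingError, match="target"):
            roles.validate_create(2)

    def test_attribute_role_can_rename(self):
        roles = nq.ColumnRoleMap.parse(["source", "target", "edgeattr:weight"])
        assert roles.roles[2].attr_name == "weight"

    def test_unknown_role_rejected(self):
        with pytest.raises(MappingError):
            nq.ColumnRoleMap.parse(["sorce"])


class TestCreateNetwork:
    def test_confirmed_interactions_network_matches_ground_truth(self, toy, toy_network):
        _, _, gt = toy
        nodes, triples = confirmed_truth(gt)
        assert set(toy_network.node_ids()) == nodes
        assert set(toy_network.edge_keys()) == triples

    def test_every_edge_carries_confirmed_flag_and_type(self, toy_network):
        for s, t, ty in toy_network.edge_keys():
            attrs = toy_network.edge_attrs((s, t, ty))
            assert attrs["confirmed"] == "Y"
            assert ty in ("pp", "pd", "genetic")

    def test_empty_result_gives_empty_network(self):
        res = nq.ResultTable(["a", "b"], ["text", "text"], [])
        roles = nq.ColumnRoleMap.parse(["source", "target"])
        net = nq.create_network(res, roles)
        assert net.node_count == 0 and net.edge_count == 0

    def test_null_source_id_skips_row(self):
        res = nq.ResultTable(["a", "b"], ["text", "text"], [(None, "B"), ("A", "B")])
        net = nq.create_network(res, nq.ColumnRoleMap.parse(["source", "target"]))
        assert set(net.node_ids()) == {"A", "B"}
        assert net.edge_count == 1

    def test_null_target_creates_source_only(self):
        res = nq.ResultTable(["a", "b"], ["text", "text"], [("A", None)])
        net = nq.create_network(res, nq.ColumnRoleMap.parse(["source", "target"]))
        assert set(net.node_ids()) == {"A"}
        assert net.edge_count == 0

    def test_default_edge_type_is_interaction(self):
        res = nq.ResultTable(["a", "b"], ["text", "text"], [("A", "B")])
        net = nq.create_network(res, nq.ColumnRoleMap.parse(["source", "target"]))
        assert list(net.edge_keys()) == [("A", "B", "interaction")]

    def test_null_attribute_sets_nothing(self):
        res = nq.ResultTable(["a", "b", "w"], ["text", "text", "real"],
                             [("A", "B", None)])
        net = nq.create_network(res, nq.ColumnRoleMap.parse(["source", "target", "edgeattr"]))
        assert "w" not in net.edge_attrs(("A", "B", "interaction"))


class TestLoadNodeAttributes:
    def test_every_node_gains_mass_and_pi(self, toy, toy_conn, toy_network):
        _, _, gt = toy
        features = {r[0]: (r[1], r[2]) for r in gt.rows("features")}
        q = nq.validate_select(MODE2_QUERY)
        net = nq.load_node_attributes(toy_conn, q, nq.BindSpec(("ID",)), toy_network)
        for n in net.node_ids():
            attrs = net.node_attrs(n)
            assert (attrs["mass"], attrs["pI"]) == features[n]

    def test_echoed_id_column_not_stored(self, toy_conn, toy_network):
        q = nq.validate_select(MODE2_QUERY)
        net = nq.load_node_attributes(toy_conn, q, nq.BindSpec(("ID",)), toy_network)
        assert all("protein" not in net.node_attrs(n) for n in net.node_ids())

    def test_store_echo_flag_keeps_echo_column(self, toy_conn, toy_network):
        q = nq.validate_select(MODE2_QUERY)
        net = nq.load_node_attributes(toy_conn, q, nq.BindSpec(("ID",)), toy_network,
                                      store_echo=True)
        some = next(iter(net.node_ids()))
        assert net.node_attrs(some)["protein"] == some

    def test_one_query_per_processed_node(self, toy_conn, toy_network):
        q = nq.validate_select(MODE2_QUERY)
        before = toy_conn.query_count
        nq.load_node_attributes(toy_conn, q, nq.BindSpec(("ID",)), toy_network)
        assert toy_conn.query_count - before == toy_network.node_count

    def test_selection_restricts_processing(self, toy, toy_conn, toy_network):
        _, _, gt = toy
        target = sorted(toy_network.node_ids())[0]
        q = nq.validate_select(MODE2_QUERY)
        before = toy_conn.query_count
        net = nq.load_node_attributes(toy_conn, q, nq.BindSpec(("ID",)),
                                      toy_network, nq.Selection.nodes([target]))
        assert toy_conn.query_count - before == 1
        others = [n for n in net.node_ids() if n != target]
        assert all("mass" not in net.node_attrs(n) for n in others)

    def test_zero_row_result_leaves_node_unchanged(self, toy_conn):
        net = nq.Network()
        net.add_node("GHOST")
        q = nq.validate_select(MODE2_QUERY)
        nq.load_node_attributes(toy_conn, q, nq.BindSpec(("ID",)), net)
        assert net.node_attrs("GHOST") == {}

    def test_multi_row_result_becomes_list_attributes(self, toy_conn):
        net = nq.Network()
        net.add_node("P1")
        q = nq.validate_select(
            "SELECT protn2, intType FROM interactions WHERE protn1 = ? ORDER BY rowid")
        nq.load_node_attributes(toy_conn, q, nq.BindSpec(("ID",)), net)
        attrs = net.node_attrs("P1")
        if "intType" in attrs:  # P1 appears more than once as protn1 in this fixture
            assert isinstance(attrs["intType"], (str, list))

    def test_edge_field_reference_rejected(self, toy_conn, toy_network):
        q = nq.validate_select(MODE2_QUERY)
        with pytest.raises(MappingError):
            nq.load_node_attributes(toy_conn, q, nq.BindSpec(("SOURCE",)), toy_network)

    def test_zero_placeholder_query_rejected(self, toy_conn, toy_network):
        q = nq.validate_select("SELECT protein, mass FROM features")
        with pytest.raises(MappingError):
            nq.load_node_attributes(toy_conn, q, nq.BindSpec(()), toy_network)

    def test_node_missing_bound_attribute_is_skipped(self, toy_conn):
        net = nq.Network()
        net.add_node("A", {"alias": "P1"})
        net.add_node("B")  # lacks the alias attribute
        q = nq.validate_select(MODE2_QUERY)
        before = toy_conn.query_count
        nq.load_node_attributes(toy_conn, q, nq.BindSpec(("alias",)), net)
        assert toy_conn.query_count - before == 1  # only A processed

    def test_mode2_equals_in_memory_join(self, toy, toy_conn, toy_network):
        """Looped per-node enrichment == joining the features table against
        the node id set in memory."""
        _, _, gt = toy
        q = nq.validate_select(MODE2_QUERY)
        net = nq.load_node_attributes(toy_conn, q, nq.BindSpec(("ID",)), toy_network)
        join = {r[0]: {"mass": r[1], "pI": r[2]}
                for r in gt.rows("features") if net.has_node(r[0])}
        looped = {n: {k: v for k, v in net.node_attrs(n).items() if k in ("mass", "pI")}
                  for n in net.node_ids()}
        assert looped == join


class TestLoadEdgeAttributes:
    def test_predicted_scores_land_on_existing_edges(self, toy, toy_conn, toy_network):
        _, _, gt = toy
        q = nq.validate_select(MODE3_QUERY)
        net = nq.load_edge_attributes(toy_conn, q, nq.BindSpec(("SOURCE", "TARGET")),
                                      toy_network)
        predicted_pairs = {(r[0], r[1]) for r in gt.rows("predictedInteractions")}
        scored = {(s, t) for s, t, ty in net.edge_keys()
                  if "score" in net.edge_attrs((s, t, ty))}
        assert scored  # the fixture guarantees overlap
        assert scored <= predicted_pairs

    def test_score_value_matches_inserted_row(self, toy, toy_conn, toy_network):
        _, _, gt = toy
        q = nq.validate_select(MODE3_QUERY)
        net = nq.load_edge_attributes(toy_conn, q, nq.BindSpec(("SOURCE", "TARGET")),
                                      toy_network)
        by_pair = {}
        for a, b, ty, score in gt.rows("predictedInteractions"):
            by_pair.setdefault((a, b), []).append(score)
        for key in net.edge_keys():
            attrs = net.edge_attrs(key)
            if "score" in attrs:
                expect = by_pair[(key[0], key[1])]
                got = attrs["score"] if isinstance(attrs["score"], list) else [attrs["score"]]
                assert got == expect

    def test_one_query_per_edge(self, toy_conn, toy_network):
        q = nq.validate_select(MODE3_QUERY)
        before = toy_conn.query_count
        nq.load_edge_attributes(toy_conn, q, nq.BindSpec(("SOURCE", "TARGET")), toy_network)
        assert toy_conn.query_count - before == toy_network.edge_count

    def test_edgeless_network_issues_no_queries(self, toy_conn):
        net = nq.Network()
        net.add_node("A")
        q = nq.validate_select(MODE3_QUERY)
        before = toy_conn.query_count
        out = nq.load_edge_attributes(toy_conn, q, nq.BindSpec(("SOURCE", "TARGET")), net)
        assert toy_conn.query_count == before
        assert out == net

    def test_endpoint_attribute_binds_resolve_source_then_prefix(self, toy_conn):
        net = nq.Network()
        net.add_node("A", {"alias": "P1"})
        net.add_node("B", {"alias": "P2"})
        key = net.add_edge("A", "B", "pp")
        q = nq.validate_select("SELECT protein, mass FROM features WHERE protein = ?")
        # bare attribute name missing on the edge falls back to the source node
        nq.load_edge_attributes(toy_conn, q, nq.BindSpec(("alias",)), net,
                                nq.Selection.edges([key]), store_echo=True)
        assert net.edge_attrs(key)["protein"] == "P1"
        nq.load_edge_attributes(toy_conn, q, nq.BindSpec(("target.alias",)), net,
                                nq.Selection.edges([key]), store_echo=True)
        assert net.edge_attrs(key)["protein"] == "P2"


class TestExpandNetwork:
    ROLES = ["source", "edgetype", "edgeattr"]

    def test_expansion_adds_predicted_neighbors(self, toy, toy_conn, toy_network):
        _, _, gt = toy
        q = nq.validate_select(MODE4_QUERY)
        before_edges = set(toy_network.edge_keys())
        seeds = set(toy_network.node_ids())
        net = nq.expand_network(toy_conn, q, nq.BindSpec(("ID",)),
                                nq.ColumnRoleMap.parse(self.ROLES), toy_network)
        new_edges = set(net.edge_keys()) - before_edges
        assert new_edges
        # locality: every new edge is incident to a seed node
        assert all(s in seeds or t in seeds for s, t, _ in new_edges)
        # and originates from a seed (seed is the source by default)
        assert all(s in seeds for s, _, _ in new_edges)

    def test_expansion_is_idempotent(self, toy_conn, toy_network):
        q = nq.validate_select(MODE4_QUERY)
        roles = nq.ColumnRoleMap.parse(self.ROLES)
        seeds = nq.Selection.nodes(sorted(toy_network.node_ids()))
        once = nq.expand_network(toy_conn, q, nq.BindSpec(("ID",)), roles,
                                 toy_network, seeds)
        again = nq.expand_network(toy_conn, q, nq.BindSpec(("ID",)), roles,
                                  once.copy(), seeds)
        assert again == once

    def test_seed_without_predictions_changes_nothing(self, toy_conn):
        net = nq.Network()
        net.add_node("GHOST")
        q = nq.validate_select(MODE4_QUERY)
        out = nq.expand_network(toy_conn, q, nq.BindSpec(("ID",)),
                                nq.ColumnRoleMap.parse(self.ROLES), net)
        assert out.node_count == 1 and out.edge_count == 0

    def test_direction_flip_makes_seed_the_target(self, toy, toy_conn):
        _, _, gt = toy
        seed = gt.rows("predictedInteractions")[0][0]
        net = nq.Network()
        net.add_node(seed)
        q = nq.validate_select(MODE4_QUERY)
        out = nq.expand_network(toy_conn, q, nq.BindSpec(("ID",)),
                                nq.ColumnRoleMap.parse(self.ROLES), net,
                                seed_is_source=False)
        assert all(t == seed for _, t, _ in out.edge_keys())

    def test_target_roles_rejected_in_expand_mode(self, toy_conn, toy_network):
        q = nq.validate_select(MODE4_QUERY)
        roles = nq.ColumnRoleMap.parse(["source", "target", "edgeattr"])
        with pytest.raises(MappingError):
            nq.expand_network(toy_conn, q, nq.BindSpec(("ID",)), roles, toy_network)


def test_mode1_plus_mode2_equals_single_join_query(toy, toy_conn):
    """Cross-mode consistency: creating then enriching equals a one-shot
    two-table join mapped with node-attribute roles."""
    q1 = nq.validate_select(
        "SELECT protn1, protn2, intType, confirmed FROM interactions WHERE confirmed = 'Y'")
    roles1 = nq.ColumnRoleMap.parse(["source", "target", "edgetype", "edgeattr"])
    net = nq.create_network(nq.execute(toy_conn, q1), roles1)
    net = nq.load_node_attributes(
        toy_conn, nq.validate_select(MODE2_QUERY), nq.BindSpec(("ID",)), net)

    joined = nq.validate_select(
        "SELECT i.protn1, i.protn2, i.intType, i.confirmed, f1.mass, f1.pI, f2.mass, f2.pI "
        "FROM interactions i "
        "JOIN features f1 ON f1.protein = i.protn1 "
        "JOIN features f2 ON f2.protein = i.protn2 "
        "WHERE i.confirmed = 'Y'")
    roles2 = nq.ColumnRoleMap.parse([
        "source", "target", "edgetype", "edgeattr",
        "sourceattr:mass", "sourceattr:pI", "targetattr:mass", "targetattr:pI"])
    onepass = nq.create_network(nq.execute(toy_conn, joined), roles2)
    assert onepass == net
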