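import hashlib
import sqlite3

import pytest

import netquery as nq

#: The four canonical example queries, one per mapping mode.
MODE1_QUERY = "SELECT protn1, protn2, intType, confirmed FROM interactions WHERE confirmed = 'Y'"
MODE2_QUERY = "SELECT protein, mass, pI FROM features WHERE protein = ?"
MODE3_QUERY = "SELECT protn1, protn2, intType, score FROM predictedInteractions WHERE protn1 = ? AND protn2 = ?"
MODE4_QUERY = "SELECT protn2, intType, score FROM predictedInteractions WHERE protn1 = ?"


@pytest.fixture(scope="session")
def toy(tmp_path_factory):
    """Toy protein-interaction fixture: (spec, db path, ground truth)."""
    d = tmp_path_factory.mktemp("toy")
    spec = nq.FixtureSpec(seed=1, n_proteins=20, n_interactions=40,
                          confirmed_fraction=0.5, n_predictions=30)
    gt = nq.build_toy_db(spec, d / "toy.db")
    return spec, d / "toy.db", gt


@pytest.fixture
def toy_conn(toy):
    _, path, _ = toy
    conn = nq.open_connection(
        nq.ConnectionProfile(name="toy", engine="sqlite", location=str(path))
    )
    yield conn
    conn.close()


@pytest.fixture
def toy_network(toy_conn):
    """Mode-1 network of confirmed interactions from the toy fixture."""
    query = nq.validate_select(MODE1_QUERY)
    roles = nq.ColumnRoleMap.parse(["source", "target", "edgetype", "edgeattr"])
    return nq.create_network(nq.execute(toy_conn, query), roles)


def table_checksums(db_path) -> dict[str, str]:
    """SHA-256 of every table's full content, for read-only guarantees."""
    con = sqlite3.connect(db_path)
    sums = {}
    try:
        tables = [r[0] for r in con.execute(
            "SELECT name FROM sqlite_master WHERE type='table' ORDER BY name")]
        for t in tables:
            h = hashlib.sha256()
            for row in con.execute(f"SELECT * FROM {t}"):
                h.update(repr(row).encode())
            sums[t] = h.hexdigest()
    finally:
        con.close()
    return sums
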