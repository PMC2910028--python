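"""Deterministic synthetic relational databases for tests and tutorials.

Real deployments point the engine at whatever molecular database a lab
runs; these builders stand in for them.  Each builder creates an embedded
single-file database from a seeded :class:`FixtureSpec` and returns a
:class:`GroundTruth` -- the exact record of every inserted row -- so any
assertion about mapped networks can be computed without re-querying the
database.  Identical specs produce identical content.

Four schemas are provided:

* ``build_toy_db`` -- a protein interaction toy schema with tables
  ``interactions`` (pairs with a type and a confirmed flag), ``features``
  (mass and isoelectric point per protein) and ``predictedInteractions``
  (scored predicted pairs).  All four canonical example queries (one per
  mapping mode) run against it.
* ``build_protein_domain_db`` -- proteins, domains and a membership table
  whose three-table join yields a bipartite protein-domain network.
* ``build_reaction_db`` -- molecules, reactions, a participation table,
  and a descriptions table for per-node enrichment.
* ``build_term_db`` -- controlled-vocabulary terms arranged in several
  disjoint rooted hierarchies (one per ontology) linked by parent
  relationships.
"""

from __future__ import annotations

import json
import random
import sqlite3
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

from .errors import UsageError

INT_TYPES = ("pp", "pd", "genetic")

#: Probability that an interaction is a self-interaction, and that a drawn
#: pair duplicates an earlier one (both exercise the mapper's merge path).
SELF_LOOP_PROB = 0.05
DUPLICATE_PROB = 0.05


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters controlling fixture content; equal specs give equal databases."""

    seed: int = 1
    n_proteins: int = 20
    n_interactions: int = 40
    confirmed_fraction: float = 0.5
    n_predictions: int = 30
    # case builders
    n_domains: int = 8
    memberships_per_protein: int = 2
    n_molecules: int = 15
    n_reactions: int = 6
    n_terms: int = 12
    n_ontologies: int = 3
    branching: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.confirmed_fraction <= 1.0:
            raise ValueError("confirmed_fraction must lie in [0, 1]")
        if min(self.n_proteins, self.n_terms) < 2:
            raise ValueError("fixtures need at least two proteins and two terms")


@dataclass
class GroundTruth:
    """Exact copy of every inserted row, per table, in insertion order."""

    columns: dict[str, list[str]] = field(default_factory=dict)
    tables: dict[str, list[tuple]] = field(default_factory=dict)

    def rows(self, table: str) -> list[tuple]:
        return self.tables[table]

    def to_json(self, path: str | Path) -> None:
        doc = {
            name: {"columns": self.columns[name], "rows": [list(r) for r in rows]}
            for name, rows in self.tables.items()
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GroundTruth):
            return NotImplemented
        return self.columns == other.columns and self.tables == other.tables


def _create_db(path: str | Path, overwrite: bool) -> sqlite3.Connection:
    p = Path(path)
    if p.exists():
        if not overwrite:
            raise UsageError(f"refusing to overwrite existing database {p} (pass overwrite=True)")
        p.unlink()
    return sqlite3.connect(p)


def _insert(con: sqlite3.Connection, gt: GroundTruth, table: str,
            columns: list[str], rows: list[tuple]) -> None:
    marks = ",".join("?" * len(columns))
    con.executemany(f"INSERT INTO {table} ({','.join(columns)}) VALUES ({marks})", rows)
    gt.columns[table] = columns
    gt.tables[table] = rows


def build_toy_db(spec: FixtureSpec, path: str | Path, overwrite: bool = False) -> GroundTruth:
    """Protein-interaction toy schema.

    ``confirmed`` is 'Y' for exactly ``round(n_interactions *
    confirmed_fraction)`` rows (positions shuffled by the seed), so counts
    derived from the spec are exact, not expectations.  Predictions
    overlap existing interaction pairs for about half their rows so the
    edge-enrichment and expansion modes have hits.
    """
    rng = random.Random(spec.seed)
    gt = GroundTruth()
    proteins = [f"P{i}" for i in range(1, spec.n_proteins + 1)]

    def draw_pair(prev: list[tuple[str, str]]) -> tuple[str, str]:
        if prev and rng.random() < DUPLICATE_PROB:
            return rng.choice(prev)
        a = rng.choice(proteins)
        b = a if rng.random() < SELF_LOOP_PROB else rng.choice(proteins)
        return a, b

    pairs: list[tuple[str, str]] = []
    for _ in range(spec.n_interactions):
        pairs.append(draw_pair(pairs))
    n_confirmed = round(spec.n_interactions * spec.confirmed_fraction)
    flags = ["Y"] * n_confirmed + ["N"] * (spec.n_interactions - n_confirmed)
    rng.shuffle(flags)
    interactions = [
        (a, b, rng.choice(INT_TYPES), flag) for (a, b), flag in zip(pairs, flags)
    ]

    features = [
        (p, round(rng.uniform(8.0, 250.0), 2), round(rng.uniform(3.5, 11.5), 2))
        for p in proteins
    ]

    predictions: list[tuple] = []
    for i in range(spec.n_predictions):
        if interactions and i % 2 == 0:
            a, b, _, _ = rng.choice(interactions)
        else:
            a, b = draw_pair([])
        predictions.append((a, b, rng.choice(INT_TYPES), round(rng.uniform(0.0, 1.0), 3)))

    con = _create_db(path, overwrite)
    with con:
        con.execute("CREATE TABLE interactions (protn1 TEXT, protn2 TEXT, intType TEXT, confirmed TEXT)")
        con.execute("CREATE TABLE features (protein TEXT, mass REAL, pI REAL)")
        con.execute("CREATE TABLE predictedInteractions (protn1 TEXT, protn2 TEXT, intType TEXT, score REAL)")
        _insert(con, gt, "interactions", ["protn1", "protn2", "intType", "confirmed"], interactions)
        _insert(con, gt, "features", ["protein", "mass", "pI"], features)
        _insert(con, gt, "predictedInteractions", ["protn1", "protn2", "intType", "score"], predictions)
    con.close()
    return gt


def build_protein_domain_db(spec: FixtureSpec, path: str | Path, overwrite: bool = False) -> GroundTruth:
    """Bipartite protein-domain schema: proteins, domains, membership.

    A single three-table join yields the protein-domain edge list with the
    node kind ('protein' / 'domain') available as attributes.
    """
    rng = random.Random(spec.seed + 101)
    gt = GroundTruth()
    proteins = [(f"P{i}", f"protein {i}", "protein") for i in range(1, spec.n_proteins + 1)]
    domains = [(f"D{j}", f"domain {j}", "domain") for j in range(1, spec.n_domains + 1)]
    membership = []
    for pid, _, _ in proteins:
        for did in rng.sample([d[0] for d in domains],
                              min(spec.memberships_per_protein, spec.n_domains)):
            membership.append((pid, did))

    con = _create_db(path, overwrite)
    with con:
        con.execute("CREATE TABLE proteins (id TEXT, name TEXT, kind TEXT)")
        con.execute("CREATE TABLE domains (id TEXT, name TEXT, kind TEXT)")
        con.execute("CREATE TABLE membership (protein TEXT, domain TEXT)")
        _insert(con, gt, "proteins", ["id", "name", "kind"], proteins)
        _insert(con, gt, "domains", ["id", "name", "kind"], domains)
        _insert(con, gt, "membership", ["protein", "domain"], membership)
    con.close()
    return gt


def build_reaction_db(spec: FixtureSpec, path: str | Path, overwrite: bool = False) -> GroundTruth:
    """Molecule/reaction schema with participation and descriptions.

    The network query joins participation; a per-node enrichment query
    against ``descriptions`` loads a description for every node, whether
    it is a molecule or a reaction.
    """
    rng = random.Random(spec.seed + 202)
    gt = GroundTruth()
    molecules = [(f"M{i}", f"molecule {i}") for i in range(1, spec.n_molecules + 1)]
    reactions = [(f"R{j}", f"reaction {j}") for j in range(1, spec.n_reactions + 1)]
    participation = []
    for rid, _ in reactions:
        pool = [m[0] for m in molecules]
        ins = rng.sample(pool, min(2, len(pool)))
        outs = rng.sample([m for m in pool if m not in ins], min(2, len(pool) - len(ins)))
        for mid in ins:
            participation.append((mid, rid, "substrate"))
        for mid in outs:
            participation.append((mid, rid, "product"))
    descriptions = (
        [(mid, "molecule", f"synthetic description of {name}") for mid, name in molecules]
        + [(rid, "reaction", f"synthetic description of {name}") for rid, name in reactions]
    )

    con = _create_db(path, overwrite)
    with con:
        con.execute("CREATE TABLE molecules (id TEXT, name TEXT)")
        con.execute("CREATE TABLE reactions (id TEXT, name TEXT)")
        con.execute("CREATE TABLE participation (molecule TEXT, reaction TEXT, role TEXT)")
        con.execute("CREATE TABLE descriptions (id TEXT, kind TEXT, description TEXT)")
        _insert(con, gt, "molecules", ["id", "name"], molecules)
        _insert(con, gt, "reactions", ["id", "name"], reactions)
        _insert(con, gt, "participation", ["molecule", "reaction", "role"], participation)
        _insert(con, gt, "descriptions", ["id", "kind", "description"], descriptions)
    con.close()
    return gt


def build_term_db(spec: FixtureSpec, path: str | Path, overwrite: bool = False) -> GroundTruth:
    """Term hierarchies: ``n_ontologies`` disjoint rooted trees.

    Every non-root term has exactly one parent within its ontology, each
    parent takes at most ``branching`` children, so the mapped network has
    exactly ``n_ontologies`` weakly connected components, each acyclic
    under the child→parent direction.
    """
    rng = random.Random(spec.seed + 303)
    gt = GroundTruth()
    terms: list[tuple] = []
    rels: list[tuple] = []
    for o in range(1, spec.n_ontologies + 1):
        ids = [f"T{o}_{k}" for k in range(1, spec.n_terms + 1)]
        for tid in ids:
            terms.append((tid, f"term {tid}", f"ontology{o}"))
        children_count = {ids[0]: 0}
        for tid in ids[1:]:
            open_parents = [p for p, c in children_count.items() if c < spec.branching]
            parent = rng.choice(open_parents)
            children_count[parent] += 1
            children_count[tid] = 0
            rels.append((tid, parent, "is_a"))

    con = _create_db(path, overwrite)
    with con:
        con.execute("CREATE TABLE terms (term_id TEXT, name TEXT, ontology TEXT)")
        con.execute("CREATE TABLE termRelationships (child TEXT, parent TEXT, relType TEXT)")
        _insert(con, gt, "terms", ["term_id", "name", "ontology"], terms)
        _insert(con, gt, "termRelationships", ["child", "parent", "relType"], rels)
    con.close()
    return gt
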