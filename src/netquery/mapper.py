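"""The four modes that map query result tables onto a network.

Mode 1 (create) turns one result table into a new network, guided by a
:class:`ColumnRoleMap` that says for every column whether it is the source
node id, the target node id, an attribute of the source/target/edge, or
the edge type.  Modes 2 and 3 (node/edge enrichment) run a parameterized
query once per selected element, instantiating each ``?`` placeholder with
a field of that element, and attach the returned columns as attributes.
Mode 4 (expand) runs a per-seed query whose rows name new neighbor nodes,
wiring each neighbor to its seed.

Per-element execution is the semantic contract: the enrichment modes issue
exactly one query per processed element, observable through the
connection handle's ``query_count``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Any, Sequence

from .connections import ConnectionHandle
from .errors import MappingError
from .network_model import MISSING, EdgeKey, Network, convert_db_value
from .query_engine import ResultTable, ValidatedQuery, execute

logger = logging.getLogger(__name__)

# Column roles
SOURCE_ID = "source_id"
TARGET_ID = "target_id"
SOURCE_ATTR = "source_attr"
TARGET_ATTR = "target_attr"
EDGE_ATTR = "edge_attr"
EDGE_TYPE = "edge_type"
IGNORE = "ignore"

ROLES = (SOURCE_ID, TARGET_ID, SOURCE_ATTR, TARGET_ATTR, EDGE_ATTR, EDGE_TYPE, IGNORE)

#: Edge type used when no EDGE_TYPE column is mapped.
DEFAULT_EDGE_TYPE = "interaction"


@dataclass(frozen=True)
class ColumnRole:
    """One column's role; attribute roles carry the attribute name
    (defaulting to the column name at resolution time)."""

    role: str
    attr_name: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise MappingError(f"unknown column role {self.role!r}")


@dataclass(frozen=True)
class ColumnRoleMap:
    """Per-result-column role assignment, in column order."""

    roles: tuple[ColumnRole, ...]

    @classmethod
    def parse(cls, spec: Sequence[str]) -> "ColumnRoleMap":
        """Parse textual role specs like ``["source", "target", "edgetype",
        "edgeattr:score"]`` (role optionally followed by ``:attrname``)."""
        aliases = {
            "source": SOURCE_ID, "source_id": SOURCE_ID,
            "target": TARGET_ID, "target_id": TARGET_ID,
            "sourceattr": SOURCE_ATTR, "source_attr": SOURCE_ATTR,
            "targetattr": TARGET_ATTR, "target_attr": TARGET_ATTR,
            "edgeattr": EDGE_ATTR, "edge_attr": EDGE_ATTR,
            "edgetype": EDGE_TYPE, "edge_type": EDGE_TYPE,
            "ignore": IGNORE,
        }
        roles = []
        for item in spec:
            role_txt, _, attr = item.partition(":")
            key = role_txt.strip().lower()
            if key not in aliases:
                raise MappingError(f"unknown column role {role_txt!r}")
            roles.append(ColumnRole(aliases[key], attr.strip() or None))
        return cls(tuple(roles))

    def _count(self, role: str) -> int:
        return sum(1 for r in self.roles if r.role == role)

    def validate_create(self, n_columns: int) -> None:
        if len(self.roles) != n_columns:
            raise MappingError(
                f"role map has {len(self.roles)} entries for {n_columns} result columns"
            )
        if self._count(SOURCE_ID) != 1:
            raise MappingError("create/expand mode needs exactly one source-id column")
        if self._count(TARGET_ID) > 1:
            raise MappingError("at most one target-id column is allowed")
        if self._count(EDGE_TYPE) > 1:
            raise MappingError("at most one edge-type column is allowed")
        if self._count(TARGET_ID) == 0 and (self._count(TARGET_ATTR) or self._count(EDGE_ATTR) or self._count(EDGE_TYPE)):
            raise MappingError("target/edge roles require a target-id column")

    def validate_expand(self, n_columns: int) -> None:
        if len(self.roles) != n_columns:
            raise MappingError(
                f"role map has {len(self.roles)} entries for {n_columns} result columns"
            )
        if self._count(SOURCE_ID) != 1:
            raise MappingError("expand mode needs exactly one source-id column (the new neighbor)")
        if self._count(TARGET_ID) != 0:
            raise MappingError("expand mode takes no target-id column; the seed is the implicit endpoint")
        if self._count(EDGE_TYPE) > 1:
            raise MappingError("at most one edge-type column is allowed")


@dataclass(frozen=True)
class BindSpec:
    """Ordered field references instantiating a query's ``?`` placeholders.

    Node references: ``ID`` or an attribute name.  Edge references:
    ``SOURCE``, ``TARGET``, ``TYPE``, an edge attribute name, or an
    endpoint attribute via ``source.<name>`` / ``target.<name>`` (a bare
    attribute name missing on the edge falls back to the source node).
    """

    fields: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.fields)


@dataclass(frozen=True)
class Selection:
    """Explicit element selection; empty means "all elements"."""

    node_ids: frozenset[str] = frozenset()
    edge_keys: frozenset[EdgeKey] = frozenset()

    @classmethod
    def nodes(cls, ids: Sequence[str]) -> "Selection":
        return cls(node_ids=frozenset(ids))

    @classmethod
    def edges(cls, keys: Sequence[EdgeKey]) -> "Selection":
        return cls(edge_keys=frozenset(keys))

    @classmethod
    def all(cls) -> "Selection":
        return cls()

    @property
    def is_all(self) -> bool:
        return not self.node_ids and not self.edge_keys


# ---------------------------------------------------------------------------
# Mode 1: create network
# ---------------------------------------------------------------------------

def create_network(result: ResultTable, roles: ColumnRoleMap, net: Network | None = None) -> Network:
    """Build (or merge into) a network from one result table.

    Per row: the source-id value becomes/updates a node; when a target-id
    column is present and non-null, a target node and an edge
    ``(source, target, type)`` are created, the type taken from the
    edge-type column value (default "interaction"); attribute columns are
    converted per their declared class and attached to their element.
    Rows with a null id are skipped with a warning; null attribute values
    set nothing.
    """
    roles.validate_create(len(result.column_names))
    net = net if net is not None else Network()
    cols = list(zip(result.column_names, result.column_types, roles.roles))
    for row in result.rows:
        src = tgt = None
        edge_type = DEFAULT_EDGE_TYPE
        src_attrs: dict[str, Any] = {}
        tgt_attrs: dict[str, Any] = {}
        edge_attrs: dict[str, Any] = {}
        skip = False
        for value, (name, ctype, cr) in zip(row, cols):
            if cr.role == IGNORE:
                continue
            if cr.role == SOURCE_ID:
                if value is None:
                    logger.warning("row with null source id skipped: %r", row)
                    skip = True
                    break
                src = str(value)
            elif cr.role == TARGET_ID:
                tgt = None if value is None else str(value)
            elif cr.role == EDGE_TYPE:
                if value is not None:
                    edge_type = str(value)
            else:
                converted = convert_db_value(value, ctype)
                if converted is None:
                    continue
                attr = cr.attr_name or name
                {SOURCE_ATTR: src_attrs, TARGET_ATTR: tgt_attrs, EDGE_ATTR: edge_attrs}[cr.role][attr] = converted
        if skip:
            continue
        net.add_node(src, src_attrs)
        if tgt is not None:
            net.add_node(tgt, tgt_attrs)
            net.add_edge(src, tgt, edge_type, edge_attrs)
    return net


# ---------------------------------------------------------------------------
# Bind resolution and attribute attachment shared by Modes 2-4
# ---------------------------------------------------------------------------

def _resolve_node_binds(net: Network, node_id: str, spec: BindSpec) -> list[Any] | None:
    values = []
    for ref in spec.fields:
        if ref.startswith(("source.", "target.")):
            raise MappingError(f"node enrichment binds cannot reference edge endpoints: {ref!r}")
        if ref in ("SOURCE", "TARGET", "TYPE"):
            raise MappingError(f"node enrichment binds cannot reference edge fields: {ref!r}")
        v = net.node_field(node_id, ref)
        if v is MISSING:
            logger.warning("node %s lacks bound field %r; skipped", node_id, ref)
            return None
        values.append(v)
    return values


def _resolve_edge_binds(net: Network, key: EdgeKey, spec: BindSpec) -> list[Any] | None:
    src, tgt, _ = key
    values = []
    for ref in spec.fields:
        if ref.startswith("source."):
            v = net.node_field(src, ref[len("source."):])
        elif ref.startswith("target."):
            v = net.node_field(tgt, ref[len("target."):])
        else:
            v = net.edge_field(key, ref)
            if v is MISSING:
                # bare attribute names fall back to the source endpoint
                v = net.node_field(src, ref)
        if v is MISSING:
            logger.warning("edge %s lacks bound field %r; skipped", key, ref)
            return None
        values.append(v)
    return values


def _is_echo(col_values: list[Any], name: str, spec: BindSpec, binds: list[Any]) -> bool:
    """A returned column is a join echo if its name matches a bound field
    reference or every value it returned equals one of the bind values."""
    if name in spec.fields:
        return True
    non_null = [v for v in col_values if v is not None]
    return bool(non_null) and all(v in binds for v in non_null)


def _collapse_columns(
    result: ResultTable, spec: BindSpec, binds: list[Any], store_echo: bool
) -> dict[str, Any]:
    """Turn a per-element result into an attribute dict: single row gives
    scalars, several rows give lists in row order; nulls set nothing."""
    attrs: dict[str, Any] = {}
    for i, (name, ctype) in enumerate(zip(result.column_names, result.column_types)):
        col = [r[i] for r in result.rows]
        if not store_echo and _is_echo(col, name, spec, binds):
            continue
        converted = [convert_db_value(v, ctype) for v in col]
        non_null = [v for v in converted if v is not None]
        if not non_null:
            continue
        attrs[name] = non_null[0] if len(result.rows) == 1 else non_null
    return attrs


# ---------------------------------------------------------------------------
# Mode 2: load node attributes
# ---------------------------------------------------------------------------

def load_node_attributes(
    conn: ConnectionHandle,
    query: ValidatedQuery,
    binds: BindSpec,
    net: Network,
    sel: Selection = Selection.all(),
    store_echo: bool = False,
) -> Network:
    """Run the query once per selected node (all nodes when the selection
    is empty) and attach the returned columns as node attributes.

    A single-row result yields scalar attributes; a multi-row result
    yields one list per column, row order preserved; a zero-row result
    leaves the node unchanged.  Echoed join columns are dropped unless
    ``store_echo`` is set.
    """
    _require_placeholders(query)
    if len(binds) != query.placeholder_count:
        raise MappingError(
            f"bind spec has {len(binds)} reference(s) for {query.placeholder_count} placeholder(s)"
        )
    targets = sorted(sel.node_ids) if not sel.is_all else sorted(net.node_ids())
    for node_id in targets:
        values = _resolve_node_binds(net, node_id, binds)
        if values is None:
            continue
        result = execute(conn, query, values)
        for name, value in _collapse_columns(result, binds, values, store_echo).items():
            net.set_node_attr(node_id, name, value)
    return net


# ---------------------------------------------------------------------------
# Mode 3: load edge attributes
# ---------------------------------------------------------------------------

def load_edge_attributes(
    conn: ConnectionHandle,
    query: ValidatedQuery,
    binds: BindSpec,
    net: Network,
    sel: Selection = Selection.all(),
    store_echo: bool = False,
) -> Network:
    """Run the query once per selected edge and attach returned columns as
    edge attributes.  Bind references may name edge fields (``SOURCE``,
    ``TARGET``, ``TYPE``, attribute names) or endpoint node attributes
    (``source.<name>`` / ``target.<name>``)."""
    _require_placeholders(query)
    if len(binds) != query.placeholder_count:
        raise MappingError(
            f"bind spec has {len(binds)} reference(s) for {query.placeholder_count} placeholder(s)"
        )
    targets = sorted(sel.edge_keys) if not sel.is_all else sorted(net.edge_keys())
    for key in targets:
        values = _resolve_edge_binds(net, key, binds)
        if values is None:
            continue
        result = execute(conn, query, values)
        for name, value in _collapse_columns(result, binds, values, store_echo).items():
            net.set_edge_attr(key, name, value)
    return net


# ---------------------------------------------------------------------------
# Mode 4: expand network
# ---------------------------------------------------------------------------

def expand_network(
    conn: ConnectionHandle,
    query: ValidatedQuery,
    binds: BindSpec,
    roles: ColumnRoleMap,
    net: Network,
    sel: Selection = Selection.all(),
    seed_is_source: bool = True,
) -> Network:
    """For each seed node, add the neighbors (and their edges) the query
    returns.

    The role map's single source-id column names the NEW neighbor; the
    seed is the implicit other endpoint.  Edges run seed→neighbor by
    default (``seed_is_source=False`` flips them).  Edge-attr columns land
    on the new edge, source-attr columns on the neighbor node.
    """
    _require_placeholders(query)
    if len(binds) != query.placeholder_count:
        raise MappingError(
            f"bind spec has {len(binds)} reference(s) for {query.placeholder_count} placeholder(s)"
        )
    seeds = sorted(sel.node_ids) if not sel.is_all else sorted(net.node_ids())
    for seed in seeds:
        values = _resolve_node_binds(net, seed, binds)
        if values is None:
            continue
        result = execute(conn, query, values)
        roles.validate_expand(len(result.column_names))
        cols = list(zip(result.column_names, result.column_types, roles.roles))
        for row in result.rows:
            neighbor = None
            edge_type = DEFAULT_EDGE_TYPE
            nbr_attrs: dict[str, Any] = {}
            edge_attrs: dict[str, Any] = {}
            for value, (name, ctype, cr) in zip(row, cols):
                if cr.role == IGNORE:
                    continue
                if cr.role == SOURCE_ID:
                    neighbor = None if value is None else str(value)
                elif cr.role == EDGE_TYPE:
                    if value is not None:
                        edge_type = str(value)
                elif cr.role in (SOURCE_ATTR, EDGE_ATTR):
                    converted = convert_db_value(value, ctype)
                    if converted is None:
                        continue
                    attr = cr.attr_name or name
                    (nbr_attrs if cr.role == SOURCE_ATTR else edge_attrs)[attr] = converted
                else:
                    raise MappingError(f"role {cr.role!r} is not valid in expand mode")
            if neighbor is None:
                logger.warning("expansion row with null neighbor id skipped: %r", row)
                continue
            net.add_node(neighbor, nbr_attrs)
            if seed_is_source:
                net.add_edge(seed, neighbor, edge_type, edge_attrs)
            else:
                net.add_edge(neighbor, seed, edge_type, edge_attrs)
    return net


def _require_placeholders(query: ValidatedQuery) -> None:
    if query.placeholder_count < 1:
        raise MappingError("this mode requires at least one ? bind variable in the query")
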