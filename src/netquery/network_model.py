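"""Attributed directed multigraph shared by all mapping modes.

The model mirrors the conventions of interactive network tools: nodes are
keyed by a text identifier, edges by the triple ``(source, target, type)``
(the familiar ``source (type) target`` notation), and both carry typed
attributes.  Attribute values are restricted to the scalar kinds a typical
attribute browser understands -- integer, real, text, boolean -- or a
homogeneous non-empty list of one of those, which is what multi-row
enrichment results become.

Internally the graph is a :class:`networkx.MultiDiGraph` whose edge key is
the edge type, so referential integrity (no dangling edges, node removal
removes incident edges) is inherited rather than re-implemented.
"""

from __future__ import annotations

import logging
import math
from typing import Any, Iterator

import networkx as nx

from .errors import NotFoundError

logger = logging.getLogger(__name__)

#: Sentinel returned by field lookups when an attribute is absent.
#: Distinct from None so callers can tell "no such attribute" from a
#: database null that happened to be stored (nulls are never stored).
MISSING = object()

EdgeKey = tuple[str, str, str]

_SCALAR_KINDS = {int: "integer", float: "real", str: "text", bool: "boolean"}


def attribute_kind(value: Any) -> str:
    """Classify an attribute value: 'integer', 'real', 'text', 'boolean',
    or 'list_<kind>' for homogeneous lists.  Raises TypeError otherwise."""
    if isinstance(value, bool):
        return "boolean"
    if isinstance(value, int):
        return "integer"
    if isinstance(value, float):
        return "real"
    if isinstance(value, str):
        return "text"
    if isinstance(value, list):
        if not value:
            raise TypeError("list attributes must be non-empty")
        kinds = {attribute_kind(v) for v in value}
        if len(kinds) != 1 or next(iter(kinds)).startswith("list_"):
            raise TypeError(f"list attributes must be homogeneous scalars, got kinds {kinds}")
        return "list_" + next(iter(kinds))
    raise TypeError(f"unsupported attribute value type: {type(value).__name__}")


def convert_db_value(raw: Any, declared_type: str) -> Any:
    """Convert one database value to an attribute value.

    ``declared_type`` is one of the column-type classes reported by the
    query engine: ``integer``, ``real``, ``text``, ``boolean``, ``unknown``.
    Nulls return None (the caller sets no attribute); unknown types degrade
    to their text rendering so conversion is total.
    """
    if raw is None:
        return None
    if declared_type == "integer":
        return int(raw)
    if declared_type == "real":
        f = float(raw)
        return f if math.isfinite(f) else str(raw)
    if declared_type == "boolean":
        if isinstance(raw, str):
            return raw.strip().lower() in ("1", "true", "t", "y", "yes")
        return bool(raw)
    if declared_type == "text":
        return raw if isinstance(raw, str) else str(raw)
    # unknown → text rendering
    return raw if isinstance(raw, str) else str(raw)


class Network:
    """Directed attributed multigraph with ``(source, target, type)`` edge keys."""

    def __init__(self) -> None:
        self._g = nx.MultiDiGraph()

    # -- construction -------------------------------------------------

    def add_node(self, node_id: str, attrs: dict[str, Any] | None = None) -> None:
        """Add or merge a node.  Re-adding merges attributes, new values
        overwriting old ones; other attributes are preserved."""
        if not isinstance(node_id, str) or node_id == "":
            raise ValueError("node id must be non-empty text")
        if self._g.has_node(node_id):
            if attrs:
                self._g.nodes[node_id].update(attrs)
        else:
            self._g.add_node(node_id, **(attrs or {}))

    def add_edge(
        self,
        source: str,
        target: str,
        type: str = "interaction",
        attrs: dict[str, Any] | None = None,
    ) -> EdgeKey:
        """Add or merge an edge keyed by (source, target, type).

        Endpoints are auto-created with empty attributes.  A duplicate key
        merges attributes with overwrite and logs a warning, so re-running
        an enrichment converges instead of erroring.
        """
        self.add_node(source)
        self.add_node(target)
        if self._g.has_edge(source, target, key=type):
            logger.warning("duplicate edge (%s, %s, %s): merging attributes", source, target, type)
            if attrs:
                self._g.edges[source, target, type].update(attrs)
        else:
            self._g.add_edge(source, target, key=type, **(attrs or {}))
        return (source, target, type)

    def remove_node(self, node_id: str) -> None:
        if not self._g.has_node(node_id):
            raise NotFoundError(f"no node {node_id!r}")
        self._g.remove_node(node_id)

    # -- inspection ----------------------------------------------------

    def has_node(self, node_id: str) -> bool:
        return self._g.has_node(node_id)

    def has_edge(self, key: EdgeKey) -> bool:
        s, t, ty = key
        return self._g.has_edge(s, t, key=ty)

    @property
    def node_count(self) -> int:
        return self._g.number_of_nodes()

    @property
    def edge_count(self) -> int:
        return self._g.number_of_edges()

    def node_ids(self) -> Iterator[str]:
        return iter(self._g.nodes)

    def edge_keys(self) -> Iterator[EdgeKey]:
        for s, t, ty in self._g.edges(keys=True):
            yield (s, t, ty)

    def node_attrs(self, node_id: str) -> dict[str, Any]:
        if not self._g.has_node(node_id):
            raise NotFoundError(f"no node {node_id!r}")
        return dict(self._g.nodes[node_id])

    def edge_attrs(self, key: EdgeKey) -> dict[str, Any]:
        s, t, ty = key
        if not self._g.has_edge(s, t, key=ty):
            raise NotFoundError(f"no edge {key!r}")
        return dict(self._g.edges[s, t, ty])

    def set_node_attr(self, node_id: str, name: str, value: Any) -> None:
        if not self._g.has_node(node_id):
            raise NotFoundError(f"no node {node_id!r}")
        attribute_kind(value)  # validates
        self._g.nodes[node_id][name] = value

    def set_edge_attr(self, key: EdgeKey, name: str, value: Any) -> None:
        s, t, ty = key
        if not self._g.has_edge(s, t, key=ty):
            raise NotFoundError(f"no edge {key!r}")
        attribute_kind(value)
        self._g.edges[s, t, ty][name] = value

    # -- field access (bind-variable resolution) -----------------------

    def node_field(self, node_id: str, field_name: str) -> Any:
        """Value of a node field: "ID" is the identifier, anything else an
        attribute name.  Returns MISSING when the attribute is absent."""
        if not self._g.has_node(node_id):
            raise NotFoundError(f"no node {node_id!r}")
        if field_name == "ID":
            return node_id
        return self._g.nodes[node_id].get(field_name, MISSING)

    def edge_field(self, key: EdgeKey, field_name: str) -> Any:
        """Value of an edge field: "SOURCE"/"TARGET" are endpoint ids,
        "TYPE" the edge type, anything else an attribute name."""
        s, t, ty = key
        if not self._g.has_edge(s, t, key=ty):
            raise NotFoundError(f"no edge {key!r}")
        if field_name == "SOURCE":
            return s
        if field_name == "TARGET":
            return t
        if field_name == "TYPE":
            return ty
        return self._g.edges[s, t, ty].get(field_name, MISSING)

    # -- comparison ----------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Network):
            return NotImplemented
        if set(self._g.nodes) != set(other._g.nodes):
            return False
        if set(self.edge_keys()) != set(other.edge_keys()):
            return False
        for n in self._g.nodes:
            if dict(self._g.nodes[n]) != dict(other._g.nodes[n]):
                return False
        for s, t, ty in self.edge_keys():
            if dict(self._g.edges[s, t, ty]) != dict(other._g.edges[s, t, ty]):
                return False
        return True

    def __hash__(self):  # networks are mutable; identity hash
        return id(self)

    def copy(self) -> "Network":
        net = Network()
        net._g = self._g.copy()
        return net

    def __repr__(self) -> str:
        return f"<Network nodes={self.node_count} edges={self.edge_count}>"

    @property
    def graph(self) -> nx.MultiDiGraph:
        """The underlying networkx graph (read access for analysis)."""
        return self._g
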