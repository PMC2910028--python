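"""Network serialization: SIF, GraphML, and tab-separated attribute tables.

All writers are deterministic -- nodes are ordered lexicographically by id
and edges by their (source, target, type) key -- so two writes of the same
network are byte-identical, which makes pipeline outputs diffable.

SIF here is the tab-delimited dialect: one ``source<TAB>type<TAB>target``
line per edge, isolated nodes as bare-id lines.  Multi-target lines
(``source type t1 t2 ...``) are accepted on read but never written.  SIF
carries structure only; attributes travel in GraphML or attribute tables.

GraphML documents declare one <key> per attribute with its scalar type;
list attributes are serialized as "|"-delimited text ("\\|" escapes a
literal bar) with the element type and delimiter declared in the key's
<desc>, so the read side restores them exactly.
"""

from __future__ import annotations

import csv
import logging
import os
from pathlib import Path
from typing import Any

from lxml import etree

from .errors import GraphIOError
from .network_model import Network, attribute_kind

logger = logging.getLogger(__name__)

GRAPHML_NS = "http://graphml.graphdrawing.org/xmlns"

LIST_DELIMITER = "|"


# ---------------------------------------------------------------------------
# SIF
# ---------------------------------------------------------------------------

def write_sif(net: Network, path: str | os.PathLike) -> None:
    """One tab-delimited edge per line; isolated nodes as bare-id lines."""
    lines = []
    connected: set[str] = set()
    for s, t, ty in sorted(net.edge_keys()):
        lines.append(f"{s}\t{ty}\t{t}")
        connected.update((s, t))
    for n in sorted(net.node_ids()):
        if n not in connected:
            lines.append(n)
    lines.sort()  # stable global order: bare ids interleave deterministically
    Path(path).write_text("".join(line + "\n" for line in lines))


def read_sif(path: str | os.PathLike) -> Network:
    """Parse SIF text.

    Tab-delimited lines are authoritative: one field is an isolated node,
    two fields are malformed (an edge needs three), three or more are a
    (multi-target) edge.  A line without tabs is space-split only when it
    has three or more tokens (legacy space-delimited edges); otherwise the
    whole line is one node id, so ids containing spaces survive.
    """
    net = Network()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if "\t" in line:
            fields = line.split("\t")
            if len(fields) == 2:
                raise GraphIOError(f"{path}:{lineno}: malformed SIF line (2 fields): {line!r}")
        else:
            tokens = line.split()
            fields = tokens if len(tokens) >= 3 else [line.strip()]
        if len(fields) == 1:
            net.add_node(fields[0])
        else:
            src, ty, *targets = fields
            for tgt in targets:
                net.add_edge(src, tgt, ty)
    return net


# ---------------------------------------------------------------------------
# GraphML
# ---------------------------------------------------------------------------

_GRAPHML_TYPE = {"integer": "long", "real": "double", "text": "string", "boolean": "boolean"}
_FROM_GRAPHML = {"long": "integer", "int": "integer", "integer": "integer",
                 "double": "real", "float": "real",
                 "string": "text", "boolean": "boolean"}


def _escape_item(item: Any) -> str:
    s = _scalar_to_text(item)
    return s.replace("\\", "\\\\").replace(LIST_DELIMITER, "\\" + LIST_DELIMITER)


def _split_list(text: str) -> list[str]:
    items, cur, i = [], [], 0
    while i < len(text):
        c = text[i]
        if c == "\\" and i + 1 < len(text):
            cur.append(text[i + 1])
            i += 2
        elif c == LIST_DELIMITER:
            items.append("".join(cur))
            cur = []
            i += 1
        else:
            cur.append(c)
            i += 1
    items.append("".join(cur))
    return items


def _scalar_to_text(v: Any) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, float):
        return repr(v)
    return str(v)


def _scalar_from_text(text: str, kind: str) -> Any:
    if kind == "integer":
        return int(text)
    if kind == "real":
        return float(text)
    if kind == "boolean":
        return text == "true"
    return text


def _element_attrs(net: Network, element: str):
    return (
        (net.node_attrs(n) for n in net.node_ids())
        if element == "node"
        else (net.edge_attrs(k) for k in net.edge_keys())
    )


def _collect_keys(net: Network, element: str) -> dict[str, str]:
    """Map attribute name -> kind over all nodes or edges.  An attribute
    that is scalar on one element and a list of the same scalar kind on
    another is promoted to the list kind; otherwise conflicting kinds
    degrade to text."""
    kinds: dict[str, str] = {}
    for attrs in _element_attrs(net, element):
        for name, value in attrs.items():
            kind = attribute_kind(value)
            prev = kinds.get(name)
            if prev is None or prev == kind:
                kinds[name] = kind
            elif prev.removeprefix("list_") == kind.removeprefix("list_"):
                kinds[name] = "list_" + kind.removeprefix("list_")
            else:
                kinds[name] = "text"
    return kinds


def write_graphml(net: Network, path: str | os.PathLike) -> None:
    """Full network with typed attributes.

    One <key> is declared per (attribute name, value kind) pair seen in
    the network, so an attribute that is a scalar on one element and a
    list on another round-trips exactly: the key id on each <data>
    element records which representation that element used.
    """
    root = etree.Element(f"{{{GRAPHML_NS}}}graphml", nsmap={None: GRAPHML_NS})
    key_ids: dict[tuple[str, str, str], str] = {}

    def declare_keys(element: str) -> None:
        pairs = sorted(
            {(name, attribute_kind(v)) for attrs in _element_attrs(net, element)
             for name, v in attrs.items()}
        )
        for name, kind in pairs:
            kid = f"{element[0]}{len(key_ids)}"
            key_ids[(element, name, kind)] = kid
            key = etree.SubElement(root, f"{{{GRAPHML_NS}}}key",
                                   id=kid, attrib={"for": element})
            key.set("attr.name", name)
            if kind.startswith("list_"):
                key.set("attr.type", "string")
                desc = etree.SubElement(key, f"{{{GRAPHML_NS}}}desc")
                desc.text = f"list of {kind[5:]}; delimiter {LIST_DELIMITER!r}"
            else:
                key.set("attr.type", _GRAPHML_TYPE[kind])

    declare_keys("node")
    declare_keys("edge")
    # a reserved key carries the edge type so it survives the round trip
    etype_key = etree.SubElement(root, f"{{{GRAPHML_NS}}}key",
                                 id="etype", attrib={"for": "edge"})
    etype_key.set("attr.name", "__edge_type__")
    etype_key.set("attr.type", "string")

    graph = etree.SubElement(root, f"{{{GRAPHML_NS}}}graph", edgedefault="directed")

    def write_data(parent, element: str, attrs: dict[str, Any]) -> None:
        for name in sorted(attrs):
            value = attrs[name]
            data = etree.SubElement(parent, f"{{{GRAPHML_NS}}}data",
                                    key=key_ids[(element, name, attribute_kind(value))])
            if isinstance(value, list):
                data.text = LIST_DELIMITER.join(_escape_item(v) for v in value)
            else:
                data.text = _scalar_to_text(value)

    for n in sorted(net.node_ids()):
        node_el = etree.SubElement(graph, f"{{{GRAPHML_NS}}}node", id=n)
        write_data(node_el, "node", net.node_attrs(n))
    for s, t, ty in sorted(net.edge_keys()):
        edge_el = etree.SubElement(graph, f"{{{GRAPHML_NS}}}edge", source=s, target=t)
        data = etree.SubElement(edge_el, f"{{{GRAPHML_NS}}}data", key="etype")
        data.text = ty
        write_data(edge_el, "edge", net.edge_attrs((s, t, ty)))

    etree.ElementTree(root).write(str(path), xml_declaration=True,
                                  encoding="UTF-8", pretty_print=True)


def read_graphml(path: str | os.PathLike) -> Network:
    """Inverse of :func:`write_graphml`; unknown attribute types degrade to
    text with a warning."""
    try:
        tree = etree.parse(str(path))
    except (OSError, etree.XMLSyntaxError) as exc:
        raise GraphIOError(f"cannot parse GraphML {path}: {exc}") from exc
    root = tree.getroot()
    ns = {"g": GRAPHML_NS}
    keys: dict[str, tuple[str, str]] = {}  # key id -> (attr name, kind)
    for key in root.findall("g:key", ns):
        name = key.get("attr.name")
        gtype = key.get("attr.type", "string")
        desc_el = key.find("g:desc", ns)
        desc = desc_el.text if desc_el is not None else ""
        if desc and desc.startswith("list of "):
            elem_kind = desc[len("list of "):].split(";")[0].strip()
            if elem_kind not in ("integer", "real", "text", "boolean"):
                logger.warning("unknown list element type %r; reading as text", elem_kind)
                elem_kind = "text"
            kind = "list_" + elem_kind
        elif gtype in _FROM_GRAPHML:
            kind = _FROM_GRAPHML[gtype]
        else:
            logger.warning("unknown GraphML attr.type %r; reading as text", gtype)
            kind = "text"
        keys[key.get("id")] = (name, kind)

    def read_data(el) -> tuple[dict[str, Any], str | None]:
        attrs: dict[str, Any] = {}
        etype = None
        for data in el.findall("g:data", ns):
            name, kind = keys.get(data.get("key"), (data.get("key"), "text"))
            text = data.text or ""
            if name == "__edge_type__":
                etype = text
            elif kind.startswith("list_"):
                attrs[name] = [_scalar_from_text(i, kind[5:]) for i in _split_list(text)]
            else:
                attrs[name] = _scalar_from_text(text, kind)
        return attrs, etype

    net = Network()
    graph = root.find("g:graph", ns)
    if graph is None:
        raise GraphIOError(f"{path}: no <graph> element")
    for node_el in graph.findall("g:node", ns):
        attrs, _ = read_data(node_el)
        net.add_node(node_el.get("id"), attrs)
    for edge_el in graph.findall("g:edge", ns):
        attrs, etype = read_data(edge_el)
        net.add_edge(edge_el.get("source"), edge_el.get("target"),
                     etype or "interaction", attrs)
    return net


# ---------------------------------------------------------------------------
# Attribute tables (TSV)
# ---------------------------------------------------------------------------
#
# Node tables are keyed by an ID column; edge tables by SOURCE, TYPE and
# TARGET columns.  Attribute column headers carry the declared type as
# "name:kind" (kind one of integer/real/text/boolean or list_<kind>).
# In a list-typed column, list cells start with the delimiter
# ("|a|b" is the list [a, b]); a cell without that prefix is a scalar of
# the element kind, so mixed scalar/list attributes round-trip exactly.

def _format_cell(value: Any, kind: str) -> str:
    if isinstance(value, list):
        return LIST_DELIMITER + LIST_DELIMITER.join(_escape_item(v) for v in value)
    if kind.startswith("list_"):
        return _escape_item(value)  # scalar cell in a list column: escape delimiters
    return _scalar_to_text(value)


def _parse_cell(text: str, kind: str) -> Any:
    if kind.startswith("list_"):
        elem = kind[5:]
        if text.startswith(LIST_DELIMITER):
            return [_scalar_from_text(i, elem) for i in _split_list(text[1:])]
        return _scalar_from_text(_split_list(text)[0], elem)
    return _scalar_from_text(text, kind)


def write_attribute_tables(
    net: Network, node_path: str | os.PathLike, edge_path: str | os.PathLike
) -> None:
    """Write node and edge attribute tables as TSV with typed headers.
    Cells for attributes an element lacks are left empty."""
    node_kinds = _collect_keys(net, "node")
    with open(node_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        attr_names = sorted(node_kinds)
        w.writerow(["ID"] + [f"{a}:{node_kinds[a]}" for a in attr_names])
        for n in sorted(net.node_ids()):
            attrs = net.node_attrs(n)
            w.writerow([n] + [_format_cell(attrs[a], node_kinds[a]) if a in attrs else "" for a in attr_names])

    edge_kinds = _collect_keys(net, "edge")
    with open(edge_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        attr_names = sorted(edge_kinds)
        w.writerow(["SOURCE", "TYPE", "TARGET"] + [f"{a}:{edge_kinds[a]}" for a in attr_names])
        for s, t, ty in sorted(net.edge_keys()):
            attrs = net.edge_attrs((s, t, ty))
            w.writerow([s, ty, t] + [_format_cell(attrs[a], edge_kinds[a]) if a in attrs else "" for a in attr_names])


def read_attribute_table(path: str | os.PathLike, net: Network) -> tuple[Network, int]:
    """Attach a table's attributes to matching elements of ``net``.

    The element kind is detected from the key columns (ID, or
    SOURCE/TYPE/TARGET).  A composite edge key column of the form
    ``source (type) target`` is also accepted.  Rows whose key matches no
    existing element are skipped; the skip count is returned.
    """
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows:
        raise GraphIOError(f"{path}: empty attribute table (header row required)")
    header = rows[0]

    def parse_attr_header(cell: str) -> tuple[str, str]:
        name, _, kind = cell.rpartition(":")
        if not name or kind not in ("integer", "real", "text", "boolean",
                                    "list_integer", "list_real", "list_text", "list_boolean"):
            return cell, "text"
        return name, kind

    skipped = 0
    if header[0] == "ID":
        attr_cols = [parse_attr_header(h) for h in header[1:]]
        for row in rows[1:]:
            if not row:
                continue
            node_id = row[0]
            if not net.has_node(node_id):
                skipped += 1
                continue
            for (name, kind), cell in zip(attr_cols, row[1:]):
                if cell != "":
                    net.set_node_attr(node_id, name, _parse_cell(cell, kind))
    elif header[:3] == ["SOURCE", "TYPE", "TARGET"]:
        attr_cols = [parse_attr_header(h) for h in header[3:]]
        for row in rows[1:]:
            if not row:
                continue
            key = (row[0], row[2], row[1])
            if not net.has_edge(key):
                skipped += 1
                continue
            for (name, kind), cell in zip(attr_cols, row[3:]):
                if cell != "":
                    net.set_edge_attr(key, name, _parse_cell(cell, kind))
    elif header[0] == "KEY":
        # composite edge key: "source (type) target"
        attr_cols = [parse_attr_header(h) for h in header[1:]]
        for row in rows[1:]:
            if not row:
                continue
            key = _parse_composite_key(row[0], path)
            if not net.has_edge(key):
                skipped += 1
                continue
            for (name, kind), cell in zip(attr_cols, row[1:]):
                if cell != "":
                    net.set_edge_attr(key, name, _parse_cell(cell, kind))
    else:
        raise GraphIOError(
            f"{path}: missing key column; expected ID, SOURCE/TYPE/TARGET, or KEY header"
        )
    if skipped:
        logger.info("%s: skipped %d row(s) with unmatched keys", path, skipped)
    return net, skipped


def _parse_composite_key(text: str, path) -> tuple[str, str, str]:
    lp, rp = text.find(" ("), text.rfind(") ")
    if lp < 0 or rp < 0 or rp <= lp:
        raise GraphIOError(f"{path}: malformed composite edge key {text!r}")
    return (text[:lp], text[rp + 2 :], text[lp + 2 : rp])
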