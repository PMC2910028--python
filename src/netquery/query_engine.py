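"""SELECT validation, parameterized execution, preview and query archives.

Validation is deliberately lexical rather than a full SQL parse: the
statement must start with SELECT (or WITH, for common-table-expression
queries), contain no second statement after an unquoted ``;``, and its
``?`` placeholders are counted by a quote- and comment-aware scan.  This
keeps the engine portable across database dialects while guaranteeing
read-only execution: bind values are always passed as typed positional
parameters, never spliced into the text.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import yaml

from .connections import ConnectionHandle
from .errors import (
    BindCountError,
    ExecutionError,
    NotFoundError,
    PersistenceError,
    QueryValidationError,
)

_WRITE_KEYWORDS = {
    "insert", "update", "delete", "drop", "create", "alter", "truncate",
    "replace", "grant", "revoke", "attach", "detach", "pragma", "vacuum",
    "begin", "commit", "rollback", "merge", "call", "exec", "execute", "set",
}


def _scan(sql: str) -> tuple[str, int, list[int]]:
    """Quote/comment-aware scan.

    Returns (text with quoted literals and comments blanked out,
    placeholder count, positions of unquoted semicolons).
    """
    out = []
    placeholders = 0
    semis: list[int] = []
    i, n = 0, len(sql)
    while i < n:
        c = sql[i]
        if c in ("'", '"', "`"):
            quote = c
            out.append(" ")
            i += 1
            while i < n:
                if sql[i] == quote:
                    if quote == "'" and i + 1 < n and sql[i + 1] == "'":
                        i += 2  # escaped '' inside a string literal
                        continue
                    i += 1
                    break
                i += 1
            out.append(" ")
        elif c == "-" and i + 1 < n and sql[i + 1] == "-":
            while i < n and sql[i] != "\n":
                i += 1
            out.append(" ")
        elif c == "/" and i + 1 < n and sql[i + 1] == "*":
            i += 2
            while i + 1 < n and not (sql[i] == "*" and sql[i + 1] == "/"):
                i += 1
            i = min(i + 2, n)
            out.append(" ")
        else:
            if c == "?":
                placeholders += 1
            elif c == ";":
                semis.append(len("".join(out)))
            out.append(c)
            i += 1
    return "".join(out), placeholders, semis


@dataclass(frozen=True)
class ValidatedQuery:
    """A single read-only SELECT with its counted ``?`` placeholders."""

    text: str
    placeholder_count: int


def validate_select(sql: str) -> ValidatedQuery:
    """Accept exactly one SELECT (or WITH ... SELECT) statement.

    Raises QueryValidationError for write statements (naming the offending
    keyword) and for multi-statement input.
    """
    if not sql or not sql.strip():
        raise QueryValidationError("empty query text")
    stripped, placeholders, semis = _scan(sql)
    words = stripped.split()
    if not words:
        raise QueryValidationError("query contains no statement")
    head = words[0].lower()
    if head in _WRITE_KEYWORDS:
        raise QueryValidationError(f"only SELECT statements are allowed, got {words[0].upper()!r}")
    if head not in ("select", "with"):
        raise QueryValidationError(f"statement must start with SELECT, got {words[0]!r}")
    for pos in semis:
        if stripped[pos + 1 :].strip():
            raise QueryValidationError("multiple statements are not allowed")
    return ValidatedQuery(text=sql.strip().rstrip(";").rstrip(), placeholder_count=placeholders)


@dataclass
class ResultTable:
    """Rows-and-columns answer to one query execution.

    ``column_types`` holds one declared class per column: ``integer``,
    ``real``, ``text``, ``boolean`` or ``unknown`` (inferred from returned
    values; all-null or empty columns are ``unknown``).
    """

    column_names: list[str]
    column_types: list[str]
    rows: list[tuple]

    def __post_init__(self) -> None:
        for r in self.rows:
            if len(r) != len(self.column_names):
                raise ValueError("row width does not match column count")

    def __len__(self) -> int:
        return len(self.rows)

    def column(self, name: str) -> list[Any]:
        idx = self.column_names.index(name)
        return [r[idx] for r in self.rows]


def _infer_type(values: Sequence[Any]) -> str:
    for v in values:
        if v is None:
            continue
        if isinstance(v, bool):
            return "boolean"
        if isinstance(v, int):
            return "integer"
        if isinstance(v, float):
            return "real"
        if isinstance(v, str):
            return "text"
        return "unknown"
    return "unknown"


def execute(conn: ConnectionHandle, query: ValidatedQuery, binds: Sequence[Any] = ()) -> ResultTable:
    """Run the query with positional bind values; nulls are preserved."""
    if len(binds) != query.placeholder_count:
        raise BindCountError(
            f"query has {query.placeholder_count} placeholder(s) but {len(binds)} bind value(s) given"
        )
    try:
        cols, rows = conn.execute(query.text, tuple(binds))
    except Exception as exc:  # database-side error
        raise ExecutionError(f"database error: {exc}") from exc
    types = [_infer_type([r[i] for r in rows]) for i in range(len(cols))]
    return ResultTable(column_names=cols, column_types=types, rows=rows)


def preview(
    conn: ConnectionHandle,
    query: ValidatedQuery,
    binds: Sequence[Any] = (),
    limit: int = 10,
) -> ResultTable:
    """Like execute, truncated to the first ``limit`` rows of the full result."""
    if limit <= 0:
        raise ValueError("preview limit must be positive")
    full = execute(conn, query, binds)
    return ResultTable(full.column_names, full.column_types, full.rows[:limit])


@dataclass
class QueryArchive:
    """Recent-query history (bounded, most-recent-first) and named favorites."""

    history: list[str] = field(default_factory=list)
    favorites: dict[str, str] = field(default_factory=dict)
    history_bound: int = 50
    path: Path | None = None

    @classmethod
    def load(cls, path: str | os.PathLike, history_bound: int = 50) -> "QueryArchive":
        p = Path(path)
        if not p.exists():
            return cls(history_bound=history_bound, path=p)
        try:
            doc = yaml.safe_load(p.read_text()) or {}
        except (OSError, yaml.YAMLError) as exc:
            raise PersistenceError(f"cannot read archive {p}: {exc}") from exc
        return cls(
            history=list(doc.get("history", []))[:history_bound],
            favorites=dict(doc.get("favorites", {})),
            history_bound=history_bound,
            path=p,
        )

    def save(self) -> None:
        if self.path is None:
            return
        try:
            self.path.parent.mkdir(parents=True, exist_ok=True)
            self.path.write_text(
                yaml.safe_dump({"history": self.history, "favorites": self.favorites}, sort_keys=False)
            )
        except OSError as exc:
            raise PersistenceError(f"cannot write archive {self.path}: {exc}") from exc


def record_query(archive: QueryArchive, sql: str) -> QueryArchive:
    """Push a query onto the history unless it repeats the most recent entry;
    evict the oldest entry beyond the bound."""
    if not archive.history or archive.history[0] != sql:
        archive.history.insert(0, sql)
        del archive.history[archive.history_bound :]
        archive.save()
    return archive


def save_favorite(archive: QueryArchive, name: str, sql: str) -> QueryArchive:
    archive.favorites[name] = sql
    archive.save()
    return archive


def list_favorites(archive: QueryArchive) -> list[str]:
    return sorted(archive.favorites)


def delete_favorite(archive: QueryArchive, name: str) -> QueryArchive:
    if name not in archive.favorites:
        raise NotFoundError(f"no favorite named {name!r}")
    del archive.favorites[name]
    archive.save()
    return archive
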