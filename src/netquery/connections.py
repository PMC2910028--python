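"""Named database connection profiles and session-level handles.

A :class:`ConnectionProfile` records the coordinates of one database; a
:class:`ProfileStore` persists any number of them in a single
human-editable YAML file so a session can switch between databases by
name.  Secrets are never written to the store: ``password_ref`` is an
opaque reference (conventionally the name of an environment variable)
resolved only at connection time.

The reference engine is the embedded single-file engine (SQLite via the
standard library).  Server engines (mysql-like, postgres-like) are valid
profile kinds -- the store round-trips them -- but opening them requires a
driver this package does not ship.
"""

from __future__ import annotations

import os
import sqlite3
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ConnectionError, PersistenceError

#: Supported engine kinds.
ENGINES = ("sqlite", "mysql", "postgres")


@dataclass(frozen=True)
class ConnectionProfile:
    """Access coordinates for one database.

    Parameters
    ----------
    name : unique label within a store.
    engine : one of ``sqlite`` (embedded file), ``mysql``, ``postgres``.
    location : file path (sqlite) or ``host[:port]`` (server engines).
    database : schema name; empty for the embedded engine.
    user, password_ref : account name and an opaque secret reference
        (e.g. an environment-variable name); the secret itself is never
        stored.
    """

    name: str
    engine: str
    location: str
    database: str = ""
    user: str = ""
    password_ref: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("profile name must be non-empty")
        if self.engine not in ENGINES:
            raise ValueError(f"unsupported engine {self.engine!r}; expected one of {ENGINES}")
        if self.engine == "sqlite":
            if not self.location:
                raise ValueError("embedded-file profiles need a non-empty file path")
            if self.database:
                raise ValueError("embedded-file profiles take no database name")


class ConnectionHandle:
    """An open, read-only session on one database.

    Counts executed statements (``query_count``) so callers can verify the
    one-query-per-element contract of the enrichment modes.
    """

    def __init__(self, profile: ConnectionProfile, raw: sqlite3.Connection):
        self.profile = profile
        self._raw = raw
        self.query_count = 0

    def execute(self, sql: str, params: tuple = ()) -> tuple[list[str], list[tuple]]:
        """Run one statement, returning (column names, rows)."""
        cur = self._raw.execute(sql, params)
        self.query_count += 1
        cols = [d[0] for d in cur.description] if cur.description else []
        return cols, cur.fetchall()

    def close(self) -> None:
        self._raw.close()

    def __enter__(self) -> "ConnectionHandle":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def open_connection(profile: ConnectionProfile) -> ConnectionHandle:
    """Open a handle for a profile.

    The embedded engine is opened in read-only mode (the file must already
    exist); handles for different profiles may coexist within a session.
    """
    if profile.engine != "sqlite":
        raise ConnectionError(profile.name, f"no driver available for engine {profile.engine!r}")
    path = Path(profile.location)
    if not path.exists():
        raise ConnectionError(profile.name, f"database file does not exist: {path}")
    try:
        raw = sqlite3.connect(f"file:{path}?mode=ro", uri=True)
    except sqlite3.Error as exc:
        raise ConnectionError(profile.name, str(exc)) from exc
    return ConnectionHandle(profile, raw)


def resolve_password(profile: ConnectionProfile) -> str | None:
    """Resolve the secret reference from the environment at connection time."""
    if not profile.password_ref:
        return None
    return os.environ.get(profile.password_ref)


class ProfileStore:
    """All known profiles, persisted as one YAML document."""

    def __init__(self, path: str | os.PathLike):
        self.path = Path(path)
        self.profiles: dict[str, ConnectionProfile] = {}

    @classmethod
    def load(cls, path: str | os.PathLike) -> "ProfileStore":
        """Load a store; a missing file yields an empty store."""
        store = cls(path)
        if not store.path.exists():
            return store
        try:
            doc = yaml.safe_load(store.path.read_text()) or {}
        except (OSError, yaml.YAMLError) as exc:
            raise PersistenceError(f"cannot read profile store {store.path}: {exc}") from exc
        for entry in doc.get("profiles", []):
            p = ConnectionProfile(**entry)
            store.profiles[p.name] = p
        return store

    def save(self) -> None:
        doc = {
            "profiles": [
                {
                    "name": p.name,
                    "engine": p.engine,
                    "location": p.location,
                    "database": p.database,
                    "user": p.user,
                    "password_ref": p.password_ref,
                }
                for p in sorted(self.profiles.values(), key=lambda p: p.name)
            ]
        }
        try:
            self.path.parent.mkdir(parents=True, exist_ok=True)
            self.path.write_text(yaml.safe_dump(doc, sort_keys=False))
        except OSError as exc:
            raise PersistenceError(f"cannot write profile store {self.path}: {exc}") from exc

    def names(self) -> list[str]:
        return sorted(self.profiles)

    def get(self, name: str) -> ConnectionProfile:
        try:
            return self.profiles[name]
        except KeyError:
            raise PersistenceError(f"no profile named {name!r} in {self.path}") from None


def save_profile(profile: ConnectionProfile, store: ProfileStore) -> ProfileStore:
    """Insert or replace a profile in the store and persist it."""
    store.profiles[profile.name] = profile
    store.save()
    return store


def remove_profile(name: str, store: ProfileStore) -> ProfileStore:
    if name not in store.profiles:
        raise PersistenceError(f"no profile named {name!r}")
    del store.profiles[name]
    store.save()
    return store
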