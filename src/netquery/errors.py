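"""Exception hierarchy.

Each branch maps onto one CLI exit code so shell callers can distinguish
usage mistakes from connection, query, mapping and I/O failures.
"""


class NetQueryError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class UsageError(NetQueryError):
    """Invalid arguments or manifest, detected before any database contact."""

    exit_code = 2


class PersistenceError(NetQueryError):
    """A config/archive store could not be read or written."""

    exit_code = 2


class ConnectionError(NetQueryError):  # noqa: A001 - deliberate shadowing, namespaced
    """A database could not be opened; carries the profile name and cause."""

    exit_code = 3

    def __init__(self, profile_name: str, cause: str):
        self.profile_name = profile_name
        self.cause = cause
        super().__init__(f"cannot open connection for profile {profile_name!r}: {cause}")


class QueryValidationError(NetQueryError):
    """The statement is not a single read-only SELECT."""

    exit_code = 4


class BindCountError(NetQueryError):
    """Number of bind values does not match the query's placeholder count."""

    exit_code = 4


class ExecutionError(NetQueryError):
    """The database rejected the statement; wraps the database message."""

    exit_code = 4


class MappingError(NetQueryError):
    """A column-role map or bind spec violates a mode's requirements."""

    exit_code = 5


class NotFoundError(NetQueryError):
    """A named element (node, edge, favorite, profile) does not exist."""

    exit_code = 5


class GraphIOError(NetQueryError):
    """A network or attribute-table file could not be parsed or written."""

    exit_code = 6
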