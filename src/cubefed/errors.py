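"""Exception hierarchy.

Every error raised deliberately by this package derives from
:class:`CubefedError`, so callers (and the CLI) can distinguish our
failures from genuine bugs.  The CLI maps each subclass to a distinct
exit code.
"""


class CubefedError(Exception):
    """Base class for all errors raised by cubefed."""

    exit_code = 1


class InputError(CubefedError):
    """A data or query file could not be parsed (syntax error)."""

    exit_code = 3


class QueryParseError(InputError):
    """The SPARQL query text is syntactically invalid."""


class UnsupportedFeatureError(CubefedError):
    """The query uses a SPARQL feature outside the supported fragment."""

    exit_code = 3


class ConfigurationError(CubefedError):
    """The federation configuration or run configuration is invalid."""

    exit_code = 4


class ConnectionError(CubefedError):  # noqa: A001 - mirrors the builtin on purpose
    """A remote SPARQL endpoint could not be reached."""

    exit_code = 5


class ValidationError(CubefedError):
    """Loaded data violates a structural invariant (blank node,
    default-graph triple, duplicate graph name, ...)."""

    exit_code = 6


class UnsupportedOperationError(CubefedError):
    """The operation is not available in the current mode
    (e.g. locality validation against remote endpoints)."""

    exit_code = 6
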