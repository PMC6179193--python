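"""Exception hierarchy shared across the package.

Everything derives from :class:`CassError` so callers (notably the CLI) can
distinguish data/parameter problems from genuine bugs with one except clause.
"""


class CassError(Exception):
    """Base class for all errors raised by cassnet."""


class ParseError(CassError, ValueError):
    """An input file line could not be parsed."""


class ValidationError(CassError, ValueError):
    """A value or structure violates a container invariant."""


class ParameterError(CassError, ValueError):
    """A user-supplied parameter is outside its valid range."""


class ConsistencyError(CassError, ValueError):
    """Two inputs that must describe the same graph disagree."""


class EdgeDomainError(CassError, ValueError):
    """An operation defined only on edges was asked about a non-edge."""


class UndefinedMetricError(CassError, ValueError):
    """A quality metric is undefined for the given clustering (e.g. empty)."""
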