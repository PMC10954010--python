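"""Exception hierarchy shared across the package.

Exit-code mapping for the CLI lives in :mod:`foodsec.cli`; library code raises
these and never calls ``sys.exit``.
"""


class FoodsecError(Exception):
    """Base class for all package errors."""


class SchemaError(FoodsecError):
    """A survey table does not conform to the documented CSV schema."""


class ValidationError(FoodsecError):
    """A value is outside its documented domain (e.g. food days not in 0..7)."""


class ConfigError(FoodsecError):
    """An indicator/tree configuration is inconsistent or incomplete."""


class MissingDataError(FoodsecError):
    """An operation that requires complete data met a missing field."""


class DegenerateTableError(FoodsecError):
    """A contingency table has fewer than two categories on some margin."""


class GenerationError(FoodsecError):
    """The synthetic generator was asked for an infeasible target."""
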