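"""Exception hierarchy.

Parsing problems (malformed files) raise :class:`FormatError`; well-formed but
physically or structurally invalid input raises :class:`ValidationError`;
inconsistent run options raise :class:`ConfigurationError`.  All derive from
:class:`AwespecError` so callers can catch the package's errors in one clause.
"""


class AwespecError(Exception):
    """Base class for all errors raised by awespec."""


class FormatError(AwespecError, ValueError):
    """A file or stream does not conform to its declared on-disk format."""


class ValidationError(AwespecError, ValueError):
    """Input parses but violates a domain invariant (e.g. non-monotone grid)."""


class ConfigurationError(AwespecError, ValueError):
    """Run options are inconsistent with each other or with the data."""


class RangeError(AwespecError, ValueError):
    """A requested target grid lies outside a source spectrum's energy range."""


class ContractError(AwespecError, ValueError):
    """A pluggable component returned output violating its contract (shape, order)."""


class NumericalError(AwespecError, ArithmeticError):
    """A linear solve or optimization step failed numerically (singular system, NaN loss)."""


class GenerationError(AwespecError, RuntimeError):
    """The synthetic-structure generator could not satisfy its geometric constraints."""
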