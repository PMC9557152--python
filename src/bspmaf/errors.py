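"""Exception hierarchy.

All bspmaf errors derive from :class:`BspmError` so callers can catch the
package's failures with a single except clause; each subclass also derives
from ``ValueError`` to stay friendly to generic validation code.
"""


class BspmError(Exception):
    """Base class for all bspmaf errors."""


class FormatError(BspmError, ValueError):
    """A file or sidecar is malformed or of an unsupported format."""


class DimensionError(BspmError, ValueError):
    """Array shapes are inconsistent with the declared lead/sample counts."""


class ConfigError(BspmError, ValueError):
    """A configuration value is out of its admissible range."""


class QualityError(BspmError, ValueError):
    """Too many leads are unusable for the requested operation."""


class InsufficientDataError(BspmError, ValueError):
    """Not enough samples, beats or values to perform the computation."""


class UndefinedResultError(BspmError, ArithmeticError):
    """The requested quantity is mathematically undefined on this input."""
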