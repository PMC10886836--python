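"""Exception hierarchy for mstate.

All exceptions derive from :class:`MstateError` so callers can catch the
package's failures with a single except clause; the subclasses distinguish
bad configuration, mismatched array shapes, quantities that are
mathematically undefined for the given input, and invalid data values.
"""


class MstateError(Exception):
    """Base class for all mstate errors."""


class ConfigurationError(MstateError, ValueError):
    """A parameter combination is invalid (e.g. band above Nyquist)."""


class DimensionError(MstateError, ValueError):
    """Array shapes or channel counts do not match."""


class UndefinedResultError(MstateError, ArithmeticError):
    """The requested quantity is undefined for this input (e.g. GEV of an
    all-zero epoch, features of an all-unassigned label sequence)."""


class InvalidInputError(MstateError, ValueError):
    """A data value is outside its documented domain (e.g. valence not 1-9)."""
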