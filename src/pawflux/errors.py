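"""Exception hierarchy.

``PawfluxError`` is the base for everything raised deliberately by this
package; ``UserInputError`` subclasses map to CLI exit code 1, anything
else escaping to the CLI is treated as an internal error (exit code 2).
"""


class PawfluxError(Exception):
    """Base class for all deliberate pawflux errors."""


class UserInputError(PawfluxError):
    """Problems caused by user-supplied data or parameters."""


class FormatError(UserInputError):
    """Malformed input file (e.g. a broken DeepLabCut CSV header)."""


class EmptyInputError(UserInputError):
    """Structurally valid input that contains no usable data."""


class ParameterError(UserInputError):
    """Out-of-range or inconsistent parameter value."""


class UnusablePartError(UserInputError):
    """A body part has no observed samples at all."""


class DegenerateSeriesError(UserInputError):
    """A series is constant (zero detrended variance), so correlation
    coefficients are undefined."""


class IncompleteGraphError(UserInputError):
    """Coupling data is missing for one or more body-part pairs."""


class AnalysisError(PawfluxError):
    """Internal inconsistency detected during analysis."""
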