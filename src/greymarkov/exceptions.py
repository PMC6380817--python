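"""Exception hierarchy for grey-model fitting and Markov correction."""


class GreyModelError(Exception):
    """Base class for all package errors."""


class InvalidSeriesError(GreyModelError, ValueError):
    """Input series violates a precondition (empty, non-positive, too short)."""


class DegenerateFitError(GreyModelError, ArithmeticError):
    """Normal equations are singular; the grey parameters are not identifiable."""


class FitQualityWarning(UserWarning):
    """Fitted values are non-positive; ratio states will be unstable."""


class DegeneratePartitionError(GreyModelError, ValueError):
    """Ratio range has zero width; no state partition exists."""


class StateRangeWarning(UserWarning):
    """A ratio fell outside the partition and was clamped to the nearest state."""


class UndefinedTestError(GreyModelError, ValueError):
    """Markov-property test undefined (fewer than two distinct states)."""


class UndefinedDiagnosticError(GreyModelError, ArithmeticError):
    """Diagnostic undefined (constant original series: Sx = 0)."""


class ConfigError(GreyModelError, ValueError):
    """Run configuration is inconsistent (window, horizon, boundaries)."""


class ParseError(GreyModelError, ValueError):
    """Input file is malformed; message names the offending row."""
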