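"""Exception types shared across the pipeline."""


class SpastEMGError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SpastEMGError, ValueError):
    """A file or table does not have the expected layout."""


class ParseError(SpastEMGError, ValueError):
    """A cell could not be parsed; carries the offending row index."""


class GradeError(SpastEMGError, ValueError):
    """An MAS label outside the supported set."""


class BoundsError(SpastEMGError, ValueError):
    """A sample interval falls outside the recording."""


class ConfigurationError(SpastEMGError, ValueError):
    """Inconsistent pipeline or generator configuration."""


class DomainError(SpastEMGError, ValueError):
    """Input violates an operation's preconditions (e.g. empty signal)."""


class UndefinedFeatureError(SpastEMGError, ValueError):
    """A feature is undefined for the input (e.g. zero spectral power)."""


class DegenerateFeatureError(SpastEMGError, ValueError):
    """A feature column is constant, so max-min normalization is undefined."""


class UndefinedCorrelationError(SpastEMGError, ValueError):
    """Rank correlation undefined because one side has zero rank variance."""


class DegenerateWeightsError(SpastEMGError, ValueError):
    """Channel correlations cannot be turned into weights (zero sum or mixed signs)."""


class DataError(SpastEMGError, ValueError):
    """Dataset does not meet the sampling design (e.g. too few samples per grade)."""
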