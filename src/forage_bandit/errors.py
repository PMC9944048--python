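"""Exception hierarchy for the forage-bandit pipeline.

Each error class maps to a distinct nonzero exit code in the CLI, so shell
pipelines can distinguish bad configuration from bad input data.
"""


class ForageBanditError(Exception):
    """Base class for all package-specific errors."""

    exit_code = 1


class ConfigurationError(ForageBanditError):
    """Invalid parameter values or inconsistent run configuration."""

    exit_code = 5


class ValidationError(ForageBanditError):
    """Malformed input data (bad CSV schema, non-binary outcomes, ...)."""

    exit_code = 4


class MissingInputError(ForageBanditError):
    """A required input file does not exist."""

    exit_code = 3


class InsufficientDataError(ForageBanditError):
    """Too few valid records for the requested computation."""

    exit_code = 6


class DegenerateRangeError(ForageBanditError):
    """Min-max normalization attempted on a constant vector."""

    exit_code = 7


class UndefinedCorrelationError(ForageBanditError):
    """Pearson correlation requested on <3 points or a zero-variance vector."""

    exit_code = 8
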