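"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: configuration problems -> 2,
data/schema problems -> 3, model-fitting problems -> 4.
"""


class AlcodocError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AlcodocError):
    """Invalid or incomplete configuration (bad probabilities, missing paths)."""

    exit_code = 2


class DataError(AlcodocError):
    """Malformed or relationally inconsistent input data."""

    exit_code = 3


class SchemaError(DataError):
    """A table is missing required columns."""


class EmptyExtractError(DataError):
    """An operation received an empty extract where rows are required."""


class TemplateError(AlcodocError):
    """A note template was requested with an inconsistent quantity/category."""

    exit_code = 3


class ModelError(AlcodocError):
    """A regression model could not be fit (degenerate outcome, single cluster,
    non-convergence)."""

    exit_code = 4
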