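"""Exception hierarchy shared across the package."""


class AkiscoreError(Exception):
    """Base class for all package errors."""


class InvalidInputError(AkiscoreError, ValueError):
    """A scalar argument violates an operation's precondition."""


class CohortSchemaError(AkiscoreError, ValueError):
    """A cohort CSV file does not match the expected schema."""


class ConfigError(AkiscoreError, ValueError):
    """A generator or run configuration is invalid."""


class DesignError(AkiscoreError, ValueError):
    """A regression design matrix is rank deficient or otherwise unusable."""


class SeparationError(AkiscoreError, RuntimeError):
    """Maximum-likelihood logistic fit is degenerate (perfect separation)."""


class FitError(AkiscoreError, RuntimeError):
    """A model fit failed to converge or the data were degenerate."""
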