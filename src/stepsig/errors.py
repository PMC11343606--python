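"""Exception hierarchy shared across the package."""


class StepSigError(Exception):
    """Base class for all package errors."""


class ConfigurationError(StepSigError):
    """A configuration value is invalid; the message names the field."""


class InputError(StepSigError):
    """Input data violates a precondition (shape, finiteness, labels...)."""


class DegenerateFitError(StepSigError):
    """A fit cannot produce a meaningful statistic (e.g. n <= dof)."""


class ZeroEventsError(StepSigError):
    """Survival test requested but no events observed.

    Carries the per-stratum curves that were still computable.
    """

    def __init__(self, message: str, curves=None):
        super().__init__(message)
        self.curves = curves


class PipelineError(StepSigError):
    """A pipeline stage failed; names the stage and wraps the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
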