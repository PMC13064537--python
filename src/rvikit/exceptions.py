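"""Exception hierarchy shared across the package."""


class RvikitError(Exception):
    """Base class for all package errors."""


class ConfigurationError(RvikitError, ValueError):
    """A configuration value is invalid; the message names the offending field."""


class InputError(RvikitError, ValueError):
    """Input data violate a documented precondition (schema, ordering, signs)."""


class UndefinedExposureError(RvikitError, ValueError):
    """The regularity score is undefined (no inter-visit intervals).

    Raised instead of returning a sentinel so that callers are forced to
    exclude such patients upstream, mirroring the minimum-visit eligibility
    rule of the cohort design.
    """


class ConvergenceError(RvikitError, RuntimeError):
    """A maximum-likelihood fit failed to converge; carries the fit trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace


class PipelineStageError(RvikitError, RuntimeError):
    """A pipeline stage failed; partial artifacts are left in place."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage
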