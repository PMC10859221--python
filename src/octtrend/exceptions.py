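"""Exception hierarchy shared across the pipeline."""


class OctTrendError(Exception):
    """Base class for all package errors."""


class SchemaError(OctTrendError):
    """Input file does not provide a required column."""


class CohortValidationError(OctTrendError):
    """A cohort record violates a data invariant (duplicate row, bad value)."""


class LookupError_(OctTrendError):
    """An eye or session referenced by an operation does not exist."""


class EmptyCohortError(OctTrendError):
    """No eyes remain after filtering; downstream stages must not run."""


class IdentifiabilityError(OctTrendError):
    """A regression cannot be fit (e.g. all time points identical)."""


class ParameterError(OctTrendError):
    """An analysis parameter is outside its valid range."""


class ConfigurationError(OctTrendError):
    """A simulation or pipeline configuration is internally inconsistent."""


class PipelineStageError(OctTrendError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
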