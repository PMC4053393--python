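"""Exception hierarchy shared by all antnet modules."""


class AntNetError(Exception):
    """Base class for all antnet errors."""


class ValidationError(AntNetError):
    """Input data violates a domain invariant (bad period, non-positive count, ...)."""


class ConfigurationError(AntNetError):
    """A configuration value or file layout is unusable (missing column, bad schedule, ...)."""


class EmptyNetworkError(AntNetError):
    """No interactions remain after filtering; a network cannot be built."""


class UndefinedMetricError(AntNetError):
    """The requested metric is undefined on this input (too small, all-zero, ...)."""


class DegenerateDegreeError(AntNetError):
    """All species have identical degree: no generalist core is distinguishable."""


class DegeneratePredictorError(AntNetError):
    """A statistical test's input has zero variance."""


class PipelineStageError(AntNetError):
    """A pipeline stage failed; carries the stage name so reports never silently truncate."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"pipeline stage '{stage}' failed: {original}")
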