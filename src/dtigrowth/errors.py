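"""Exception hierarchy shared across the pipeline stages."""


class DtiGrowthError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DtiGrowthError):
    """Invalid configuration: bad parameter values, unusable acquisition scheme."""


class GridMismatchError(DtiGrowthError):
    """Companion volumes do not share the same voxel grid."""


class DomainError(DtiGrowthError):
    """Input outside the mathematical domain of an operation (empty ROI, zero SD, ...)."""


class PipelineStageError(DtiGrowthError):
    """Failure inside a named stage of the per-subject pipeline."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
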