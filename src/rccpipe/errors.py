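"""Exception hierarchy shared across the pipeline stages."""


class RCCPipeError(Exception):
    """Base class for all pipeline errors."""


class RCCFormatError(RCCPipeError):
    """An RCC stream is structurally malformed (e.g. a missing section)."""


class ConsistencyError(RCCPipeError):
    """Cross-object consistency violated (unknown probe, duplicate name...)."""


class JoinError(RCCPipeError):
    """Lanes could not be joined to the study design."""

    def __init__(self, orphan_sample_ids):
        self.orphan_sample_ids = list(orphan_sample_ids)
        super().__init__(
            "lanes without a study-design row: "
            + ", ".join(self.orphan_sample_ids)
        )


class InsufficientDataError(RCCPipeError):
    """Too few observations for a metric to be defined."""


class PipelineOrderError(RCCPipeError):
    """A normalization stage was applied out of its fixed order."""


class EstimationError(RCCPipeError):
    """Model estimation failed (singular design, non-convergence...)."""


class ConfigError(RCCPipeError):
    """Invalid configuration."""
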