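"""Exception hierarchy shared across the package."""


class HeatdexError(Exception):
    """Base class for all package-specific errors."""


class DomainError(HeatdexError, ValueError):
    """An input value lies outside the physically admissible range.

    The message always names the offending field and the value, so that
    logger faults surface instead of being silently absorbed.
    """


class ConfigurationError(HeatdexError, ValueError):
    """A scheme, generator or pipeline configuration is malformed."""


class LoggerFormatError(HeatdexError, ValueError):
    """A logger export file cannot be parsed into a valid reading series."""


class PipelineStageError(HeatdexError, RuntimeError):
    """Wraps a component failure with the pipeline stage that raised it."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"pipeline stage {stage!r} failed: {original}")
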