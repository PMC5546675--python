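"""Exception hierarchy for the autozyg pipeline."""


class AutozygError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AutozygError):
    """Invalid simulation or run configuration."""


class FormatError(AutozygError):
    """Malformed or inconsistent input file."""


class PipelineError(AutozygError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: str):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
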