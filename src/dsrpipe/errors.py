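"""Exception hierarchy shared across the package."""


class DsrPipeError(Exception):
    """Base class for all package-specific errors."""


class FormatError(DsrPipeError, ValueError):
    """Malformed on-disk artifact; the message names file and line."""


class ConfigError(DsrPipeError, ValueError):
    """Invalid simulation or pipeline configuration."""


class StageError(DsrPipeError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")
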