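"""Exception types shared across pipeline stages."""


class BcrPipeError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(BcrPipeError):
    """Invalid simulation or run configuration."""


class MalformedInputError(BcrPipeError):
    """An input record violates its format contract."""


class StageError(BcrPipeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
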