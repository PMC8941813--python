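"""Exception hierarchy shared across the package."""


class ValidationError(ValueError):
    """Invalid configuration or input values; names the offending field."""


class FormatError(ValueError):
    """Malformed input file (missing header, wrong columns, empty)."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
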