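"""Exception hierarchy for the measurement pipeline."""


class CornoctError(Exception):
    """Base class for all package errors."""


class StageError(CornoctError):
    """A pipeline stage failed; the message is prefixed with the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"{stage}: {message}")


class NoCorneaError(CornoctError):
    """No corneal region could be located in the image."""
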