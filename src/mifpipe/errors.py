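"""Exception hierarchy for the pipeline."""


class MifpipeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MifpipeError):
    """Invalid or inconsistent configuration (unknown rule names, bad grids...)."""


class DatasetError(MifpipeError):
    """Incomplete or inconsistent image collections."""

    def __init__(self, message, missing=None, skipped=None):
        super().__init__(message)
        self.missing = list(missing) if missing else []
        self.skipped = list(skipped) if skipped else []


class StageError(MifpipeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage, message):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
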