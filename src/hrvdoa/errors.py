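"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ConfigurationError -> 2, DataError -> 3,
any other stage failure -> 4.
"""


class HrvDoaError(Exception):
    """Base class for all package errors."""


class ConfigurationError(HrvDoaError):
    """Invalid configuration or parameters (CLI exit code 2)."""


class DataError(HrvDoaError):
    """Malformed, insufficient, or out-of-contract data (CLI exit code 3)."""


class StageError(HrvDoaError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
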