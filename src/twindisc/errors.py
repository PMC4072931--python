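"""Exception hierarchy."""


class TwindiscError(Exception):
    """Base class for all package errors."""


class ParameterError(TwindiscError, ValueError):
    """A parameter is outside its documented range."""


class InputError(TwindiscError, ValueError):
    """Malformed input data (intervals, tables, counts)."""


class PairingError(TwindiscError, ValueError):
    """Twin pairing table is inconsistent with the sample set."""


class SampleError(TwindiscError, ValueError):
    """A sample violates a per-sample requirement (e.g. zero total reads)."""


class StageError(TwindiscError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
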