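"""Exception types shared across the pipeline."""


class TcncallError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(TcncallError, ValueError):
    """An argument violates an operation's precondition."""


class InvalidRecordError(TcncallError, ValueError):
    """A mutation record is inconsistent with the sequence it annotates."""


class SimulationInfeasibleError(TcncallError, RuntimeError):
    """The simulator config demands more non-overlapping mutations than fit."""


class StratificationError(TcncallError, ValueError):
    """Too few items to form the requested stratified split."""


class TrainingFailureError(TcncallError, RuntimeError):
    """Optimization diverged to a non-finite loss."""

    def __init__(self, message: str, epoch: int | None = None):
        super().__init__(message)
        self.epoch = epoch


class UndefinedMetricError(TcncallError, ValueError):
    """A metric is undefined for the given data (e.g. absent class for AUC)."""


class InvalidInputError(TcncallError, ValueError):
    """Runtime input does not match the model or pairing contract."""


class InvalidStateError(TcncallError, RuntimeError):
    """Internal configuration is inconsistent (e.g. channel mismatch)."""


class ConfigError(TcncallError, ValueError):
    """A configuration object failed validation."""
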