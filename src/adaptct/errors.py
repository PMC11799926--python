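"""Exception hierarchy for the toolkit."""


class AdaptCTError(Exception):
    """Base class for all toolkit errors."""


class ConfigurationError(AdaptCTError, ValueError):
    """Invalid specification, architecture or training configuration."""


class DegenerateInputError(AdaptCTError, ValueError):
    """Input is structurally valid but degenerate (empty mask, zero variance, ...)."""


class GridMismatchError(AdaptCTError, ValueError):
    """Two volumes that must share a grid do not."""


class RegistrationError(AdaptCTError, RuntimeError):
    """Rigid registration could not produce an acceptable alignment."""


class TrainingDivergedError(AdaptCTError, RuntimeError):
    """Loss became non-finite during optimization."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"training diverged (non-finite loss) at epoch {epoch}")


class ModelStateError(AdaptCTError, RuntimeError):
    """Operation requires a trained or loaded model."""
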