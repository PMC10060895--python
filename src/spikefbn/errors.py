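"""Exception hierarchy shared by all stages of the pipeline."""


class SpikeFBNError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(SpikeFBNError, ValueError):
    """An invalid parameter value or combination."""


class FormatError(SpikeFBNError, ValueError):
    """A file could not be parsed as the requested format."""


class MontageError(SpikeFBNError, ValueError):
    """A montage derivation is impossible (missing or unknown electrode)."""


class CapacityError(SpikeFBNError, ValueError):
    """Requested event count does not fit the recording at the required spacing."""


class TemplateError(SpikeFBNError, ValueError):
    """A matching template is degenerate (all zero) or missing."""


class LandmarkError(SpikeFBNError, ValueError):
    """A frame has no resolvable apex/trough landmarks."""


class UndefinedPhaseError(SpikeFBNError, ValueError):
    """Instantaneous phase is undefined (all-zero signal)."""


class InsufficientDataError(SpikeFBNError, ValueError):
    """A segment is shorter than one analysis window."""


class DisconnectedNetworkError(SpikeFBNError, ValueError):
    """Characteristic path length is undefined on a disconnected graph."""


class ClassBalanceError(SpikeFBNError, ValueError):
    """A dataset operation requires both classes to be present."""


class TrainingDivergenceError(SpikeFBNError, RuntimeError):
    """Training loss became non-finite."""

    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(f"training loss became non-finite at epoch {epoch}")
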