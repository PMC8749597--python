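"""Exception taxonomy shared across the pipeline stages."""


class CamImuError(Exception):
    """Base class for all camimu errors."""


class UnreachableTargetError(CamImuError, ValueError):
    """A reach target lies outside the two-segment arm's workspace."""


class InsufficientLengthError(CamImuError, ValueError):
    """A time series is too short for the requested operation."""


class ProjectionError(CamImuError, ValueError):
    """A joint cannot be projected (e.g. it lies behind the camera)."""


class MissingDepthError(CamImuError, ValueError):
    """No valid point-cloud depth found around a joint's pixel location."""


class FeatureError(CamImuError, ValueError):
    """A per-frame feature vector cannot be formed (missing joint, bad shape)."""


class EmptyDatasetError(CamImuError, ValueError):
    """Windowing produced no supervised examples."""


class ShapeError(CamImuError, ValueError):
    """Input dimensionality does not match a model's specification."""


class DivergenceError(CamImuError, RuntimeError):
    """Training loss became non-finite."""

    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(f"training diverged (non-finite loss) at epoch {epoch}")


class ConfigError(CamImuError, ValueError):
    """An experiment or model configuration is invalid."""


class AlignmentError(CamImuError, ValueError):
    """Two series that must be frame-aligned have different lengths."""
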