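"""Exception hierarchy shared across the package."""


class WallMotionError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(WallMotionError, ValueError):
    """A configuration value or function argument is out of its valid range."""


class InvalidInputError(WallMotionError, ValueError):
    """Input data violates a structural precondition (shape, dtype, metadata)."""


class EmptyROIError(WallMotionError):
    """The end-diastole minus end-systole subtraction left no voxels."""


class EmptyVAMaskError(WallMotionError):
    """The union of end-diastolic segmentations is empty."""


class DegenerateSignalError(WallMotionError):
    """A signal has no usable energy (all-zero or constant where variation is required)."""


class ConfigError(WallMotionError, ValueError):
    """A run configuration failed schema validation."""
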