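"""Exception hierarchy shared across the package.

The CLI maps these onto distinct exit codes (config = 2, I/O = 3,
validation = 4), so keep the split between configuration problems,
file problems and bad runtime inputs.
"""


class DeskewError(Exception):
    """Base class for all package errors."""


class GeometryError(DeskewError, ValueError):
    """Invalid acquisition geometry or view parameters."""


class ConfigError(DeskewError, ValueError):
    """Malformed or inconsistent run configuration."""


class ValidationError(DeskewError, ValueError):
    """Runtime input rejected (shape mismatch, bad band, bad layout...)."""


class StateError(DeskewError, RuntimeError):
    """Operation not legal in the current pipeline state (e.g. double warp)."""


class IOFormatError(DeskewError, OSError):
    """File could not be read or written in the expected format."""


class MeasurementError(DeskewError, ValueError):
    """A quantitative measurement on an image could not be made."""
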