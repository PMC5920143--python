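"""Exception types shared across the package."""


class AmputeBiasError(Exception):
    """Base class for package errors."""


class ParameterError(AmputeBiasError, ValueError):
    """A specification or function argument violates its invariants."""


class ConfigError(AmputeBiasError, ValueError):
    """A configuration file fails schema validation.

    ``field_path`` locates the offending entry, e.g. ``"mechanisms[1].loss_rate"``.
    """

    def __init__(self, message: str, field_path: str = ""):
        self.field_path = field_path
        super().__init__(f"{field_path}: {message}" if field_path else message)


class DegenerateSegmentationError(AmputeBiasError, ValueError):
    """Percentile segmentation is impossible (e.g. a constant column)."""


class InfeasiblePlanError(AmputeBiasError, ValueError):
    """A deletion plan asks for more cases than a stratum (or group) holds."""


class InestimableTermError(AmputeBiasError, ValueError):
    """A model term cannot be estimated, typically because a design cell is empty."""

    def __init__(self, message: str, cell=None):
        self.cell = cell
        super().__init__(message)


class UndefinedBiasError(AmputeBiasError, ZeroDivisionError):
    """Percentage bias is undefined because the complete-data reference is zero."""
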