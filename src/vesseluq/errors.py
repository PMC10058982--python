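"""Exception and warning types shared across the package."""


class VesselUQError(Exception):
    """Base class for all package-specific errors."""


class DegenerateInputError(VesselUQError, ValueError):
    """Input curve carries no usable signal (e.g. constant or falling flow)."""


class WindowTooSmallError(VesselUQError, ValueError):
    """Fewer than the minimum number of samples qualify for a fit window."""


class DegenerateFitError(VesselUQError, ValueError):
    """Regression is undefined, e.g. zero variance of the regressor."""


class NonPhysicalSlopeError(VesselUQError, ValueError):
    """QA-loop slope is non-positive; wrong window or corrupted data."""


class ZeroDeformationError(VesselUQError, ValueError):
    """Area trace has no excursion, so relative area change is undefined."""


class ConfigurationError(VesselUQError, ValueError):
    """Model configuration is missing a key or holds a non-physical value."""


class InstabilityError(VesselUQError, RuntimeError):
    """Time integration diverged; a smaller step is required."""


class UnknownLabelError(VesselUQError, KeyError):
    """Requested cross-section label does not exist in the result."""


class ParseError(VesselUQError, ValueError):
    """A data file does not conform to the documented schema."""


class ConvergenceWarning(UserWarning):
    """Statistical-quality warning (periodicity or gPC truncation)."""


class UnitSanityWarning(UserWarning):
    """A value is far outside the physiological range for its unit."""
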