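"""Exception hierarchy for spharray.

All package-specific failures derive from :class:`SpharrayError` so callers can
catch one base class at batch level and keep going on a per-image basis.
"""


class SpharrayError(Exception):
    """Base class for all spharray errors."""


class InvalidParameterError(SpharrayError, ValueError):
    """A parameter is outside its documented domain."""


class SingularStainSystemError(SpharrayError, ValueError):
    """Stain vectors are zero or collinear; the 3x3 unmixing system is singular."""


class DimensionError(SpharrayError, ValueError):
    """Raster shapes do not match the operation's contract."""


class DegenerateBlankError(SpharrayError, ValueError):
    """Blank/flat-field image contains zeros after smoothing."""


class DegenerateThresholdError(SpharrayError, ValueError):
    """Automatic thresholding on a constant-valued map; use a fixed threshold."""


class NoTissueError(SpharrayError, ValueError):
    """Tissue mask is empty; the percent-positive ratio is undefined."""


class NoNucleiError(SpharrayError, ValueError):
    """No nuclei detected in the denominator channel."""


class CalibrationError(SpharrayError, ValueError):
    """A physical-unit parameter was given without a pixel-size calibration."""


class NoDataError(SpharrayError, ValueError):
    """An empty collection where at least one element is required."""


class UndefinedSeparationError(SpharrayError, ValueError):
    """Sample and control medians coincide; Z' is undefined."""


class FitFailureError(SpharrayError, RuntimeError):
    """Dose-response fit failed to converge or the data are degenerate.

    Carries a ``diagnostics`` dict with whatever the optimiser reported.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class CapacityError(SpharrayError, ValueError):
    """Requested spots exceed the array layout capacity."""


class LayoutConfigError(SpharrayError, ValueError):
    """Array layout geometry is degenerate (e.g. non-positive pitch)."""


class FixtureSpecError(SpharrayError, ValueError):
    """A synthetic-fixture specification is internally inconsistent."""
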