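"""Exception types raised across the pipeline.

Stride-level data problems (gaps, uncorrectable frames) are flags on the
returned objects, not exceptions: a bad stride is excluded from summaries
with a logged reason while the rest of the study keeps processing.
"""


class SuspendkinError(Exception):
    """Base class for all package errors."""


class CalibrationDegenerateError(SuspendkinError):
    """Control points cannot determine the 11 DLT coefficients
    (fewer than 6 correspondences, or coplanar 3D points)."""


class ProjectionSingularError(SuspendkinError):
    """3D point lies on the camera plane: DLT denominator is ~0."""


class EmptyTrajectoryError(SuspendkinError):
    """No frame has the >= 2 valid camera views triangulation needs."""


class DirectionUndefinedError(SuspendkinError):
    """Travel direction cannot be inferred: zero net fore-aft displacement."""


class FitInfeasibleError(SuspendkinError):
    """Too few valid samples to fit the smoothing spline."""


class WindowRangeError(SuspendkinError):
    """Requested evaluation window lies outside the fitted frame range."""


class InfeasibleProfileError(SuspendkinError):
    """Prescribed angle profiles have no limb-chain solution
    (e.g. |cos| > 1 geometry)."""


class EmptyOverlapError(SuspendkinError):
    """Factor levels share no overlapping speed range."""


class StrideExcludedError(SuspendkinError):
    """Stride cannot be summarized (invalid frames span an event window,
    or a required event is missing)."""
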