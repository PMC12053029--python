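"""Camera calibration, triangulation, and beam-frame axis standardization.

Cameras are modeled with the classical 11-parameter direct linear
transformation (DLT): for a 3D point (x, y, z) in the beam coordinate
system the image position is

    u = (L1 x + L2 y + L3 z + L4) / (L9 x + L10 y + L11 z + 1)
    v = (L5 x + L6 y + L7 z + L8) / (L9 x + L10 y + L11 z + 1)

Coefficients are solved by linear least squares from >= 6 non-coplanar
control points with known beam-frame coordinates.  Reconstruction of a
digitized marker stacks the two linear equations contributed by every
camera that saw the frame and solves for (x, y, z); frames seen by fewer
than two cameras are masked invalid rather than raising.

The beam coordinate system has its origin at the midpoint of the runway
beam's central axis, x along the beam (fore-aft), y mediolateral and z
vertical (up).  Left- and right-side camera pairs form separate systems
that are never merged; each stride is standardized so that positive x is
the direction of travel, flipping x and y together to keep the frame
right-handed with z fixed up.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    CalibrationDegenerateError,
    DirectionUndefinedError,
    EmptyTrajectoryError,
    ProjectionSingularError,
)

logger = logging.getLogger(__name__)

#: marker names ordered proximal-most to distal-most, forelimb then hindlimb
FORELIMB_MARKERS = ("shoulder", "elbow", "wrist")
HINDLIMB_MARKERS = ("hip", "knee", "ankle")
DYNAMIC_MARKERS = FORELIMB_MARKERS + HINDLIMB_MARKERS

_DENOM_EPS = 1e-12
_COPLANAR_RTOL = 1e-8


@dataclass
class CameraDLT:
    """One calibrated camera view: 11 DLT coefficients plus bookkeeping."""

    camera_id: str
    coefficients: np.ndarray            # shape (11,)
    image_size: tuple[int, int] = (1920, 1080)
    rms_reprojection_error: float = 0.0

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (11,):
            raise ValueError("a DLT camera has exactly 11 coefficients")
        if self.rms_reprojection_error < 0:
            raise ValueError("rms_reprojection_error must be >= 0")


@dataclass
class ControlPointSet:
    """Calibration correspondences: beam-frame 3D points and, per camera,
    their digitized pixel positions (NaN where a camera did not see one)."""

    points3d: np.ndarray                      # (n, 3) meters
    points2d: dict[str, np.ndarray]           # camera_id -> (n, 2) pixels

    def __post_init__(self) -> None:
        self.points3d = np.asarray(self.points3d, dtype=float)
        self.points2d = {k: np.asarray(v, dtype=float) for k, v in self.points2d.items()}


@dataclass
class BeamFrame:
    """Right-handed beam coordinate frame with the travel-direction sign."""

    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    x_axis: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    y_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))
    z_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    travel_sign: int = 1


@dataclass
class MarkerTrajectory:
    """Per-marker time series of reconstructed 3D positions."""

    marker_id: str
    frames: np.ndarray                  # (n,) strictly increasing ints
    position: np.ndarray                # (n, 3) meters; NaN where invalid
    valid: np.ndarray                   # (n,) bool
    reconstruction_residual: np.ndarray | None = None   # (n,) pixels
    frame_rate: float = 60.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.position = np.asarray(self.position, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("frame indices must be strictly increasing")
        if not np.all(np.isfinite(self.position[self.valid])):
            raise ValueError("position must be finite wherever valid")


# ---------------------------------------------------------------------------
# calibration


def _check_noncoplanar(points3d: np.ndarray) -> None:
    centered = points3d - points3d.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[0] == 0 or s[2] / s[0] < _COPLANAR_RTOL:
        raise CalibrationDegenerateError(
            "control points are (near-)coplanar; DLT calibration is rank-deficient"
        )


def dlt_calibrate(
    control: ControlPointSet,
    camera_id: str,
    image_size: tuple[int, int] = (1920, 1080),
) -> CameraDLT:
    """Solve the 11 DLT coefficients for one camera by least squares.

    Raises :class:`CalibrationDegenerateError` for < 6 usable
    correspondences or coplanar control points.
    """
    uv = control.points2d[camera_id]
    ok = np.all(np.isfinite(uv), axis=1)
    xyz = control.points3d[ok]
    uv = uv[ok]
    n = len(xyz)
    if n < 6:
        raise CalibrationDegenerateError(
            f"camera {camera_id!r}: {n} correspondences, need >= 6"
        )
    _check_noncoplanar(xyz)

    a = np.zeros((2 * n, 11))
    b = np.empty(2 * n)
    x, y, z = xyz.T
    u, v = uv.T
    a[0::2, 0:3] = xyz
    a[0::2, 3] = 1.0
    a[0::2, 8:11] = -u[:, None] * xyz
    a[1::2, 4:7] = xyz
    a[1::2, 7] = 1.0
    a[1::2, 8:11] = -v[:, None] * xyz
    b[0::2] = u
    b[1::2] = v
    coeffs, *_ = np.linalg.lstsq(a, b, rcond=None)

    cam = CameraDLT(camera_id=camera_id, coefficients=coeffs, image_size=image_size)
    proj = dlt_project(cam, xyz)
    cam.rms_reprojection_error = float(np.sqrt(np.mean(np.sum((proj - uv) ** 2, axis=1))))
    return cam


def dlt_project(cam: CameraDLT, p3d: np.ndarray) -> np.ndarray:
    """Project 3D point(s) to pixels with the DLT rational form.

    Accepts a single (3,) point or an (n, 3) array; raises
    :class:`ProjectionSingularError` if any point lies on the camera plane.
    """
    p = np.atleast_2d(np.asarray(p3d, dtype=float))
    L = cam.coefficients
    denom = p @ L[8:11] + 1.0
    if np.any(np.abs(denom) < _DENOM_EPS):
        raise ProjectionSingularError(
            f"camera {cam.camera_id!r}: point on the camera plane (denominator ~ 0)"
        )
    u = (p @ L[0:3] + L[3]) / denom
    v = (p @ L[4:7] + L[7]) / denom
    out = np.stack([u, v], axis=1)
    return out[0] if np.ndim(p3d) == 1 else out


def _reconstruct_frame(
    cams: list[CameraDLT], uvs: np.ndarray
) -> tuple[np.ndarray, float]:
    """Triangulate one frame from >= 2 cameras; returns (p3d, rms residual px)."""
    rows = []
    rhs = []
    for cam, (u, v) in zip(cams, uvs):
        L = cam.coefficients
        rows.append(L[0:3] - u * L[8:11])
        rhs.append(u - L[3])
        rows.append(L[4:7] - v * L[8:11])
        rhs.append(v - L[7])
    a = np.array(rows)
    b = np.array(rhs)
    p3d, *_ = np.linalg.lstsq(a, b, rcond=None)
    err = np.array([dlt_project(cam, p3d) - uv for cam, uv in zip(cams, uvs)])
    residual = float(np.sqrt(np.mean(np.sum(err ** 2, axis=1))))
    return p3d, residual


def dlt_reconstruct(
    cameras: dict[str, CameraDLT],
    observations: dict[str, np.ndarray],
    marker_id: str = "marker",
    frame_rate: float = 60.0,
) -> MarkerTrajectory:
    """Triangulate a marker's per-frame 2D observations into 3D.

    ``observations`` maps camera_id to an (n_frames, 2) pixel array with
    NaN for occluded frames.  Frames with fewer than two valid views are
    returned masked invalid; if *no* frame has two views an
    :class:`EmptyTrajectoryError` is raised.
    """
    if len(cameras) < 2:
        raise EmptyTrajectoryError("triangulation needs >= 2 cameras")
    cam_ids = [cid for cid in cameras if cid in observations]
    obs = np.stack([observations[cid] for cid in cam_ids], axis=0)  # (ncam, n, 2)
    n_frames = obs.shape[1]
    ok = np.all(np.isfinite(obs), axis=2)                           # (ncam, n)

    position = np.full((n_frames, 3), np.nan)
    residual = np.full(n_frames, np.nan)
    valid = np.zeros(n_frames, dtype=bool)
    for i in range(n_frames):
        use = np.flatnonzero(ok[:, i])
        if len(use) < 2:
            continue
        cams = [cameras[cam_ids[j]] for j in use]
        position[i], residual[i] = _reconstruct_frame(cams, obs[use, i])
        valid[i] = True
    if not valid.any():
        raise EmptyTrajectoryError(
            f"marker {marker_id!r}: no frame observed by >= 2 cameras"
        )
    return MarkerTrajectory(
        marker_id=marker_id,
        frames=np.arange(n_frames),
        position=position,
        valid=valid,
        reconstruction_residual=residual,
        frame_rate=frame_rate,
    )


# ---------------------------------------------------------------------------
# axis standardization


def _proximal_most(trajectories: dict[str, MarkerTrajectory]) -> MarkerTrajectory:
    for name in ("shoulder", "hip", "elbow", "knee", "wrist", "ankle"):
        if name in trajectories:
            return trajectories[name]
    return next(iter(trajectories.values()))


def standardize_axes(
    trajectories: dict[str, MarkerTrajectory],
    beam: BeamFrame | None = None,
    window: tuple[int, int] | None = None,
) -> tuple[dict[str, MarkerTrajectory], BeamFrame]:
    """Orient the beam frame so positive x is the direction of travel.

    The travel sign is the sign of the net fore-aft displacement of the
    proximal-most marker (optionally restricted to a frame ``window``).
    A negative sign flips x and y together (180 deg rotation about z),
    preserving right-handedness with z up.  Applying the function twice
    is a no-op.
    """
    beam = beam or BeamFrame()
    ref = _proximal_most(trajectories)
    sel = ref.valid.copy()
    if window is not None:
        sel &= (ref.frames >= window[0]) & (ref.frames <= window[1])
    xs = ref.position[sel, 0]
    if len(xs) < 2 or abs(xs[-1] - xs[0]) < 1e-12:
        raise DirectionUndefinedError(
            f"marker {ref.marker_id!r}: zero net fore-aft displacement"
        )
    sign = 1 if xs[-1] > xs[0] else -1
    out_beam = replace(beam, travel_sign=beam.travel_sign * sign)
    if sign == 1:
        return dict(trajectories), out_beam
    flipped = {}
    for name, tr in trajectories.items():
        pos = tr.position.copy()
        pos[:, 0] *= -1.0
        pos[:, 1] *= -1.0
        flipped[name] = replace(tr, position=pos)
    logger.debug("standardize_axes: flipped x/y for travel direction")
    return flipped, out_beam
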