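"""Trajectory smoothing, the gap-interpolation rule, and stride speed.

Raw reconstructed marker paths are fit, coordinate by coordinate, with a
quintic smoothing spline whose total squared deviation from the valid
samples is bounded by a tolerance (default 0.5 cm^2 per marker, shared
equally across the three coordinates).  The fitted spline also supplies
positions for occluded frames, but only if every gap inside the support
phase is <= 10% of the support duration; a longer gap flags the stride
``gap_exceeded`` and it is excluded from summaries rather than silently
filled.  Stride speed is the mean of the spline's analytic first
derivative (fore-aft component) for the proximal-most marker over the
support window -- never a finite difference of raw samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import UnivariateSpline

from .errors import FitInfeasibleError, WindowRangeError
from .geometry import MarkerTrajectory

logger = logging.getLogger(__name__)

_SPLINE_ORDER = 5


@dataclass
class SmoothingConfig:
    """Smoothing-spline settings.

    tolerance_cm2
        Budget for the sum over valid frames of squared 3D residuals, in
        cm^2 (0.5 by default).
    max_gap_fraction
        Longest tolerated occlusion run inside the support phase, as a
        fraction of support duration (0.10 by default); longer gaps flag
        the stride.
    edge_buffer_frames
        Frames beyond [TD, LO] included in the fit so event frames are
        not evaluated at the spline boundary.
    """

    tolerance_cm2: float = 0.5
    max_gap_fraction: float = 0.10
    spline_order: int = _SPLINE_ORDER
    edge_buffer_frames: int = 5

    def __post_init__(self) -> None:
        if self.tolerance_cm2 <= 0:
            raise ValueError("tolerance must be > 0")
        if not 0 <= self.max_gap_fraction < 1:
            raise ValueError("max_gap_fraction must be in [0, 1)")
        if self.spline_order != _SPLINE_ORDER:
            raise ValueError("only the quintic (order 5) spline is supported")


@dataclass
class SmoothedTrajectory:
    """Spline-smoothed marker path evaluated at every frame in its window."""

    marker_id: str
    frames: np.ndarray                    # (n,) ints, contiguous
    position: np.ndarray                  # (n, 3) m
    velocity: np.ndarray                  # (n, 3) m/s, analytic derivative
    interpolated: np.ndarray              # (n,) bool: frame had no valid sample
    source_valid_fraction: float
    gap_exceeded: bool = False
    frame_rate: float = 60.0
    splines: tuple = field(default=(), repr=False)

    def window_slice(self, first: int, last: int) -> slice:
        if first < self.frames[0] or last > self.frames[-1]:
            raise WindowRangeError(
                f"window [{first}, {last}] outside fitted range "
                f"[{self.frames[0]}, {self.frames[-1]}]"
            )
        i0 = int(np.searchsorted(self.frames, first))
        return slice(i0, i0 + (last - first) + 1)


def _error_allowance(y: np.ndarray, budget: float) -> float:
    """Squared-error allowance for one coordinate's spline fit.

    The configured tolerance is a hard budget, never exceeded; but
    spending it in full would deliberately distort samples that carry
    less noise than the budget allows.  The allowance is therefore the
    expected squared error of the samples themselves -- n * sigma^2 with
    sigma estimated from third differences (variance 20 sigma^2 for
    white noise; smooth 60 Hz limb motion contributes ~1e-4 m, i.e.
    negligibly, to a third difference) -- capped at the budget.
    Noiseless samples get a (near-)interpolating spline.
    """
    n = len(y)
    if n < 4:
        return budget
    d3 = np.diff(y, n=3)
    # median-based scale: robust to a handful of outlying differences
    # (e.g. where tracking resumes after a gap); for white noise
    # d3 ~ N(0, 20 sigma^2) and median|d3| = 0.6745 * sqrt(20) * sigma
    sigma = float(np.median(np.abs(d3))) / (0.6745 * np.sqrt(20.0))
    allowance = min(budget, n * sigma**2)
    # below numerical noise, ask for an interpolating spline outright
    # rather than sending FITPACK chasing an unreachable tiny residual
    return 0.0 if allowance < 1e-16 else allowance


def _longest_invalid_run(valid: np.ndarray) -> int:
    worst = run = 0
    for ok in valid:
        run = 0 if ok else run + 1
        worst = max(worst, run)
    return worst


def fit_smoothing_spline(
    traj: MarkerTrajectory,
    cfg: SmoothingConfig,
    support: tuple[int, int],
) -> SmoothedTrajectory:
    """Fit per-coordinate quintic smoothing splines over one support phase.

    ``support`` is the (TD, LO) frame pair.  Fitting uses valid samples in
    [TD - buffer, LO + buffer]; the returned trajectory is evaluated at
    every frame of that window.  Gap checking applies inside [TD, LO]
    only.
    """
    td, lo = support
    if lo <= td:
        raise ValueError("support must satisfy TD < LO")
    valid_frames = traj.frames[traj.valid]
    if len(valid_frames) == 0:
        raise FitInfeasibleError(f"marker {traj.marker_id!r}: no valid samples")
    # never evaluate beyond the outermost samples: polynomial extrapolation
    # of a quintic is unbounded, so the window is the buffered support
    # clipped to the span the digitizer actually covered
    first = max(int(valid_frames[0]), td - cfg.edge_buffer_frames)
    last = min(int(valid_frames[-1]), lo + cfg.edge_buffer_frames)
    in_window = (traj.frames >= first) & (traj.frames <= last)
    frames = traj.frames[in_window]
    pos = traj.position[in_window]
    valid = traj.valid[in_window]

    n_valid = int(valid.sum())
    if n_valid < cfg.spline_order + 1:
        raise FitInfeasibleError(
            f"marker {traj.marker_id!r}: {n_valid} valid samples, "
            f"need >= {cfg.spline_order + 1}"
        )

    # gap rule: longest occlusion run strictly inside [TD, LO]
    in_support = (frames >= td) & (frames <= lo)
    support_frames = np.arange(td, lo + 1)
    support_valid = np.zeros(len(support_frames), dtype=bool)
    support_valid[np.searchsorted(support_frames, frames[in_support & valid])] = True
    gap_limit = cfg.max_gap_fraction * (lo - td + 1)
    longest_gap = _longest_invalid_run(support_valid)
    gap_exceeded = longest_gap > gap_limit
    if gap_exceeded:
        logger.warning(
            "marker %s: gap of %d frames exceeds %.1f-frame limit "
            "(%.0f%% of %d-frame support)",
            traj.marker_id, longest_gap, gap_limit,
            100 * cfg.max_gap_fraction, lo - td + 1,
        )

    t = frames[valid] / traj.frame_rate
    budget_per_coord = cfg.tolerance_cm2 * 1e-4 / 3.0  # cm^2 -> m^2, split x/y/z
    splines = tuple(
        UnivariateSpline(
            t, pos[valid, axis], k=cfg.spline_order,
            s=_error_allowance(pos[valid, axis], budget_per_coord),
        )
        for axis in range(3)
    )
    out_frames = np.arange(first, last + 1)
    tt = out_frames / traj.frame_rate
    position = np.stack([sp(tt) for sp in splines], axis=1)
    velocity = np.stack([sp.derivative()(tt) for sp in splines], axis=1)

    had_sample = np.isin(out_frames, frames[valid])
    return SmoothedTrajectory(
        marker_id=traj.marker_id,
        frames=out_frames,
        position=position,
        velocity=velocity,
        interpolated=~had_sample,
        source_valid_fraction=n_valid / len(out_frames),
        gap_exceeded=gap_exceeded,
        frame_rate=traj.frame_rate,
        splines=splines,
    )


def compute_speed(
    smoothed: SmoothedTrajectory,
    window: tuple[int, int],
    component: str = "x",
) -> float:
    """Mean spline-derivative speed of a marker over [TD, LO], in m/s.

    ``component='x'`` (default) averages the fore-aft velocity in the
    standardized frame -- locomotor progression speed along the beam.
    ``component='3d'`` averages the full derivative magnitude instead.
    """
    sel = smoothed.window_slice(*window)
    v = smoothed.velocity[sel]
    if component == "x":
        return float(np.mean(v[:, 0]))
    if component == "3d":
        return float(np.mean(np.linalg.norm(v, axis=1)))
    raise ValueError("component must be 'x' or '3d'")
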