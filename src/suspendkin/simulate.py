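"""Forward-kinematic simulator of suspensory limb strides.

Generates ground-truth marker trajectories -- and their synthetic
multi-camera 2D observations -- for a sloth-like quadruped walking
below a horizontal beam, so every pipeline stage can be tested without
video data.

Model of one support phase (one limb, three markers):

* the distal marker (wrist/ankle) grips the beam and stays fixed;
* the limb hangs below: segment unit vectors point from the body up to
  the beam;
* mid-joint angle and whole-limb protraction follow prescribed
  profiles (smooth cosine pieces through the TD / mid-stride / LO
  values), and each segment holds a prescribed constant abduction;
* given those angles and the measured segment lengths, the elbow/knee
  and shoulder/hip positions are solved by two-link inverse kinematics
  frame by frame;
* time is parameterized so the shoulder/hip x position advances
  *linearly* at the realized speed -- the per-support fore-aft advance
  is fixed by the prescribed angles and segment lengths, so the target
  speed is met up to one-frame quantization at 60 Hz and the realized
  value is recorded as the truth.

Because protraction is the sagittal deviation of the limb vector from
vertical, the frame where it crosses zero is exactly where shoulder and
wrist have equal x: mid-stride emerges at the prescribed dip of the
mid-joint profile by construction.

Observation rendering projects true (or skin-slipped) marker positions
through synthetic DLT cameras, adds Gaussian pixel noise, and blanks
random frames.  Skin slip displaces the apparent shoulder/elbow (hip/
knee) positions along their segment axes sinusoidally in time -- the
component the segment-length correction removes exactly; an optional
off-axis term demonstrates the method's residual error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import kinematics
from .correction import SegmentLengths
from .errors import InfeasibleProfileError
from .geometry import CameraDLT, ControlPointSet, dlt_project

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# prescribed limb profiles


@dataclass
class LimbProfile:
    """Prescribed support-phase angle profiles for one limb girdle (deg)."""

    midjoint: tuple[float, float, float]      # TD, mid-stride dip, LO
    protraction: tuple[float, float]          # TD, LO
    prox_abduction: float
    dist_abduction: float


#: study-condition defaults: forelimb elbow 137 -> 102 -> 105 with
#: protraction +30 -> -20; hindlimb knee 148 -> 126 -> 148 with
#: protraction +21 -> -38; arm/thigh abducted, forearm/leg adducted.
FORE_PROFILE = LimbProfile((137.0, 102.0, 105.0), (30.0, -20.0), 4.2, -18.0)
HIND_PROFILE = LimbProfile((148.0, 126.0, 148.0), (21.0, -38.0), 2.7, -18.2)

GIRDLE_MARKERS = {
    "fore": ("shoulder", "elbow", "wrist"),
    "hind": ("hip", "knee", "ankle"),
}


@dataclass
class SimulationParams:
    """Study-shaped dataset settings (defaults emulate the experiment:
    4 individuals, 44 fore + 40 hind strides, 60 Hz, 4 cameras)."""

    n_individuals: int = 4
    strides_per_individual: tuple[int, int] = (11, 10)     # fore, hind
    strides_per_trial: int = 2
    speed_range: tuple[float, float] = (0.05, 0.5)         # m/s
    frame_rate: float = 60.0
    # segment-length draw ranges, cm
    arm_range: tuple[float, float] = (16.0, 18.5)
    forearm_range: tuple[float, float] = (16.5, 18.5)
    thigh_range: tuple[float, float] = (9.75, 12.5)
    leg_range: tuple[float, float] = (10.0, 13.5)
    fore_profile: LimbProfile = field(default_factory=lambda: FORE_PROFILE)
    hind_profile: LimbProfile = field(default_factory=lambda: HIND_PROFILE)
    # biological variation, deg
    individual_sd: float = 2.5
    trial_sd: float = 1.5
    angle_jitter_sd: float = 4.0
    # observation model
    pixel_noise_sd: float = 0.5               # px
    skin_slip_amplitude: float = 0.01         # m, along-segment
    skin_slip_frequency: float = 1.0          # cycles per support phase
    skin_slip_off_axis: float = 0.0           # m, perpendicular component
    missing_rate: float = 0.02                # per frame/marker/camera
    edge_pad_frames: int = 5                  # digitized frames beyond TD/LO
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_noise_sd < 0 or self.missing_rate < 0:
            raise ValueError("noise levels and rates must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth for one simulated stride."""

    girdle: str
    side: str
    individual: str
    trial: str
    stride_id: str
    frame_rate: float
    frames: np.ndarray                       # local 0..n-1
    positions: dict[str, np.ndarray]         # marker -> (n, 3) m
    events: kinematics.StrideEvents
    speed: float                             # realized, exact
    event_angles: dict[str, float]           # '<var>_<event>' -> deg
    excursion: float
    prescribed: LimbProfile
    lengths: SegmentLengths

    @property
    def marker_names(self) -> tuple[str, str, str]:
        return GIRDLE_MARKERS[self.girdle]


# ---------------------------------------------------------------------------
# profile evaluation and inverse kinematics


def _midjoint_of_s(s: np.ndarray, g_td: float, g_ms: float, g_lo: float,
                   s_ms: float) -> np.ndarray:
    """C1 two-piece cosine through (0, TD), (s_ms, dip), (1, LO)."""
    s = np.asarray(s, dtype=float)
    first = g_ms + 0.5 * (g_td - g_ms) * (1 + np.cos(np.pi * np.clip(s, 0, s_ms) / s_ms))
    second = g_ms + 0.5 * (g_lo - g_ms) * (
        1 - np.cos(np.pi * (np.clip(s, s_ms, 1) - s_ms) / (1 - s_ms))
    )
    return np.where(s <= s_ms, first, second)


def _protraction_of_s(s: np.ndarray, p_td: float, p_lo: float) -> np.ndarray:
    return p_td + (p_lo - p_td) * np.asarray(s, dtype=float)


def _midstride_s(p_td: float, p_lo: float) -> float:
    if p_td > 0 > p_lo:
        return p_td / (p_td - p_lo)
    return 0.5


def _units(alpha: np.ndarray, beta_world: float) -> np.ndarray:
    """Segment unit vectors (n, 3) from sagittal angle alpha (rad) and the
    world-frame coronal angle beta (rad, sign already includes side)."""
    t = np.tan(alpha)
    b = np.full_like(t, np.tan(beta_world))
    v = np.stack([t, b, np.ones_like(t)], axis=1)
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _chain_residual(a_dist, a_prox, theta, gamma, beta_d, beta_p, l_dist, l_prox):
    u_d = _units(a_dist, beta_d)
    u_p = _units(a_prox, beta_p)
    r1 = -np.sum(u_p * u_d, axis=1) - np.cos(gamma)
    delta = l_prox * u_p + l_dist * u_d
    r2 = np.arctan2(delta[:, 0], delta[:, 2]) - theta
    return r1, r2


def solve_chain(
    theta: np.ndarray,
    gamma: np.ndarray,
    beta_dist: float,
    beta_prox: float,
    l_dist: float,
    l_prox: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-link inverse kinematics, vectorized over frames.

    Solves the segments' sagittal angles (rad) so the chain reproduces
    limb protraction ``theta`` and interior mid-joint angle ``gamma``
    exactly, with fixed world-frame coronal angles.  Raises
    :class:`InfeasibleProfileError` when no solution exists.
    """
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    gamma = np.atleast_1d(np.asarray(gamma, dtype=float))
    if np.any(gamma <= 0) or np.any(gamma > np.pi):
        raise InfeasibleProfileError("mid-joint angle must lie in (0, 180] deg")

    # planar initialization (exact for zero abduction): interior triangle
    c = np.sqrt(l_prox**2 + l_dist**2 - 2 * l_prox * l_dist * np.cos(gamma))
    if np.any(c < 1e-9):
        raise InfeasibleProfileError("segments fold onto each other (chord ~ 0)")
    psi_w = np.arcsin(np.clip(l_prox * np.sin(gamma) / c, -1.0, 1.0))
    psi_s = np.arcsin(np.clip(l_dist * np.sin(gamma) / c, -1.0, 1.0))
    a_d = theta + psi_w
    a_p = theta - psi_s

    eps = 1e-7
    for _ in range(60):
        r1, r2 = _chain_residual(a_d, a_p, theta, gamma, beta_dist, beta_prox,
                                 l_dist, l_prox)
        if max(np.abs(r1).max(), np.abs(r2).max()) < 1e-13:
            break
        j11, j21 = _chain_residual(a_d + eps, a_p, theta, gamma, beta_dist,
                                   beta_prox, l_dist, l_prox)
        j12, j22 = _chain_residual(a_d, a_p + eps, theta, gamma, beta_dist,
                                   beta_prox, l_dist, l_prox)
        d11 = (j11 - r1) / eps
        d21 = (j21 - r2) / eps
        d12 = (j12 - r1) / eps
        d22 = (j22 - r2) / eps
        det = d11 * d22 - d12 * d21
        if np.any(np.abs(det) < 1e-14):
            raise InfeasibleProfileError("singular chain Jacobian")
        step_d = (r1 * d22 - r2 * d12) / det
        step_p = (r2 * d11 - r1 * d21) / det
        clip = 0.3
        a_d = a_d - np.clip(step_d, -clip, clip)
        a_p = a_p - np.clip(step_p, -clip, clip)
    else:
        raise InfeasibleProfileError("chain inverse kinematics did not converge")
    if np.any(np.abs(a_d) >= np.pi / 2) or np.any(np.abs(a_p) >= np.pi / 2):
        raise InfeasibleProfileError("segment pitched past horizontal")
    return a_d, a_p


# ---------------------------------------------------------------------------
# one stride


def _chain_positions(s, profile, side_sign, l_dist, l_prox, wrist):
    """Marker positions (prox, mid, dist each (n,3)) at progress values s."""
    s_ms = _midstride_s(*profile.protraction)
    theta = np.radians(_protraction_of_s(s, *profile.protraction))
    gamma = np.radians(_midjoint_of_s(s, *profile.midjoint, s_ms))
    beta_d = side_sign * np.radians(profile.dist_abduction)
    beta_p = side_sign * np.radians(profile.prox_abduction)
    a_d, a_p = solve_chain(theta, gamma, beta_d, beta_p, l_dist, l_prox)
    u_d = _units(a_d, beta_d)
    u_p = _units(a_p, beta_p)
    dist = np.broadcast_to(wrist, (len(s), 3)).copy()
    mid = dist - l_dist * u_d
    prox = mid - l_prox * u_p
    return prox, mid, dist


def simulate_stride(
    girdle: str,
    side: str,
    lengths: SegmentLengths,
    speed: float,
    profile: LimbProfile | None = None,
    frame_rate: float = 60.0,
    individual: str = "BV1",
    trial: str = "T1",
    stride_id: str = "s1",
    wrist_x: float = 0.0,
) -> SyntheticTruth:
    """Simulate one noiseless support phase by forward kinematics.

    ``speed`` is the target progression speed; the realized speed (one
    60 Hz frame-count quantum away at most) is stored in the returned
    truth and achieved exactly: the proximal marker's x advances
    linearly in time.
    """
    if girdle not in GIRDLE_MARKERS:
        raise ValueError("girdle must be 'fore' or 'hind'")
    profile = profile or (FORE_PROFILE if girdle == "fore" else HIND_PROFILE)
    l_dist, l_prox = lengths.for_girdle(girdle)
    side_sign = 1.0 if side == "left" else -1.0
    wrist = np.array([wrist_x, side_sign * 0.04, -0.02])

    def advance(s: np.ndarray) -> np.ndarray:
        prox, _, dist = _chain_positions(np.atleast_1d(s), profile, side_sign,
                                         l_dist, l_prox, wrist)
        x_prox = prox[:, 0]
        return x_prox - x_prox0

    prox0, _, _ = _chain_positions(np.array([0.0]), profile, side_sign,
                                   l_dist, l_prox, wrist)
    x_prox0 = prox0[0, 0]
    total = float(advance(np.array([1.0]))[0])
    if total <= 0:
        raise InfeasibleProfileError("profiles imply no forward progression")
    n = max(10, int(round(total * frame_rate / speed)) + 1)
    v_real = total * frame_rate / (n - 1)

    # invert advance(s) so shoulder/hip x is linear in time
    targets = np.arange(n) * v_real / frame_rate
    s = np.linspace(0.0, 1.0, n)
    eps = 1e-6
    for _ in range(60):
        f = advance(s) - targets
        if np.abs(f).max() < 1e-12:
            break
        slope = (advance(np.clip(s + eps, 0, 1)) - advance(np.clip(s - eps, 0, 1))) / (
            np.clip(s + eps, 0, 1) - np.clip(s - eps, 0, 1)
        )
        s = np.clip(s - f / slope, 0.0, 1.0)
    s[0], s[-1] = 0.0, 1.0

    prox, mid, dist = _chain_positions(s, profile, side_sign, l_dist, l_prox, wrist)
    names = GIRDLE_MARKERS[girdle]
    positions = {names[0]: prox, names[1]: mid, names[2]: dist}

    ms = kinematics.detect_midstride(prox[:, 0], dist[:, 0], 0, n - 1)
    events = kinematics.StrideEvents(td=0, ms=ms, lo=n - 1)
    event_angles: dict[str, float] = {}
    for ev, frame in (("td", 0), ("ms", ms), ("lo", n - 1)):
        i = slice(frame, frame + 1)
        event_angles[f"midjoint_angle_{ev}"] = float(
            kinematics.midjoint_angle(prox[i], mid[i], dist[i])[0]
        )
        event_angles[f"proximal_abduction_{ev}"] = float(
            kinematics.segment_abduction_angle(prox[i], mid[i], side)[0]
        )
        event_angles[f"distal_abduction_{ev}"] = float(
            kinematics.segment_abduction_angle(mid[i], dist[i], side)[0]
        )
        event_angles[f"protraction_{ev}"] = float(
            kinematics.limb_protraction_angle(prox[i], dist[i])[0]
        )
    excursion = event_angles["protraction_td"] - event_angles["protraction_lo"]

    return SyntheticTruth(
        girdle=girdle, side=side, individual=individual, trial=trial,
        stride_id=stride_id, frame_rate=frame_rate, frames=np.arange(n),
        positions=positions, events=events, speed=v_real,
        event_angles=event_angles, excursion=excursion,
        prescribed=profile, lengths=lengths,
    )


# ---------------------------------------------------------------------------
# synthetic cameras


def pinhole_dlt(
    camera_id: str,
    position: np.ndarray,
    target: np.ndarray,
    focal_px: float = 1500.0,
    image_size: tuple[int, int] = (1920, 1080),
) -> CameraDLT:
    """Build exact DLT coefficients for an ideal pinhole camera."""
    position = np.asarray(position, dtype=float)
    z_cam = target - position
    z_cam = z_cam / np.linalg.norm(z_cam)
    up = np.array([0.0, 0.0, 1.0])
    x_cam = np.cross(z_cam, up)
    x_cam /= np.linalg.norm(x_cam)
    y_cam = np.cross(z_cam, x_cam)
    r = np.stack([x_cam, y_cam, z_cam])
    k = np.array(
        [[focal_px, 0, image_size[0] / 2],
         [0, focal_px, image_size[1] / 2],
         [0, 0, 1.0]]
    )
    p = k @ np.hstack([r, (-r @ position)[:, None]])
    p = p / p[2, 3]
    coeffs = np.concatenate([p[0, :], p[1, :], p[2, :3]])
    return CameraDLT(camera_id=camera_id, coefficients=coeffs, image_size=image_size)


def default_camera_rig(side: str) -> dict[str, CameraDLT]:
    """Two cameras per beam side: sagittal and 45-degree diagonal views."""
    s = 1.0 if side == "left" else -1.0
    target = np.array([0.0, 0.0, -0.2])
    return {
        f"{side}_sag": pinhole_dlt(f"{side}_sag", np.array([0.0, s * 2.2, -0.25]), target),
        f"{side}_diag": pinhole_dlt(f"{side}_diag", np.array([1.6, s * 1.6, -0.25]), target),
    }


def default_control_points(side: str) -> ControlPointSet:
    """12 exactly-projected control points spanning the limb workspace."""
    s = 1.0 if side == "left" else -1.0
    xs = (-1.2, 0.0, 1.2)
    ys = (s * 0.02, s * 0.42)
    zs = (-0.55, 0.05)
    pts = np.array([(x, y, z) for x in xs for y in ys for z in zs])
    cams = default_camera_rig(side)
    points2d = {cid: dlt_project(cam, pts) for cid, cam in cams.items()}
    return ControlPointSet(points3d=pts, points2d=points2d)


# ---------------------------------------------------------------------------
# observation rendering


def apparent_positions(
    truth: SyntheticTruth,
    slip_amplitude: float,
    slip_frequency: float,
    slip_phases: tuple[float, float] = (0.5 * np.pi, 0.5 * np.pi),
    off_axis_amplitude: float = 0.0,
) -> dict[str, np.ndarray]:
    """True positions with sinusoidal skin slip on the mid/proximal markers.

    Slip is directed along each segment's axis (proximal marker relative
    to the corrected anchor below it), the component the segment-length
    correction removes; ``off_axis_amplitude`` adds a perpendicular
    component that it cannot.
    """
    names = truth.marker_names
    prox = truth.positions[names[0]]
    mid = truth.positions[names[1]]
    dist = truth.positions[names[2]]
    n = len(truth.frames)
    t = truth.frames / max(n - 1, 1)
    wave_mid = np.sin(2 * np.pi * slip_frequency * t + slip_phases[0])
    wave_prox = np.sin(2 * np.pi * slip_frequency * t + slip_phases[1])

    def unit(v):
        return v / np.linalg.norm(v, axis=1, keepdims=True)

    u_mid = unit(mid - dist)
    u_prox = unit(prox - mid)
    mid_app = mid + slip_amplitude * wave_mid[:, None] * u_mid
    prox_app = prox + slip_amplitude * wave_prox[:, None] * u_prox
    if off_axis_amplitude > 0:
        x_hat = np.array([1.0, 0.0, 0.0])
        w_mid = unit(np.cross(u_mid, x_hat))
        w_prox = unit(np.cross(u_prox, x_hat))
        mid_app = mid_app + off_axis_amplitude * wave_mid[:, None] * w_mid
        prox_app = prox_app + off_axis_amplitude * wave_prox[:, None] * w_prox
    return {names[0]: prox_app, names[1]: mid_app, names[2]: dist.copy()}


def render_observations(
    truth: SyntheticTruth,
    cameras: dict[str, CameraDLT],
    rng: np.random.Generator,
    pixel_noise_sd: float = 0.0,
    slip_amplitude: float = 0.0,
    slip_frequency: float = 1.0,
    off_axis_amplitude: float = 0.0,
    missing_rate: float = 0.0,
    occlusion_burst: tuple[str, int, int] | None = None,
    edge_pad: int = 0,
) -> dict[str, dict[str, np.ndarray]]:
    """Project a stride into per-camera 2D marker observations.

    Returns ``{marker: {camera_id: (n + 2*edge_pad, 2) pixels with NaN
    blanks}}``.  ``edge_pad`` emulates a digitizer tracking the markers
    a few frames before touchdown and after liftoff (positions continued
    linearly), so downstream splines never face a data boundary exactly
    at an event frame.  ``occlusion_burst=(marker, start, stop)`` blanks
    a contiguous support-local frame range in every camera (for gap-rule
    experiments).
    """
    phases = tuple(rng.uniform(0, 2 * np.pi, size=2))
    if slip_amplitude > 0 or off_axis_amplitude > 0:
        apparent = apparent_positions(
            truth, slip_amplitude, slip_frequency, phases, off_axis_amplitude
        )
    else:
        apparent = {m: p.copy() for m, p in truth.positions.items()}
    if edge_pad > 0:
        padded = {}
        for m, p in apparent.items():
            v0 = p[1] - p[0]
            v1 = p[-1] - p[-2]
            pre = p[0] - v0 * np.arange(edge_pad, 0, -1)[:, None]
            post = p[-1] + v1 * np.arange(1, edge_pad + 1)[:, None]
            padded[m] = np.vstack([pre, p, post])
        apparent = padded

    out: dict[str, dict[str, np.ndarray]] = {}
    n = len(truth.frames) + 2 * edge_pad
    for marker, p3d in apparent.items():
        per_cam: dict[str, np.ndarray] = {}
        for cid, cam in cameras.items():
            uv = dlt_project(cam, p3d).astype(float)
            if pixel_noise_sd > 0:
                uv = uv + rng.normal(0.0, pixel_noise_sd, size=uv.shape)
            if missing_rate > 0:
                gone = rng.random(n) < missing_rate
                uv[gone] = np.nan
            if occlusion_burst is not None and occlusion_burst[0] == marker:
                uv[edge_pad + occlusion_burst[1]: edge_pad + occlusion_burst[2] + 1] = np.nan
            per_cam[cid] = uv
        out[marker] = per_cam
    return out


# ---------------------------------------------------------------------------
# study-shaped dataset


def _draw_lengths(params: SimulationParams, individual: str, side: str,
                  rng: np.random.Generator) -> SegmentLengths:
    return SegmentLengths.from_cm(
        individual, side,
        arm=rng.uniform(*params.arm_range),
        forearm=rng.uniform(*params.forearm_range),
        thigh=rng.uniform(*params.thigh_range),
        leg=rng.uniform(*params.leg_range),
    )


def _jitter_profile(profile: LimbProfile, offset: float,
                    jitter: np.ndarray) -> LimbProfile:
    """Shift a profile by a scalar offset plus per-endpoint jitter (deg)."""
    m = profile.midjoint
    p = profile.protraction
    return replace(
        profile,
        midjoint=(m[0] + offset + jitter[0],
                  m[1] + offset + jitter[1],
                  m[2] + offset + jitter[2]),
        protraction=(p[0] + offset + jitter[3], p[1] + offset + jitter[4]),
        prox_abduction=profile.prox_abduction + 0.5 * offset + jitter[5],
        dist_abduction=profile.dist_abduction + 0.5 * offset + jitter[6],
    )


def _clamp_feasible(profile: LimbProfile) -> LimbProfile:
    """Clamp a jittered profile into the chain's feasible region.

    With fixed coronal tilts the interior mid-joint angle cannot exceed
    180 - |beta_dist - beta_prox| deg (segments can never anti-align
    when their y-components differ); keep a small margin, keep the limb
    away from full flexion, and keep protraction monotone TD -> LO.
    """
    ceil = 180.0 - abs(profile.dist_abduction - profile.prox_abduction) - 1.5
    mid = tuple(float(np.clip(g, 25.0, ceil)) for g in profile.midjoint)
    p_td, p_lo = profile.protraction
    p_td = float(np.clip(p_td, -70.0, 70.0))
    p_lo = float(np.clip(p_lo, -70.0, min(70.0, p_td - 15.0)))
    return replace(profile, midjoint=mid, protraction=(p_td, p_lo))


def simulate_study(params: SimulationParams) -> list[dict]:
    """Simulate every stride of a study-shaped dataset.

    Returns a list of records ``{"truth": SyntheticTruth,
    "observations": {...}, "lengths": SegmentLengths, ...}`` grouped by
    trial via the truth metadata; file writing lives in
    :func:`suspendkin.io.write_dataset`.
    """
    rng = np.random.default_rng(params.seed)
    individuals = [f"BV{i + 1}" for i in range(params.n_individuals)]
    lengths = {
        (ind, side): _draw_lengths(params, ind, side, rng)
        for ind in individuals for side in ("left", "right")
    }
    records: list[dict] = []
    for ind in individuals:
        for girdle, n_strides in zip(("fore", "hind"), params.strides_per_individual):
            base = params.fore_profile if girdle == "fore" else params.hind_profile
            ind_offset = rng.normal(0.0, params.individual_sd)
            stride_idx = 0
            trial_no = 0
            while stride_idx < n_strides:
                trial_no += 1
                trial_id = f"{ind}_{girdle}_t{trial_no:02d}"
                side = str(rng.choice(["left", "right"]))
                trial_offset = rng.normal(0.0, params.trial_sd)
                in_trial = min(params.strides_per_trial, n_strides - stride_idx)
                wrist_x = -0.8
                for j in range(in_trial):
                    stride_idx += 1
                    jit = rng.normal(0.0, params.angle_jitter_sd, size=7)
                    jit[5:] *= 0.25         # abduction varies less than flexion
                    profile = _clamp_feasible(
                        _jitter_profile(base, ind_offset + trial_offset, jit)
                    )
                    speed = rng.uniform(*params.speed_range)
                    truth = simulate_stride(
                        girdle, side, lengths[(ind, side)], speed,
                        profile=profile, frame_rate=params.frame_rate,
                        individual=ind, trial=trial_id,
                        stride_id=f"{ind}_{girdle}{stride_idx:02d}",
                        wrist_x=wrist_x,
                    )
                    wrist_x += 0.3      # next contact plants ahead along the beam
                    cameras = default_camera_rig(side)
                    obs = render_observations(
                        truth, cameras, rng,
                        pixel_noise_sd=params.pixel_noise_sd,
                        slip_amplitude=params.skin_slip_amplitude,
                        slip_frequency=params.skin_slip_frequency,
                        off_axis_amplitude=params.skin_slip_off_axis,
                        missing_rate=params.missing_rate,
                        edge_pad=params.edge_pad_frames,
                    )
                    records.append(
                        {"truth": truth, "observations": obs,
                         "lengths": lengths[(ind, side)], "trial": trial_id,
                         "side": side, "girdle": girdle, "individual": ind,
                         "edge_pad": params.edge_pad_frames}
                    )
    return records


# ---------------------------------------------------------------------------
# stats-layer generator (summary-table scale)


def simulate_summary_table(
    n_individuals: int = 4,
    n_strides: int = 80,
    event_effect: float = 0.0,
    speed_slope: float = 0.0,
    baseline: float = 120.0,
    individual_sd: float = 3.0,
    trial_sd: float = 2.0,
    residual_sd: float = 6.0,
    speed_range: tuple[float, float] = (0.1, 0.5),
    strides_per_trial: int = 2,
    rng: np.random.Generator | None = None,
) -> "pd.DataFrame":
    """Generate a long-format stride x event response table directly.

    ``event_effect`` is added at TD only (MS and LO share the baseline);
    ``speed_slope`` is in response units per m/s.  Used for type-I
    calibration and parameter-recovery experiments on the model layer
    without running the geometry pipeline.
    """
    import pandas as pd

    rng = rng or np.random.default_rng(0)
    rows = []
    ind_eff = rng.normal(0.0, individual_sd, size=n_individuals)
    per_ind = [n_strides // n_individuals] * n_individuals
    for i in range(n_strides % n_individuals):
        per_ind[i] += 1
    sidx = 0
    for ind in range(n_individuals):
        trial_counter = 0
        for local in range(per_ind[ind]):
            if local % strides_per_trial == 0:
                trial_counter += 1
                trial_eff = rng.normal(0.0, trial_sd)
            speed = rng.uniform(*speed_range)
            sidx += 1
            for ev in ("td", "ms", "lo"):
                mu = baseline + ind_eff[ind] + trial_eff + speed_slope * speed
                if ev == "td":
                    mu += event_effect
                rows.append(
                    {
                        "individual": f"I{ind + 1}",
                        "trial": f"I{ind + 1}_t{trial_counter}",
                        "stride_id": f"s{sidx}",
                        "speed": speed,
                        "event": ev,
                        "value": mu + rng.normal(0.0, residual_sd),
                    }
                )
    return pd.DataFrame(rows)
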