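"""Joint/segment angle definitions, stride events, and stride summaries.

Angle conventions (all in degrees, computed at exactly the event frames):

mid-joint angle (elbow, knee)
    Interior 3D angle at the mid joint between the proximal and distal
    segments; 180 deg is a fully extended limb, range [0, 180].

limb protraction
    Signed deviation of the limb vector (proximal-most to distal-most
    marker) from vertical, measured in the sagittal (x-z) plane.
    Positive when the distal marker is cranial to the proximal marker
    (protraction), negative when caudal (retraction).  A limb hanging
    vertically below/above its proximal joint scores 0.

segment abduction
    Signed deviation of a segment vector from vertical in the coronal
    (y-z) plane.  Positive when the distal end is lateral to the
    proximal end (abduction), negative when medial (adduction).  The
    mediolateral sign is normalized by limb side (right-side y negated)
    so values are comparable across limbs.

Support-phase events: touchdown (TD) and liftoff (LO) are video-coded
frame indices supplied with the data; mid-stride (MS) is the frame in
[TD, LO] where the fore-aft positions of the proximal-most and
distal-most markers are closest (earliest frame on ties).  Angular
excursion is protraction(TD) - protraction(LO).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .correction import CorrectedChain
from .errors import StrideExcludedError

logger = logging.getLogger(__name__)

_EPS_NORM = 1e-9

EVENTS = ("td", "ms", "lo")
ANGLE_VARS = ("midjoint_angle", "proximal_abduction", "distal_abduction", "protraction")


@dataclass
class StrideEvents:
    """Support-phase event frames for one stride: TD <= MS <= LO."""

    td: int
    ms: int
    lo: int

    def __post_init__(self) -> None:
        if not self.td <= self.ms <= self.lo:
            raise ValueError("events must satisfy TD <= MS <= LO")

    @property
    def support_duration(self) -> int:
        return self.lo - self.td + 1


def midjoint_angle(prox: np.ndarray, mid: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """Interior angle at the mid joint, degrees in [0, 180].

    Vectorized over leading axis; degenerate (zero-length) segments give NaN.
    """
    prox, mid, dist = (np.atleast_2d(np.asarray(a, float)) for a in (prox, mid, dist))
    u = prox - mid
    v = dist - mid
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    bad = (nu < _EPS_NORM) | (nv < _EPS_NORM)
    denom = np.where(bad, 1.0, nu * nv)
    cosang = np.clip(np.sum(u * v, axis=1) / denom, -1.0, 1.0)
    ang = np.degrees(np.arccos(cosang))
    ang[bad] = np.nan
    return ang


def _signed_plane_angle(longitudinal: np.ndarray, vertical: np.ndarray) -> np.ndarray:
    """Signed angle from vertical within a plane: atan2(in-plane, up)."""
    return np.degrees(np.arctan2(longitudinal, vertical))


def segment_abduction_angle(
    seg_prox: np.ndarray, seg_dist: np.ndarray, side: str
) -> np.ndarray:
    """Coronal-plane abduction(+)/adduction(-) of a segment, degrees."""
    seg_prox = np.atleast_2d(np.asarray(seg_prox, float))
    seg_dist = np.atleast_2d(np.asarray(seg_dist, float))
    d = seg_dist - seg_prox
    lateral = d[:, 1] if side == "left" else -d[:, 1]
    proj = np.hypot(lateral, d[:, 2])
    ang = _signed_plane_angle(lateral, d[:, 2])
    ang[proj < _EPS_NORM] = np.nan
    return ang


def limb_protraction_angle(prox_most: np.ndarray, dist_most: np.ndarray) -> np.ndarray:
    """Sagittal-plane protraction(+)/retraction(-) of the limb vector, degrees."""
    prox_most = np.atleast_2d(np.asarray(prox_most, float))
    dist_most = np.atleast_2d(np.asarray(dist_most, float))
    d = dist_most - prox_most
    proj = np.hypot(d[:, 0], d[:, 2])
    ang = _signed_plane_angle(d[:, 0], d[:, 2])
    ang[proj < _EPS_NORM] = np.nan
    return ang


def detect_midstride(
    prox_x: np.ndarray, dist_x: np.ndarray, td: int, lo: int,
    frames: np.ndarray | None = None,
) -> int:
    """Frame in [TD, LO] minimizing |x_prox - x_dist| (earliest on ties)."""
    if not td < lo:
        raise ValueError("detect_midstride requires TD < LO")
    prox_x = np.asarray(prox_x, float)
    dist_x = np.asarray(dist_x, float)
    frames = np.arange(len(prox_x)) if frames is None else np.asarray(frames)
    sel = (frames >= td) & (frames <= lo)
    if not sel.any():
        raise StrideExcludedError("no samples inside [TD, LO]")
    gap = np.abs(prox_x[sel] - dist_x[sel])
    if np.any(~np.isfinite(gap)):
        raise StrideExcludedError("invalid frames span the mid-stride window")
    return int(frames[sel][np.argmin(gap)])     # argmin -> first minimum


def limb_excursion(protraction_td: float, protraction_lo: float) -> float:
    """Angular excursion over support: protraction(TD) - protraction(LO)."""
    return float(protraction_td) - float(protraction_lo)


def chain_angles(chain: CorrectedChain, side: str) -> pd.DataFrame:
    """Per-frame angle profiles for a corrected limb chain."""
    return pd.DataFrame(
        {
            "frame": chain.frames,
            "midjoint_angle": midjoint_angle(
                chain.prox_corrected, chain.mid_corrected, chain.distal
            ),
            "proximal_abduction": segment_abduction_angle(
                chain.prox_corrected, chain.mid_corrected, side
            ),
            "distal_abduction": segment_abduction_angle(
                chain.mid_corrected, chain.distal, side
            ),
            "protraction": limb_protraction_angle(chain.prox_corrected, chain.distal),
        }
    )


def summarize_stride(
    chain: CorrectedChain,
    events: StrideEvents,
    speed: float,
    metadata: dict,
) -> dict:
    """One tidy summary row: per-event angles, excursion, speed, labels.

    Raises :class:`StrideExcludedError` if the chain was excluded or any
    event frame falls outside the corrected range or is uncorrectable.
    """
    if chain.excluded:
        raise StrideExcludedError("chain excluded: too many uncorrectable frames")
    profiles = chain_angles(chain, metadata.get("side", "left")).set_index("frame")
    row: dict = dict(metadata)
    row["speed"] = float(speed)
    for name, frame in (("td", events.td), ("ms", events.ms), ("lo", events.lo)):
        if frame not in profiles.index:
            raise StrideExcludedError(f"event {name.upper()} at frame {frame} missing")
        vals = profiles.loc[frame]
        if not np.all(np.isfinite(vals.to_numpy())):
            raise StrideExcludedError(f"angles undefined at event {name.upper()}")
        for var in ANGLE_VARS:
            row[f"{var}_{name}"] = float(vals[var])
    row["excursion"] = limb_excursion(row["protraction_td"], row["protraction_lo"])
    return row
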