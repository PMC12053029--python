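"""Skin-artifact correction of proximal limb markers.

Surface markers over the shoulder, elbow, hip and knee ride on mobile
skin, so their apparent positions drift relative to the underlying
joints.  The wrist and ankle markers sit where skin movement is minimal
and are trusted.  Correction rebuilds the chain distally-to-proximally:
the apparent positions fix only the *directions* between neighboring
markers, while the distances are reset to the segment lengths measured
on the anesthetized animal:

    mid_corrected  = distal        + L_distal_segment  * unit(mid_apparent  - distal)
    prox_corrected = mid_corrected + L_proximal_segment * unit(prox_apparent - mid_corrected)

Forelimb chains use (forearm, arm) lengths, hindlimb chains (leg, thigh).
After correction the inter-marker distances equal the measured lengths
to machine precision at every frame, the distal marker is untouched, and
any displacement that was purely along a segment's axis is removed
exactly.  Frames where neighboring markers nearly coincide (< 1 mm)
cannot define a direction and are flagged; a stride with > 10% of its
support frames uncorrectable is excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

#: below this inter-marker distance a unit vector is undefined
EPS_COINCIDENT_M = 1e-3

#: fraction of uncorrectable support frames beyond which a stride is excluded
MAX_UNCORRECTABLE_FRACTION = 0.10


@dataclass
class SegmentLengths:
    """Measured limb segment lengths for one individual and side, meters.

    Ingested from cm (the field convention for tape measurements); the
    arm spans shoulder-elbow, forearm elbow-wrist, thigh hip-knee and
    leg knee-ankle.
    """

    individual_id: str
    side: str                    # 'left' or 'right'
    arm_m: float
    forearm_m: float
    thigh_m: float
    leg_m: float

    def __post_init__(self) -> None:
        for name in ("arm_m", "forearm_m", "thigh_m", "leg_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @classmethod
    def from_cm(cls, individual_id: str, side: str,
                arm: float, forearm: float, thigh: float, leg: float
                ) -> "SegmentLengths":
        return cls(individual_id, side,
                   arm / 100.0, forearm / 100.0, thigh / 100.0, leg / 100.0)

    def for_girdle(self, girdle: str) -> tuple[float, float]:
        """(distal segment, proximal segment) lengths for a limb girdle."""
        if girdle == "fore":
            return self.forearm_m, self.arm_m
        if girdle == "hind":
            return self.leg_m, self.thigh_m
        raise ValueError("girdle must be 'fore' or 'hind'")


@dataclass
class CorrectedChain:
    """Three-marker limb chain after segment-length correction."""

    frames: np.ndarray                 # (n,)
    distal: np.ndarray                 # (n, 3) wrist/ankle, untouched
    mid_corrected: np.ndarray          # (n, 3) elbow/knee
    prox_corrected: np.ndarray         # (n, 3) shoulder/hip
    correction_magnitude: np.ndarray   # (n, 2): |mid shift|, |prox shift| in m
    uncorrectable: np.ndarray          # (n,) bool
    excluded: bool = False


def _unit(vec: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    norm = np.linalg.norm(vec, axis=1)
    bad = norm < EPS_COINCIDENT_M
    safe = np.where(bad, 1.0, norm)
    return vec / safe[:, None], bad


def correct_limb_markers(
    distal: np.ndarray,
    mid_apparent: np.ndarray,
    prox_apparent: np.ndarray,
    lengths: SegmentLengths,
    girdle: str,
    frames: np.ndarray | None = None,
    support: tuple[int, int] | None = None,
) -> CorrectedChain:
    """Translate mid and proximal markers along apparent directions to the
    measured segment lengths.

    Positions are (n, 3) arrays of smoothed coordinates in meters.  If
    ``support`` (TD, LO) and ``frames`` are given, the uncorrectable
    fraction is assessed over support frames only.
    """
    distal = np.asarray(distal, dtype=float)
    mid_apparent = np.asarray(mid_apparent, dtype=float)
    prox_apparent = np.asarray(prox_apparent, dtype=float)
    n = len(distal)
    frames = np.arange(n) if frames is None else np.asarray(frames)
    l_dist, l_prox = lengths.for_girdle(girdle)

    u_mid, bad_mid = _unit(mid_apparent - distal)
    mid_corrected = distal + l_dist * u_mid
    u_prox, bad_prox = _unit(prox_apparent - mid_corrected)
    prox_corrected = mid_corrected + l_prox * u_prox

    uncorrectable = bad_mid | bad_prox
    mid_corrected[uncorrectable] = np.nan
    prox_corrected[uncorrectable] = np.nan
    magnitude = np.stack(
        [
            np.linalg.norm(mid_corrected - mid_apparent, axis=1),
            np.linalg.norm(prox_corrected - prox_apparent, axis=1),
        ],
        axis=1,
    )

    if support is not None:
        in_support = (frames >= support[0]) & (frames <= support[1])
    else:
        in_support = np.ones(n, dtype=bool)
    frac_bad = float(uncorrectable[in_support].mean()) if in_support.any() else 1.0
    excluded = frac_bad > MAX_UNCORRECTABLE_FRACTION
    if uncorrectable.any():
        logger.warning(
            "%s chain: %d/%d support frames uncorrectable (near-coincident markers)%s",
            girdle, int(uncorrectable[in_support].sum()), int(in_support.sum()),
            "; stride excluded" if excluded else "",
        )
    return CorrectedChain(
        frames=frames,
        distal=distal,
        mid_corrected=mid_corrected,
        prox_corrected=prox_corrected,
        correction_magnitude=magnitude,
        uncorrectable=uncorrectable,
        excluded=excluded,
    )


def pick_side_lengths(
    table: dict[tuple[str, str], SegmentLengths],
    individual_id: str,
    side: str,
) -> SegmentLengths:
    """Look up lengths for (individual, side), substituting the other side
    with a logged warning when the requested one was not measured."""
    key = (individual_id, side)
    if key in table:
        return table[key]
    other = (individual_id, "right" if side == "left" else "left")
    if other in table:
        logger.warning(
            "segment lengths for %s/%s missing; substituting %s side",
            individual_id, side, other[1],
        )
        return table[other]
    raise KeyError(f"no segment lengths for individual {individual_id!r}")
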