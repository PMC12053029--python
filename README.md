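# suspendkin

3D limb kinematics of suspensory quadrupedal locomotion — a tested
videogrammetry-to-statistics pipeline for animals that walk hanging below
a support (tree sloths being the canonical case), plus a forward-kinematic
stride simulator with known ground truth.

Sloths and other suspensory mammals load their limbs in tension, and their
joint kinematics cannot be assumed from upright walking. Measuring them
means multi-camera video of an animal traversing a horizontal beam,
digitized joint markers, and a chain of careful processing before a single
elbow angle can be trusted: camera calibration, 3D triangulation, spline
smoothing of noisy marker paths, correction of markers that ride on mobile
skin, event detection within each limb's support phase, and mixed-effects
statistics that respect repeated measures on a handful of individuals.
`suspendkin` implements that chain end to end for researchers in animal
biomechanics, and ships a simulator so every stage is testable without any
video.

## What it computes

For each stride's support phase (touchdown TD → mid-stride MS → liftoff
LO, with MS the frame where the fore-aft positions of the proximal-most
and distal-most markers are closest):

* **mid-joint angle** — interior 3D angle at the elbow/knee, 180° = fully
  extended;
* **limb protraction** — signed sagittal-plane deviation of the limb
  vector from vertical, positive with the distal end cranial;
* **segment abduction** — signed coronal-plane deviation of the arm /
  forearm / thigh / leg from vertical, positive lateral, side-normalized;
* **angular excursion** = protraction(TD) − protraction(LO);
* **speed** — mean fore-aft derivative of the smoothed proximal marker.

Processing stages:

1. **DLT calibration & triangulation** — 11-parameter direct linear
   transformation per camera from ≥ 6 non-coplanar control points; linear
   least-squares triangulation; per-stride axis standardization so +x is
   the direction of travel (right-handed, z up).
2. **Quintic smoothing splines** with a hard 0.5 cm² squared-error budget
   per marker; gaps ≤ 10% of support duration are interpolated, longer
   gaps exclude the stride.
3. **Skin-artifact correction** — apparent inter-marker *directions* are
   kept, distances reset to the segment lengths measured on the animal:
   `mid' = distal + L_dist·û(mid − distal)`,
   `prox' = mid' + L_prox·û(prox − mid')`. Post-correction segment
   lengths match the measurements to machine precision.
4. **Mixed-effects ANCOVA** per response: fixed factor (event, girdle or
   species) × speed, random intercepts for individual and trial, optional
   Box–Cox; Tukey-adjusted estimated marginal means at the mean speed (or
   at the min/mean/max of the overlapping speed range when slopes are
   non-homogeneous).

See `docs/methods.md` for conventions, numerical choices and limitations.

## Worked example

```python
import numpy as np
from suspendkin import (SegmentLengths, simulate_stride, default_camera_rig,
                        render_observations, dlt_reconstruct,
                        correct_limb_markers, midjoint_angle)

lengths = SegmentLengths.from_cm("BV1", "left",
                                 arm=17, forearm=17.5, thigh=11.5, leg=11.5)
truth = simulate_stride("fore", "left", lengths, speed=0.30)
print(f"support: {len(truth.frames)} frames at 60 Hz, "
      f"realized speed {truth.speed:.3f} m/s")

cams = default_camera_rig("left")
rng = np.random.default_rng(0)
obs = render_observations(truth, cams, rng,
                          pixel_noise_sd=0.5, slip_amplitude=0.01)
pos = {m: dlt_reconstruct(cams, obs[m], marker_id=m).position
       for m in truth.marker_names}

biased = midjoint_angle(pos["shoulder"], pos["elbow"], pos["wrist"])
chain = correct_limb_markers(pos["wrist"], pos["elbow"], pos["shoulder"],
                             lengths, "fore")
fixed = midjoint_angle(chain.prox_corrected, chain.mid_corrected, chain.distal)
ref = midjoint_angle(*(truth.positions[m] for m in truth.marker_names))
print(f"elbow angle error with 1 cm skin slip: "
      f"{np.abs(biased - ref).mean():.2f} deg uncorrected, "
      f"{np.abs(fixed - ref).mean():.2f} deg corrected")
```

prints

```
support: 51 frames at 60 Hz, realized speed 0.303 m/s
elbow angle error with 1 cm skin slip: 1.89 deg uncorrected, 0.32 deg corrected
```

The simulated forelimb hangs from a fixed wrist contact and follows the
prescribed profiles (elbow 137 → 102 → 105°, protraction +30 → −20°); the
realized speed differs from the 0.30 m/s target only by 60 Hz frame
quantization. A 1 cm sinusoidal skin slip biases the raw elbow angle by
almost 2° on average; enforcing the measured forearm and arm lengths along
the observed directions removes nearly all of it.

## Command line

```bash
suspendkin simulate --seed 3 --out data          # synthetic study + truth
suspendkin process  --manifest data/manifest.yaml --out out
suspendkin stats    --summary out/stride_summary.csv \
                    --response midjoint_angle --girdle fore --out statsout
suspendkin run      --manifest data/manifest.yaml --out out   # both steps
suspendkin calibrate / reconstruct               # individual stages
```

`process` writes a tidy `stride_summary.csv` (one row per stride, wide per
event) and logs every exclusion with its reason; `stats` writes EMM and
Tukey-contrast CSVs plus a plain-text fit report.

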