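"""File dialects, dataset writing, configuration, and pipeline orchestration.

All on-disk formats are plain CSV/YAML:

calibration file
    ``point_id,X,Y,Z`` followed by ``cam<k>_u,cam<k>_v`` column pairs;
    blank cells mean a camera did not see the point.
digitized-point file
    One row per frame, one ``<marker>_cam<k>_x``/``_y`` column pair per
    marker per camera; blank cells are occluded frames.
events file
    ``trial,stride_id,limb,side,TD_frame,LO_frame`` -- video-coded
    touchdown/liftoff frames, 0-based (video coders often use 1-based
    frame numbers; convert before ingest).
segment-length file
    ``individual,segment,side,length_cm`` with segments arm / forearm /
    thigh / leg.

Positions are meters, angles degrees, speeds m/s in every output.
``run_pipeline`` composes the full chain (reconstruct -> standardize ->
smooth -> correct -> summarize) over a study manifest; outputs are a
pure function of inputs and configuration, and every excluded stride is
logged with its reason.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import geometry, kinematics
from .correction import SegmentLengths, correct_limb_markers, pick_side_lengths
from .errors import StrideExcludedError, SuspendkinError
from .geometry import CameraDLT, ControlPointSet, MarkerTrajectory
from .simulate import GIRDLE_MARKERS, SimulationParams, simulate_study
from .trajectories import SmoothingConfig, compute_speed, fit_smoothing_spline

logger = logging.getLogger(__name__)

SPECIES = "Bradypus variegatus"


@dataclass
class PipelineConfig:
    """Processing options: smoothing settings plus the speed convention."""

    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig)
    speed_component: str = "x"          # 'x' (fore-aft) or '3d'
    frame_rate: float = 60.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        smoothing = SmoothingConfig(**raw.get("smoothing", {}))
        return cls(
            smoothing=smoothing,
            speed_component=raw.get("speed_component", "x"),
            frame_rate=float(raw.get("frame_rate", 60.0)),
        )


# ---------------------------------------------------------------------------
# readers / writers


def write_calibration(control: ControlPointSet, path: str | Path) -> None:
    cols: dict[str, object] = {
        "point_id": [f"p{i + 1}" for i in range(len(control.points3d))],
        "X": control.points3d[:, 0],
        "Y": control.points3d[:, 1],
        "Z": control.points3d[:, 2],
    }
    for cid, uv in control.points2d.items():
        cols[f"{cid}_u"] = uv[:, 0]
        cols[f"{cid}_v"] = uv[:, 1]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.10g")


def read_calibration(path: str | Path) -> ControlPointSet:
    df = pd.read_csv(path)
    cam_ids = sorted(
        {c[:-2] for c in df.columns if c.endswith("_u")},
        key=lambda s: (len(s), s),
    )
    points2d = {
        cid: df[[f"{cid}_u", f"{cid}_v"]].to_numpy(dtype=float) for cid in cam_ids
    }
    return ControlPointSet(
        points3d=df[["X", "Y", "Z"]].to_numpy(dtype=float), points2d=points2d
    )


def write_digitized_points(
    observations: dict[str, dict[str, np.ndarray]], path: str | Path
) -> None:
    """Write a DLTdv-dialect CSV: ``<marker>_<cam>_x/_y`` per column pair."""
    cols: dict[str, np.ndarray] = {}
    for marker, per_cam in observations.items():
        for cid, uv in per_cam.items():
            cols[f"{marker}_{cid}_x"] = uv[:, 0]
            cols[f"{marker}_{cid}_y"] = uv[:, 1]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.6f")


def read_digitized_points(path: str | Path) -> dict[str, dict[str, np.ndarray]]:
    """Parse a digitized-point CSV into ``{marker: {camera: (n, 2)}}``.

    Blank cells become NaN (occluded).  A malformed header -- an x
    column without its y partner -- raises ``ValueError`` naming it.
    """
    df = pd.read_csv(path)
    out: dict[str, dict[str, np.ndarray]] = {}
    for col in df.columns:
        if not col.endswith("_x"):
            if not col.endswith("_y"):
                raise ValueError(f"unrecognized column {col!r}: expected *_x or *_y")
            continue
        stem = col[:-2]
        partner = f"{stem}_y"
        if partner not in df.columns:
            raise ValueError(f"column {col!r} has no matching {partner!r}")
        marker, _, cam = stem.rpartition("_cam") if "_cam" in stem else (None, None, None)
        if marker:
            cam = "cam" + cam
        else:
            marker, _, cam = stem.rpartition("_")
        uv = df[[col, partner]].to_numpy(dtype=float)
        out.setdefault(marker, {})[cam] = uv
    if not out:
        raise ValueError("no marker columns found")
    return out


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    events.to_csv(path, index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"trial", "stride_id", "limb", "side", "TD_frame", "LO_frame"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"events file missing columns: {sorted(missing)}")
    return df


def write_segment_lengths(
    lengths: dict[tuple[str, str], SegmentLengths], path: str | Path
) -> None:
    rows = []
    for (ind, side), sl in sorted(lengths.items()):
        for seg, meters in (
            ("arm", sl.arm_m), ("forearm", sl.forearm_m),
            ("thigh", sl.thigh_m), ("leg", sl.leg_m),
        ):
            rows.append(
                {"individual": ind, "segment": seg, "side": side,
                 "length_cm": meters * 100.0}
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6g")


def read_segment_lengths(path: str | Path) -> dict[tuple[str, str], SegmentLengths]:
    df = pd.read_csv(path)
    out: dict[tuple[str, str], SegmentLengths] = {}
    for (ind, side), grp in df.groupby(["individual", "side"]):
        seg = dict(zip(grp["segment"], grp["length_cm"]))
        out[(ind, side)] = SegmentLengths.from_cm(
            ind, side, arm=seg["arm"], forearm=seg["forearm"],
            thigh=seg["thigh"], leg=seg["leg"],
        )
    return out


# ---------------------------------------------------------------------------
# dataset writing (simulator output -> the exact dialects the pipeline reads)


def write_dataset(
    records: list[dict],
    params: SimulationParams,
    out_dir: str | Path,
) -> Path:
    """Write a simulated study to disk: per-trial point/event files, one
    calibration file per beam side, segment lengths, a manifest, and the
    truth table for recovery scoring.  Returns the manifest path."""
    from .simulate import default_control_points

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for side in ("left", "right"):
        control = default_control_points(side)
        alias = {cid: f"cam{i + 1}" for i, cid in enumerate(sorted(control.points2d))}
        control.points2d = {alias[cid]: uv for cid, uv in control.points2d.items()}
        write_calibration(control, out / f"calib_{side}.csv")

    lengths: dict[tuple[str, str], SegmentLengths] = {}
    for rec in records:
        sl = rec["lengths"]
        lengths[(sl.individual_id, sl.side)] = sl
    write_segment_lengths(lengths, out / "segment_lengths.csv")

    gap = 12
    manifest_trials = []
    truth_rows = []
    by_trial: dict[str, list[dict]] = {}
    for rec in records:
        by_trial.setdefault(rec["trial"], []).append(rec)

    for trial_id, recs in by_trial.items():
        girdle = recs[0]["girdle"]
        side = recs[0]["side"]
        markers = GIRDLE_MARKERS[girdle]
        cam_ids = sorted(recs[0]["observations"][markers[0]].keys())
        cam_alias = {cid: f"cam{i + 1}" for i, cid in enumerate(cam_ids)}

        offsets = []
        cursor = 0
        for rec in recs:
            offsets.append(cursor)
            pad = rec.get("edge_pad", 0)
            cursor += len(rec["truth"].frames) + 2 * pad + gap
        n_total = cursor - gap

        obs_full = {
            m: {cam_alias[cid]: np.full((n_total, 2), np.nan) for cid in cam_ids}
            for m in markers
        }
        ev_rows = []
        for rec, off in zip(recs, offsets):
            truth = rec["truth"]
            pad = rec.get("edge_pad", 0)
            n = len(truth.frames)
            td = off + pad                     # padded frames precede touchdown
            for m in markers:
                for cid in cam_ids:
                    obs_full[m][cam_alias[cid]][off: off + n + 2 * pad] = (
                        rec["observations"][m][cid]
                    )
            ev_rows.append(
                {
                    "trial": trial_id, "stride_id": truth.stride_id,
                    "limb": girdle, "side": side,
                    "TD_frame": td, "LO_frame": td + n - 1,
                }
            )
            row = {
                "stride_id": truth.stride_id, "trial": trial_id,
                "individual": truth.individual, "species": SPECIES,
                "limb": girdle, "side": side, "speed": truth.speed,
                "TD_frame": td, "MS_frame": td + truth.events.ms,
                "LO_frame": td + n - 1, "excursion": truth.excursion,
            }
            row.update(truth.event_angles)
            truth_rows.append(row)

        points_file = f"{trial_id}_points.csv"
        events_file = f"{trial_id}_events.csv"
        write_digitized_points(obs_full, out / points_file)
        write_events(pd.DataFrame(ev_rows), out / events_file)
        manifest_trials.append(
            {
                "trial_id": trial_id, "individual": recs[0]["individual"],
                "species": SPECIES, "side": side,
                "calibration": f"calib_{side}.csv",
                "points": points_file, "events": events_file,
            }
        )

    pd.DataFrame(truth_rows).to_csv(out / "truth.csv", index=False,
                                    float_format="%.10g")
    manifest = {
        "segment_lengths": "segment_lengths.csv",
        "seed": params.seed,
        "trials": manifest_trials,
    }
    manifest_path = out / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=True))
    return manifest_path


def make_dataset(params: SimulationParams, out_dir: str | Path) -> Path:
    """Simulate a study and write it to ``out_dir``; returns manifest path."""
    return write_dataset(simulate_study(params), params, out_dir)


# ---------------------------------------------------------------------------
# pipeline orchestration


def _calibrate_all(control: ControlPointSet) -> dict[str, CameraDLT]:
    return {cid: geometry.dlt_calibrate(control, cid) for cid in control.points2d}


def process_stride(
    trajectories: dict[str, MarkerTrajectory],
    stride: dict,
    lengths: SegmentLengths,
    cfg: PipelineConfig,
) -> dict:
    """Standardize, smooth, correct and summarize a single stride.

    ``stride`` needs keys limb, side, TD_frame, LO_frame plus metadata.
    Raises :class:`StrideExcludedError` with the reason on any exclusion.
    """
    girdle = stride["limb"]
    td, lo = int(stride["TD_frame"]), int(stride["LO_frame"])
    markers = GIRDLE_MARKERS[girdle]
    std, _beam = geometry.standardize_axes(
        {m: trajectories[m] for m in markers}, window=(td, lo)
    )
    smoothed = {
        m: fit_smoothing_spline(std[m], cfg.smoothing, (td, lo)) for m in markers
    }
    gappy = [m for m in markers if smoothed[m].gap_exceeded]
    if gappy:
        raise StrideExcludedError(f"gap_exceeded for marker(s) {', '.join(gappy)}")

    frames = smoothed[markers[0]].frames
    common = frames
    for m in markers[1:]:
        common = np.intersect1d(common, smoothed[m].frames)
    pos = {
        m: smoothed[m].position[np.isin(smoothed[m].frames, common)] for m in markers
    }
    # the standardized frame may have flipped y: infer the lateral side
    # of the beam from the trusted distal marker, not the metadata label
    in_support = (common >= td) & (common <= lo)
    lateral_side = (
        "left" if float(np.mean(pos[markers[2]][in_support, 1])) > 0 else "right"
    )

    chain = correct_limb_markers(
        pos[markers[2]], pos[markers[1]], pos[markers[0]],
        lengths, girdle, frames=common, support=(td, lo),
    )
    if chain.excluded:
        raise StrideExcludedError("too many uncorrectable frames (>10% of support)")
    ms = kinematics.detect_midstride(
        chain.prox_corrected[:, 0], chain.distal[:, 0], td, lo, frames=common
    )
    events = kinematics.StrideEvents(td=td, ms=ms, lo=lo)
    speed = compute_speed(smoothed[markers[0]], (td, lo), cfg.speed_component)
    meta = {
        "species": stride.get("species", SPECIES),
        "individual": stride["individual"],
        "trial": stride["trial"],
        "stride_id": stride["stride_id"],
        "limb": girdle,
        "side": lateral_side,
    }
    row = kinematics.summarize_stride(chain, events, speed, meta)
    row["MS_frame"] = ms
    return row


def run_pipeline(
    manifest_path: str | Path,
    cfg: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    write_profiles: bool = False,
) -> tuple[pd.DataFrame, list[dict]]:
    """Run the full kinematic pipeline over a study manifest.

    Returns ``(summary, exclusions)``: one tidy row per processed stride
    and a list of ``{"stride_id", "reason"}`` records for strides that
    were excluded.  If ``out_dir`` is given, writes ``stride_summary.csv``,
    ``exclusions.csv`` and (optionally) per-stride angle profiles.
    """
    cfg = cfg or PipelineConfig()
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    manifest = yaml.safe_load(manifest_path.read_text())
    lengths_table = read_segment_lengths(root / manifest["segment_lengths"])

    rows: list[dict] = []
    exclusions: list[dict] = []
    profiles: list[pd.DataFrame] = []
    for trial in manifest["trials"]:
        control = read_calibration(root / trial["calibration"])
        cameras = _calibrate_all(control)
        observations = read_digitized_points(root / trial["points"])
        events = read_events(root / trial["events"])
        trajs: dict[str, MarkerTrajectory] = {}
        for marker, per_cam in observations.items():
            try:
                trajs[marker] = geometry.dlt_reconstruct(
                    cameras, per_cam, marker_id=marker, frame_rate=cfg.frame_rate
                )
            except SuspendkinError as exc:
                logger.warning("trial %s marker %s: %s", trial["trial_id"], marker, exc)
        for _, stride in events.iterrows():
            info = dict(stride)
            info.setdefault("individual", trial.get("individual"))
            info.setdefault("species", trial.get("species", SPECIES))
            try:
                lengths = pick_side_lengths(
                    lengths_table, info["individual"], info["side"]
                )
                row = process_stride(trajs, info, lengths, cfg)
            except SuspendkinError as exc:
                logger.info("stride %s excluded: %s", stride["stride_id"], exc)
                exclusions.append(
                    {"stride_id": stride["stride_id"], "reason": str(exc)}
                )
                continue
            rows.append(row)

    summary = pd.DataFrame(rows)
    counts = summary["limb"].value_counts().to_dict() if len(summary) else {}
    logger.info(
        "pipeline complete: %d strides summarized (%s), %d excluded",
        len(summary),
        ", ".join(f"{k}={v}" for k, v in sorted(counts.items())),
        len(exclusions),
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out / "stride_summary.csv", index=False, float_format="%.8g")
        pd.DataFrame(exclusions, columns=["stride_id", "reason"]).to_csv(
            out / "exclusions.csv", index=False
        )
    return summary, exclusions
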