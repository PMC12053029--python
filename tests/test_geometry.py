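"""DLT calibration, projection, triangulation, axis standardization."""

import numpy as np
import pytest

from conftest import random_rig
from suspendkin.errors import (
    CalibrationDegenerateError,
    DirectionUndefinedError,
    EmptyTrajectoryError,
    ProjectionSingularError,
)
from suspendkin.geometry import (
    BeamFrame,
    CameraDLT,
    ControlPointSet,
    MarkerTrajectory,
    dlt_calibrate,
    dlt_project,
    dlt_reconstruct,
    standardize_axes,
)


def _control(points3d, cams, noise=0.0, rng=None):
    pts2d = {cid: dlt_project(cam, points3d) for cid, cam in cams.items()}
    if noise > 0:
        pts2d = {cid: uv + rng.normal(0, noise, uv.shape) for cid, uv in pts2d.items()}
    return ControlPointSet(points3d=points3d, points2d=pts2d)


class TestCalibrate:
    def test_noiseless_cube_self_consistency(self, camera_pair, cube_points):
        control = _control(cube_points, camera_pair)
        for cid in camera_pair:
            cam = dlt_calibrate(control, cid)
            assert cam.rms_reprojection_error < 1e-8
            proj = dlt_project(cam, cube_points)
            assert np.allclose(proj, control.points2d[cid], atol=1e-8)

    def test_noisy_rms_matches_independent_lstsq_oracle(self, camera_pair,
                                                        cube_points, rng):
        control = _control(cube_points, camera_pair, noise=0.5, rng=rng)
        cam = dlt_calibrate(control, "cam1")

        # independent brute-force solve of the same overdetermined linear
        # system, built from the DLT rational form written out by hand
        uv = control.points2d["cam1"]
        rows, rhs = [], []
        for (x, y, z), (u, v) in zip(cube_points, uv):
            rows.append([x, y, z, 1, 0, 0, 0, 0, -u * x, -u * y, -u * z])
            rhs.append(u)
            rows.append([0, 0, 0, 0, x, y, z, 1, -v * x, -v * y, -v * z])
            rhs.append(v)
        coeffs = np.linalg.pinv(np.array(rows)) @ np.array(rhs)
        oracle_cam = CameraDLT("oracle", coeffs)
        resid = dlt_project(oracle_cam, cube_points) - uv
        oracle_rms = np.sqrt(np.mean(np.sum(resid**2, axis=1)))

        assert cam.rms_reprojection_error <= 2 * oracle_rms
        assert cam.rms_reprojection_error > 0

    def test_rms_invariant_to_point_order(self, camera_pair, cube_points, rng):
        control = _control(cube_points, camera_pair, noise=0.5, rng=rng)
        perm = rng.permutation(len(cube_points))
        shuffled = ControlPointSet(
            points3d=control.points3d[perm],
            points2d={c: uv[perm] for c, uv in control.points2d.items()},
        )
        a = dlt_calibrate(control, "cam1").rms_reprojection_error
        b = dlt_calibrate(shuffled, "cam1").rms_reprojection_error
        assert a == pytest.approx(b, rel=1e-9)

    def test_coplanar_points_degenerate(self, camera_pair):
        flat = np.array([(x, y, 0.0) for x in (-0.5, 0, 0.5) for y in (-0.5, 0.5)])
        control = _control(flat, camera_pair)
        with pytest.raises(CalibrationDegenerateError):
            dlt_calibrate(control, "cam1")

    def test_too_few_points_degenerate(self, camera_pair, cube_points):
        control = _control(cube_points[:5], camera_pair)
        with pytest.raises(CalibrationDegenerateError):
            dlt_calibrate(control, "cam1")


class TestProject:
    def test_closed_form(self):
        # unit focal axes, zero offsets, constant denominator
        cam = CameraDLT("toy", [1, 0, 0, 0, 0, 1, 0, 0, 0, 0, 0])
        assert np.allclose(dlt_project(cam, np.array([0.0, 0.0, 1.0])), [0.0, 0.0])
        assert np.allclose(dlt_project(cam, np.array([0.3, -0.2, 1.0])), [0.3, -0.2])

    def test_roundtrip_within_calibration_residual(self, camera_pair, cube_points, rng):
        control = _control(cube_points, camera_pair, noise=0.3, rng=rng)
        cam = dlt_calibrate(control, "cam2")
        err = dlt_project(cam, cube_points) - control.points2d["cam2"]
        rms = np.sqrt(np.mean(np.sum(err**2, axis=1)))
        assert rms == pytest.approx(cam.rms_reprojection_error, rel=1e-9)

    def test_point_on_camera_plane_singular(self):
        cam = CameraDLT("toy", [1, 0, 0, 0, 0, 1, 0, 0, 0, 0, -1.0])
        with pytest.raises(ProjectionSingularError):
            dlt_project(cam, np.array([0.0, 0.0, 1.0]))   # denominator = 0


class TestReconstruct:
    def test_noiseless_roundtrip(self, camera_pair):
        p = np.array([0.10, -0.05, -0.30])
        obs = {cid: dlt_project(cam, p)[None, :] for cid, cam in camera_pair.items()}
        traj = dlt_reconstruct(camera_pair, obs)
        assert np.linalg.norm(traj.position[0] - p) < 1e-9

    def test_noisy_median_error_vs_svd_oracle(self, rng):
        cams = random_rig(rng, n_cams=4)
        pts = rng.uniform(-0.4, 0.4, size=(100, 3))
        obs = {
            cid: dlt_project(cam, pts) + rng.normal(0, 1.0, (100, 2))
            for cid, cam in cams.items()
        }
        traj = dlt_reconstruct(cams, obs)

        def svd_solve(i):
            a, b = [], []
            for cid, cam in cams.items():
                L = cam.coefficients
                u, v = obs[cid][i]
                a.append(L[0:3] - u * L[8:11]); b.append(u - L[3])
                a.append(L[4:7] - v * L[8:11]); b.append(v - L[7])
            A, bb = np.array(a), np.array(b)
            return np.linalg.pinv(A) @ bb     # SVD-based solve

        oracle = np.array([svd_solve(i) for i in range(100)])
        med_ours = np.median(np.linalg.norm(traj.position - pts, axis=1))
        med_oracle = np.median(np.linalg.norm(oracle - pts, axis=1))
        assert med_ours <= 2 * med_oracle

    def test_single_camera_frame_masked(self, camera_pair):
        p = np.array([0.0, 0.0, -0.3])
        obs = {}
        for k, (cid, cam) in enumerate(camera_pair.items()):
            uv = np.tile(dlt_project(cam, p), (3, 1))
            if k == 0:
                uv[1] = np.nan        # frame 1 seen by only one camera
            obs[cid] = uv
        traj = dlt_reconstruct(camera_pair, obs)
        assert traj.valid.tolist() == [True, False, True]
        assert np.all(np.isnan(traj.position[1]))

    def test_no_stereo_frames_raises(self, camera_pair):
        obs = {cid: np.full((4, 2), np.nan) for cid in camera_pair}
        first = next(iter(camera_pair))
        obs[first][:] = 100.0        # one camera sees everything, alone
        with pytest.raises(EmptyTrajectoryError):
            dlt_reconstruct(camera_pair, obs)


def _traj(positions, marker="shoulder"):
    positions = np.asarray(positions, dtype=float)
    return MarkerTrajectory(
        marker_id=marker,
        frames=np.arange(len(positions)),
        position=positions,
        valid=np.ones(len(positions), dtype=bool),
    )


class TestStandardizeAxes:
    def test_backward_travel_flips_x_and_y(self):
        pos = np.column_stack([-0.01 * np.arange(10), np.full(10, 0.2), np.zeros(10)])
        out, beam = standardize_axes({"shoulder": _traj(pos)})
        vx = np.diff(out["shoulder"].position[:, 0]) * 60
        assert np.mean(vx) > 0
        assert np.all(out["shoulder"].position[:, 1] == -0.2)
        assert beam.travel_sign == -1
        # right-handedness: x and y flip together, z untouched
        assert np.allclose(np.cross([1, 0, 0], [0, 1, 0]), [0, 0, 1])

    def test_forward_travel_unchanged(self):
        pos = np.column_stack([0.01 * np.arange(10), np.zeros(10), np.zeros(10)])
        out, beam = standardize_axes({"shoulder": _traj(pos)})
        assert np.array_equal(out["shoulder"].position, pos)
        assert beam.travel_sign == 1

    def test_idempotent(self):
        pos = np.column_stack([-0.01 * np.arange(10), np.zeros(10), np.zeros(10)])
        once, beam1 = standardize_axes({"shoulder": _traj(pos)})
        twice, _ = standardize_axes(once, beam1)
        assert np.array_equal(once["shoulder"].position, twice["shoulder"].position)

    def test_isometry(self, rng):
        a = rng.normal(size=(20, 3)) - np.array([5, 0, 0]) * np.linspace(0, 1, 20)[:, None]
        b = a + rng.normal(size=3)
        out, _ = standardize_axes({"shoulder": _traj(a), "elbow": _traj(b, "elbow")})
        d_before = np.linalg.norm(a - b, axis=1)
        d_after = np.linalg.norm(
            out["shoulder"].position - out["elbow"].position, axis=1
        )
        assert np.allclose(d_before, d_after, atol=1e-12)

    def test_zero_displacement_undefined(self):
        pos = np.zeros((10, 3))
        with pytest.raises(DirectionUndefinedError):
            standardize_axes({"shoulder": _traj(pos)})

    def test_simulated_stride_speed_preserved(self, bv1_lengths):
        from suspendkin.simulate import simulate_stride

        truth = simulate_stride("fore", "left", bv1_lengths, 0.35)
        trajs = {
            m: _traj(p, m) for m, p in truth.positions.items()
        }
        out, _ = standardize_axes(trajs)
        vx = np.diff(out["shoulder"].position[:, 0]) * truth.frame_rate
        assert np.mean(vx) == pytest.approx(truth.speed, abs=1e-6)
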