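"""Camera geometry, projection noise model and point-cloud rendering."""

import numpy as np
import pytest

from camimu.camera import (
    CAPSULE_RADIUS,
    CameraModel,
    ToFFrame,
    back_project,
    camera_to_world,
    joints2d_from_csv,
    joints2d_to_csv,
    make_camera,
    ply_read,
    ply_write,
    project_joints,
    render_point_cloud,
    view_rotation,
    world_to_camera,
)
from camimu.errors import ProjectionError
from camimu.motion import JOINTS


class TestCameraPlacement:
    def test_frontal_axis_antiparallel_to_x(self):
        cam = make_camera(0.0)
        np.testing.assert_allclose(cam.optical_axis, [-1.0, 0.0, 0.0], atol=1e-12)

    def test_relative_rotation_trace(self):
        # moving the station by 15° of azimuth is a pure 15° rotation
        r0 = make_camera(0.0).rotation
        r15 = make_camera(15.0).rotation
        rel = r15 @ r0.T
        assert np.trace(rel) == pytest.approx(1.0 + 2.0 * np.cos(np.deg2rad(15.0)))
        np.testing.assert_allclose(
            r15, view_rotation(15.0) @ r0, atol=1e-12
        )

    def test_views_map_points_differently(self):
        p = np.array([0.3, 0.2, 0.4])
        a = world_to_camera(p, make_camera(0.0))
        b = world_to_camera(p, make_camera(30.0))
        assert np.abs(a - b).max() > 1e-3
        on_axis = np.array([0.0, 0.0, 0.1])
        za = world_to_camera(on_axis, make_camera(0.0))[2]
        zb = world_to_camera(on_axis, make_camera(30.0))[2]
        assert za == pytest.approx(zb)  # depth to the rotation axis is view-invariant

    def test_round_trip_exact(self):
        cam = make_camera(22.5, distance=1.7)
        pts = np.random.default_rng(0).normal(size=(1000, 3))
        back = camera_to_world(world_to_camera(pts, cam), cam)
        assert np.abs(back - pts).max() < 1e-12

    def test_torso_center_on_optical_axis(self):
        cam = make_camera(15.0, distance=2.0)
        pc = world_to_camera(np.array([0.0, 0.0, cam.camera_height]), cam)
        assert abs(pc[0]) < 1e-9 and abs(pc[1]) < 1e-9
        assert pc[2] == pytest.approx(2.0)

    def test_identity_extrinsics_is_identity(self):
        cam = CameraModel()  # default rotation=I, center=0
        p = np.array([0.1, 0.2, 0.3])
        np.testing.assert_allclose(world_to_camera(p, cam), p, atol=1e-15)

    def test_invalid_distance(self):
        with pytest.raises(ValueError):
            make_camera(0.0, distance=-1.0)


class TestProjection:
    def _traj_at(self, point):
        from camimu.motion import JointTrajectory

        pos = {j: np.tile(point, (3, 1)) for j in JOINTS}
        return JointTrajectory(np.arange(3) / 50.0, pos, fps=50.0)

    def test_optical_axis_hits_principal_point(self):
        cam = make_camera(0.0)
        world_on_axis = camera_to_world(np.array([0.0, 0.0, 1.5]), cam)
        j2d = project_joints(self._traj_at(world_on_axis), cam, pixel_noise_sd=0.0)
        np.testing.assert_allclose(j2d.uv[..., 0], cam.cx, atol=1e-9)
        np.testing.assert_allclose(j2d.uv[..., 1], cam.cy, atol=1e-9)

    def test_perspective_division_halves_offset(self):
        cam = make_camera(0.0)
        near = camera_to_world(np.array([0.2, 0.1, 1.0]), cam)
        far = camera_to_world(np.array([0.2, 0.1, 2.0]), cam)
        un = project_joints(self._traj_at(near), cam, 0.0).uv[0, 0]
        uf = project_joints(self._traj_at(far), cam, 0.0).uv[0, 0]
        np.testing.assert_allclose(
            uf - [cam.cx, cam.cy], (un - [cam.cx, cam.cy]) / 2.0, atol=1e-9
        )

    def test_pixel_noise_sd_matches_request(self):
        from camimu.motion import JointTrajectory

        cam = make_camera(0.0)
        point = camera_to_world(np.array([0.0, 0.0, 2.0]), cam)
        n = 10_000
        pos = {j: np.tile(point, (n, 1)) for j in JOINTS}
        traj = JointTrajectory(np.arange(n) / 50.0, pos, fps=50.0)
        j2d = project_joints(traj, cam, pixel_noise_sd=2.0, seed=11)
        sd = j2d.uv[:, 0, 0].std()
        assert sd == pytest.approx(2.0, rel=0.05)

    def test_point_behind_camera_raises(self):
        cam = make_camera(0.0)
        behind = camera_to_world(np.array([0.0, 0.0, -1.0]), cam)
        with pytest.raises(ProjectionError):
            project_joints(self._traj_at(behind), cam, 0.0)


def _frame_positions(noiseless_params, seed=0, index=120):
    from camimu.motion import simulate_reach_cycle

    traj = simulate_reach_cycle(noiseless_params, seed=seed)
    return {j: traj.positions[j][index] for j in traj.positions}


class TestPointCloud:
    def test_noise_free_points_lie_on_body(self, noiseless_params):
        pos = _frame_positions(noiseless_params)
        cam = make_camera(0.0)
        frame = render_point_cloud(pos, cam, depth_noise_sd=0.0, dropout_rate=0.0)
        assert frame.n_valid > 100
        pts_world = camera_to_world(frame.valid_points(), cam)
        from camimu.camera import _body_capsules

        dmin = np.full(len(pts_world), np.inf)
        for a, b, r in _body_capsules(pos, CAPSULE_RADIUS):
            ab = b - a
            tt = np.clip((pts_world - a) @ ab / (ab @ ab), 0.0, 1.0)
            closest = a + tt[:, None] * ab
            dist = np.linalg.norm(pts_world - closest, axis=1) - r
            dmin = np.minimum(dmin, np.abs(dist))
        assert dmin.max() < 1e-5  # every point sits on a capsule surface

    def test_back_projection_consistency(self, noiseless_params):
        cam = make_camera(0.0)
        frame = render_point_cloud(_frame_positions(noiseless_params), cam,
                                   depth_noise_sd=0.0, dropout_rate=0.0)
        vs, us = np.nonzero(frame.valid)
        stored = frame.points[vs, us]
        redone = back_project(us.astype(float), vs.astype(float), stored[:, 2], cam)
        assert np.abs(redone - stored).max() < 1e-6  # float32 storage

    def test_dropout_thins_cloud_binomially(self, noiseless_params):
        pos = _frame_positions(noiseless_params)
        cam = make_camera(0.0)
        n_full = render_point_cloud(pos, cam, 0.0, 0.0).n_valid
        eps = 0.1
        n_kept = render_point_cloud(pos, cam, 0.0, dropout_rate=1.0 - eps,
                                    seed=5).n_valid
        expected = eps * n_full
        assert abs(n_kept - expected) < 4.0 * np.sqrt(expected)

    def test_subject_outside_frustum_gives_empty_cloud(self, noiseless_params):
        pos = {j: p + np.array([10.0, 0.0, 0.0]) for j, p in
               _frame_positions(noiseless_params).items()}  # behind the camera
        frame = render_point_cloud(pos, make_camera(0.0))
        assert frame.n_valid == 0

    def test_view_equivariance(self, noiseless_params):
        # render at θ == render the world-rotated motion at 0°, same seed
        from camimu.motion import simulate_reach_cycle

        traj = simulate_reach_cycle(noiseless_params, seed=0)
        i = 140
        pos = {j: traj.positions[j][i] for j in traj.positions}
        rot = traj.rotated_about_z(-30.0)
        pos_rot = {j: rot.positions[j][i] for j in rot.positions}
        fa = render_point_cloud(pos, make_camera(30.0), 0.01, 0.05, seed=3)
        fb = render_point_cloud(pos_rot, make_camera(0.0), 0.01, 0.05, seed=3)
        np.testing.assert_array_equal(fa.valid, fb.valid)
        np.testing.assert_allclose(fa.points[fa.valid], fb.points[fb.valid], atol=1e-5)

    def test_render_deterministic(self, noiseless_params):
        pos = _frame_positions(noiseless_params)
        cam = make_camera(15.0)
        a = render_point_cloud(pos, cam, seed=9)
        b = render_point_cloud(pos, cam, seed=9)
        np.testing.assert_array_equal(a.valid, b.valid)
        np.testing.assert_array_equal(a.points, b.points)

    def test_invalid_dropout_rejected(self, noiseless_params):
        with pytest.raises(ValueError):
            render_point_cloud(_frame_positions(noiseless_params), make_camera(0.0),
                               dropout_rate=1.0)


class TestInterchange:
    def test_ply_round_trip(self, tmp_path, noiseless_params):
        frame = render_point_cloud(_frame_positions(noiseless_params), make_camera(0.0))
        path = tmp_path / "cloud.ply"
        ply_write(frame, path)
        back = ply_read(path)
        np.testing.assert_allclose(back, frame.valid_points(), atol=1e-6)

    def test_joints2d_csv_round_trip(self, tmp_path, noiseless_params):
        from camimu.motion import simulate_reach_cycle

        traj = simulate_reach_cycle(noiseless_params, seed=1)
        j2d = project_joints(traj, make_camera(0.0), 2.0, seed=2)
        path = tmp_path / "j2d.csv"
        joints2d_to_csv(j2d, path, fps=traj.fps)
        back = joints2d_from_csv(path)
        np.testing.assert_allclose(back.uv, j2d.uv, atol=1e-9)
        np.testing.assert_allclose(back.confidence, j2d.confidence, atol=1e-9)

    def test_tof_frame_rejects_nonpositive_depth(self):
        pts = np.zeros((2, 2, 3), dtype=np.float32)
        valid = np.ones((2, 2), dtype=bool)
        with pytest.raises(ValueError):
            ToFFrame(points=pts, valid=valid)
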