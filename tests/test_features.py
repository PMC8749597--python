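"""Feature computation: depth lifting, relative-vector features, windowing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from camimu.camera import (
    CAPSULE_RADIUS,
    Joints2D,
    Joints3D,
    ToFFrame,
    make_camera,
    project_joints,
    render_point_cloud,
    world_to_camera,
)
from camimu.errors import EmptyDatasetError, FeatureError, MissingDepthError
from camimu.features import (
    FeatureSeries,
    NormStats,
    feature_names,
    features_2d,
    features_3d,
    features_from_csv,
    features_to_csv,
    lift_frame,
    lift_to_3d,
    window_series,
)
from camimu.motion import simulate_reach_cycle


def _flat_frame(depth: float, cam) -> ToFFrame:
    """A wall of constant depth filling the image."""
    H, W = cam.height, cam.width
    u, v = np.meshgrid(np.arange(W, dtype=float), np.arange(H, dtype=float))
    from camimu.camera import back_project

    pts = back_project(u, v, np.full((H, W), depth), cam).astype(np.float32)
    return ToFFrame(points=pts, valid=np.ones((H, W), dtype=bool))


class TestLifting:
    def test_constant_depth_plane_recovered_exactly(self):
        cam = make_camera(0.0)
        frame = _flat_frame(1.8, cam)
        uv = np.array([[50.0, 60.0], [80.0, 70.0], [90.0, 100.0], [120.0, 90.0]])
        out = lift_frame(uv, frame, cam, k=2)
        np.testing.assert_allclose(out[:, 2], 1.8, atol=1e-9)

    def test_median_rejects_background_outlier(self):
        cam = make_camera(0.0)
        H, W = cam.height, cam.width
        pts = np.zeros((H, W, 3), dtype=np.float32)
        valid = np.zeros((H, W), dtype=bool)
        # three valid depths near the joint: two foreground, one background
        for (r, c), z in [((60, 60), 1.0), ((60, 61), 1.0), ((61, 60), 9.0)]:
            pts[r, c] = [0.0, 0.0, z]
            valid[r, c] = True
        frame = ToFFrame(points=pts, valid=valid)
        uv = np.tile([60.0, 60.0], (4, 1))
        out = lift_frame(uv, frame, cam, k=1)
        np.testing.assert_allclose(out[:, 2], 1.0, atol=1e-12)  # median, not mean 3.67

    def test_missing_depth_raises(self):
        cam = make_camera(0.0)
        empty = ToFFrame(
            points=np.zeros((cam.height, cam.width, 3), dtype=np.float32),
            valid=np.zeros((cam.height, cam.width), dtype=bool),
        )
        with pytest.raises(MissingDepthError):
            lift_frame(np.tile([60.0, 60.0], (4, 1)), empty, cam, k=3)

    def test_lifted_wrist_close_to_ground_truth(self, noiseless_params):
        # noise-free cloud: lift error is dominated by the surface-vs-bone
        # offset (one capsule radius); when the forearm lies oblique to the
        # view, depths vary across the 7x7 median window, adding up to
        # ~window-extent x limb-slope of slack on top of the radius
        traj = simulate_reach_cycle(noiseless_params, seed=0)
        cam = make_camera(0.0)
        j2d = project_joints(traj, cam, pixel_noise_sd=0.0)
        errs = []
        for i in range(100, traj.n_frames, 40):
            pos = {j: traj.positions[j][i] for j in traj.positions}
            frame = render_point_cloud(pos, cam, 0.0, 0.0)
            lifted = lift_frame(j2d.uv[i], frame, cam, k=3)
            truth = world_to_camera(traj.positions["LW"][i], cam)
            errs.append(np.linalg.norm(lifted[3] - truth))
        assert np.mean(errs) < CAPSULE_RADIUS
        assert max(errs) < CAPSULE_RADIUS + 0.02

    def test_interpolation_fills_missing_frames(self):
        cam = make_camera(0.0)
        good = _flat_frame(2.0, cam)
        empty = ToFFrame(
            points=np.zeros_like(good.points),
            valid=np.zeros_like(good.valid),
        )
        uv = np.tile([[60.0, 60.0]], (3, 4, 1)).reshape(3, 4, 2)
        j2d = Joints2D(uv=uv, confidence=np.ones((3, 4)))
        j3d = lift_to_3d(j2d, [good, empty, good], cam, k=2)
        np.testing.assert_allclose(j3d.xyz[1], j3d.xyz[0], atol=1e-9)


class TestFeatureVectors:
    def test_coincident_joints_give_zero_vector(self):
        uv = np.tile([55.0, 44.0], (1, 4, 1)).reshape(1, 4, 2)
        series = features_2d(Joints2D(uv=uv, confidence=np.ones((1, 4))))
        np.testing.assert_array_equal(series.values, 0.0)

    def test_three_four_five_norm(self):
        uv = np.zeros((1, 4, 2))
        uv[0, 0] = [3.0, 4.0]  # RS; LS=LE=LW=(0,0)
        series = features_2d(Joints2D(uv=uv, confidence=np.ones((1, 4))))
        names = feature_names("2d")
        row = dict(zip(names, series.values[0]))
        assert row["rel_RS_x"] == 3.0 and row["rel_RS_y"] == 4.0
        assert row["d_RS"] == 5.0
        assert all(row[n] == 0.0 for n in names if "RS" not in n)

    def test_translation_invariance_2d(self):
        rng = np.random.default_rng(0)
        uv = rng.uniform(0, 200, (5, 4, 2))
        a = features_2d(Joints2D(uv=uv, confidence=np.ones((5, 4)))).values
        b = features_2d(
            Joints2D(uv=uv + [10.0, 7.0], confidence=np.ones((5, 4)))
        ).values
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_rotation_preserves_3d_distances(self):
        rng = np.random.default_rng(1)
        xyz = rng.normal(size=(4, 4, 3)) + [0, 0, 3.0]
        from scipy.spatial.transform import Rotation

        R = Rotation.from_euler("zyx", [21.0, -13.0, 40.0], degrees=True).as_matrix()
        a = features_3d(Joints3D(xyz=xyz)).values
        b = features_3d(Joints3D(xyz=xyz @ R.T)).values
        np.testing.assert_allclose(a[:, 9:], b[:, 9:], atol=1e-9)  # distances
        assert np.abs(a[:, :9] - b[:, :9]).max() > 1e-3  # vectors rotate

    def test_unit_norm_example(self):
        xyz = np.zeros((1, 4, 3))
        xyz[0, 3] = [1.0, 2.0, 2.0]  # LW; LS at origin
        xyz[:, :, 2] += 2.0  # keep depths positive
        series = features_3d(Joints3D(xyz=xyz))
        assert series.values[0, feature_names("3d").index("d_LW")] == pytest.approx(3.0)

    def test_cross_view_rel_vectors_rotate_by_extrinsics(self, noiseless_params):
        # same pose seen from 0° and 30°: distances equal, vectors related by
        # exactly the relative camera rotation
        traj = simulate_reach_cycle(noiseless_params, seed=0)
        cam0, cam30 = make_camera(0.0), make_camera(30.0)
        coords = traj.stacked()
        j0 = Joints3D(world_to_camera(coords.reshape(-1, 3), cam0).reshape(coords.shape))
        j30 = Joints3D(world_to_camera(coords.reshape(-1, 3), cam30).reshape(coords.shape))
        f0, f30 = features_3d(j0).values, features_3d(j30).values
        np.testing.assert_allclose(f0[:, 9:], f30[:, 9:], atol=1e-9)
        rel = cam30.rotation.T @ cam0.rotation  # camera0 frame -> camera30 frame
        v0 = f0[:, :9].reshape(-1, 3)
        v30 = f30[:, :9].reshape(-1, 3)
        np.testing.assert_allclose(v30, v0 @ rel.T, atol=1e-9)

    def test_2d_view_sensitive_3d_distance_stable(self, noiseless_params):
        # the geometric core of viewpoint robustness, no learning involved
        traj = simulate_reach_cycle(noiseless_params, seed=0)
        cam0, cam30 = make_camera(0.0), make_camera(30.0)
        coords = traj.stacked()
        d3 = []
        d2 = []
        for cam in (cam0, cam30):
            jc = world_to_camera(coords.reshape(-1, 3), cam).reshape(coords.shape)
            d3.append(features_3d(Joints3D(jc)).values[:, 9:])
            j2d = project_joints(traj, cam, pixel_noise_sd=0.0)
            vals = features_2d(j2d).values[:, 6:]
            d2.append(vals / vals.mean())  # scale-normalized pixel distances
        assert np.abs(d3[0] - d3[1]).mean() < 1e-6
        assert np.abs(d2[0] - d2[1]).mean() > 1e-3

    def test_distance_equals_norm_of_vector_invariant(self):
        rng = np.random.default_rng(3)
        xyz = rng.normal(size=(50, 4, 3)) + [0, 0, 5.0]
        vals = features_3d(Joints3D(xyz=xyz)).values
        norms = np.stack(
            [np.linalg.norm(vals[:, 3 * i: 3 * i + 3], axis=1) for i in range(3)],
            axis=1,
        )
        np.testing.assert_allclose(vals[:, 9:], norms, atol=1e-9)

    def test_nan_joint_rejected(self):
        uv = np.zeros((1, 4, 2))
        uv[0, 1, 0] = np.nan
        with pytest.raises((FeatureError, ValueError)):
            features_2d(Joints2D(uv=uv, confidence=np.ones((1, 4))))


class TestWindowing:
    def test_window_count_formula(self):
        vals = np.zeros((100, 12))
        acc = np.zeros((100, 3))
        assert len(window_series(vals, acc, window=25, stride=1)) == 76

    def test_window_one_is_identity(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(30, 9))
        acc = rng.normal(size=(30, 3))
        ds = window_series(vals, acc, window=1, stride=1)
        np.testing.assert_array_equal(ds.X[:, 0, :], vals)
        np.testing.assert_array_equal(ds.y, acc)

    @pytest.mark.parametrize("T,window,stride", [(100, 25, 25), (97, 10, 7), (50, 50, 1)])
    def test_counts_match_brute_force(self, T, window, stride):
        starts = [s for s in range(T) if s + window <= T and s % stride == 0]
        ds = window_series(np.zeros((T, 12)), np.zeros((T, 3)), window, stride)
        assert len(ds) == len(starts)
        np.testing.assert_array_equal(ds.centers, np.array(starts) + window // 2)

    def test_short_series_raises(self):
        with pytest.raises(EmptyDatasetError):
            window_series(np.zeros((10, 12)), np.zeros((10, 3)), window=25)

    @settings(max_examples=25, deadline=None)
    @given(
        T=st.integers(1, 200),
        window=st.integers(1, 60),
        stride=st.integers(1, 10),
    )
    def test_count_formula_property(self, T, window, stride):
        if T < window:
            with pytest.raises(EmptyDatasetError):
                window_series(np.zeros((T, 9)), None, window, stride)
        else:
            ds = window_series(np.zeros((T, 9)), None, window, stride)
            assert len(ds) == (T - window) // stride + 1


class TestNormalizationAndIO:
    def test_stats_round_trip_csv(self, tmp_path):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(40, 12))
        series = FeatureSeries(values=vals, kind="3d", stats=NormStats.fit(vals))
        csv = tmp_path / "feat.csv"
        features_to_csv(series, csv)
        back = features_from_csv(csv)
        np.testing.assert_allclose(back.values, vals, atol=1e-9)
        np.testing.assert_allclose(back.stats.mean, series.stats.mean, atol=1e-12)
        np.testing.assert_allclose(back.normalized(), series.normalized(), atol=1e-9)

    def test_zscore_stats(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(3.0, 2.0, size=(500, 9))
        z = NormStats.fit(vals).apply(vals)
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=0), 1.0, atol=1e-9)
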