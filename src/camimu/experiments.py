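"""End-to-end experiment orchestration on synthetic sessions.

Two experiments mirror the study design:

* Experiment 1 — model comparison.  Sessions recorded at the known views
  (0° and 30°) are lifted to 3D features; DNN, CNN and DBLSTM regressors are
  trained on identical data and evaluated per axis on a held-out 10 % of the
  known-view material.
* Experiment 2 — 2D vs 3D features.  The DBLSTM is trained twice (pixel
  features vs lifted 3D features) on the known views and evaluated both on
  the known-view held-out split and on a wholly unseen 15° view, testing
  viewpoint robustness.

Splits are by contiguous temporal blocks with a one-window gap at each
boundary, so overlapping windows never leak across train/test.  Feature
normalization statistics come from training frames only, and the unseen
view contributes nothing to training or normalization.  A master seed
deterministically derives one sub-seed per pipeline stage through a fixed
stage table, so any stage can be re-run in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .camera import make_camera, project_joints, render_point_cloud, ply_write
from .errors import ConfigError
from .features import (
    FeatureSeries,
    NormStats,
    WindowedDataset,
    features_2d,
    features_3d,
    lift_to_3d,
    window_series,
)
from .metrics import AXES, evaluate
from .motion import (
    IMUTarget,
    JointTrajectory,
    ReachParams,
    imu_to_csv,
    simulate_session,
    trajectory_to_csv,
)
from .camera import joints2d_to_csv
from .regressors import (
    ModelSpec,
    NeuralRegressor,
    TrainConfig,
    TrainedModel,
    build_model,
    predict,
    train,
)

__all__ = [
    "ExperimentConfig",
    "ResultsTable",
    "ViewData",
    "stage_seed",
    "simulate_view",
    "assemble_datasets",
    "run_experiment1",
    "run_experiment2",
    "generate_fixtures",
]

log = logging.getLogger("camimu")

#: fixed stage table of the seed-derivation scheme
_STAGES = {
    "simulate": 0,
    "project": 1,
    "render": 2,
    "train": 3,
    "unknown": 4,
    "fixtures": 5,
}


def stage_seed(master: int, stage: str, index: int = 0) -> int:
    """Derive the sub-seed of a named pipeline stage from the master seed."""
    ss = np.random.SeedSequence([int(master), _STAGES[stage], int(index)])
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass
class ExperimentConfig:
    """Everything a run needs; YAML-serializable with embedded defaults."""

    # recording geometry
    train_views: tuple[float, ...] = (0.0, 30.0)
    test_view: float = 15.0
    cycles_per_view: int = 50
    test_cycles: int = 10
    camera_distance: float = 2.0
    # simulator (cycle cadence at desk scale: 1 s holds between transports)
    reach: dict = field(default_factory=dict)
    pixel_noise_sd: float = 2.0
    depth_noise_sd: float = 0.01
    dropout_rate: float = 0.05
    imu_noise_sd: float = 0.05
    # features
    lift_k: int = 3
    window: int = 25
    stride: int = 1
    feature_modes: tuple[str, ...] = ("3d", "2d")
    model_kinds: tuple[str, ...] = ("DNN", "CNN", "DBLSTM")
    # training
    split_ratio: float = 0.9
    profile: str = "desk"
    learning_rate: float = 5e-4
    batch_size: int = 256
    epochs: int = 50
    patience: int = 10
    val_fraction: float = 0.1
    # bookkeeping
    seed: int = 1
    outdir: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.split_ratio < 1.0):
            raise ConfigError("split_ratio must lie in (0, 1)")
        if self.test_view in tuple(self.train_views):
            raise ConfigError("training views and the unknown test view must be disjoint")

    def reach_params(self) -> ReachParams:
        base = {"hold_start_s": 1.0}
        base.update(self.reach)
        return ReachParams(**base)

    def train_config(self) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            epochs=self.epochs,
            seed=stage_seed(self.seed, "train"),
            patience=self.patience,
            val_fraction=self.val_fraction,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["train_views"] = list(self.train_views)
        d["feature_modes"] = list(self.feature_modes)
        d["model_kinds"] = list(self.model_kinds)
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, path_or_text) -> "ExperimentConfig":
        text = str(path_or_text)
        if "\n" not in text and Path(text).exists():
            text = Path(text).read_text()
        d = yaml.safe_load(text) or {}
        for key in ("train_views", "feature_modes", "model_kinds"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha1(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class ViewData:
    """One synthetic recording: motion, IMU target and both feature series."""

    view: float
    traj: JointTrajectory
    imu: IMUTarget
    feats: dict[str, FeatureSeries]  # keys "2d", "3d"


def simulate_view(cfg: ExperimentConfig, view: float, n_cycles: int, seed: int) -> ViewData:
    """Simulate, record and featurize one session seen from ``view`` degrees."""
    t0 = time.perf_counter()
    params = cfg.reach_params()
    traj, imu = simulate_session(params, n_cycles, seed, imu_noise_sd=cfg.imu_noise_sd)
    cam = make_camera(view, distance=cfg.camera_distance)
    j2d = project_joints(traj, cam, pixel_noise_sd=cfg.pixel_noise_sd,
                         seed=stage_seed(seed, "project"))
    render_seeds = np.random.default_rng(stage_seed(seed, "render")).integers(
        0, 2**31, traj.n_frames
    )

    def frames():
        for i in range(traj.n_frames):
            pos = {j: traj.positions[j][i] for j in traj.positions}
            yield render_point_cloud(
                pos, cam,
                depth_noise_sd=cfg.depth_noise_sd,
                dropout_rate=cfg.dropout_rate,
                seed=int(render_seeds[i]),
            )

    j3d = lift_to_3d(j2d, frames(), cam, k=cfg.lift_k)
    feats = {"2d": features_2d(j2d), "3d": features_3d(j3d)}
    log.info("view %.0f°: %d frames simulated+lifted in %.1f s",
             view, traj.n_frames, time.perf_counter() - t0)
    return ViewData(view=view, traj=traj, imu=imu, feats=feats)


def simulate_train_views(cfg: ExperimentConfig) -> list[ViewData]:
    return [
        simulate_view(cfg, v, cfg.cycles_per_view, stage_seed(cfg.seed, "simulate", i))
        for i, v in enumerate(cfg.train_views)
    ]


def simulate_unknown_view(cfg: ExperimentConfig) -> ViewData:
    return simulate_view(cfg, cfg.test_view, cfg.test_cycles,
                         stage_seed(cfg.seed, "unknown"))


def _concat_windows(parts: list[WindowedDataset], window: int, stride: int) -> WindowedDataset:
    return WindowedDataset(
        X=np.concatenate([p.X for p in parts], axis=0),
        y=np.concatenate([p.y for p in parts], axis=0),
        centers=np.concatenate([p.centers for p in parts]),
        window=window,
        stride=stride,
    )


def assemble_datasets(
    views: list[ViewData],
    mode: str,
    cfg: ExperimentConfig,
) -> tuple[WindowedDataset, WindowedDataset, NormStats]:
    """Known-view train and held-out test windows plus the normalization
    statistics, with frame-level contiguous splits per view.

    Within each view's frame series the first ``split_ratio`` fraction feeds
    training (normalization statistics are fit on those frames only) and the
    final fraction is the known-view test block; ``window`` frames are
    dropped at the boundary so no test frame is visible to any training
    window.
    """
    train_parts_raw: list[np.ndarray] = []
    for vd in views:
        cut = int(vd.feats[mode].n_frames * cfg.split_ratio)
        train_parts_raw.append(vd.feats[mode].values[: cut - cfg.window])
    stats = NormStats.fit(np.concatenate(train_parts_raw, axis=0))

    train_parts, test_parts = [], []
    for vd in views:
        vals = vd.feats[mode].values
        cut = int(len(vals) * cfg.split_ratio)
        tr = stats.apply(vals[: cut - cfg.window])
        te = stats.apply(vals[cut:])
        train_parts.append(
            window_series(tr, vd.imu.acc[: cut - cfg.window], cfg.window, cfg.stride)
        )
        test_parts.append(
            window_series(te, vd.imu.acc[cut:], cfg.window, cfg.stride)
        )
    return (
        _concat_windows(train_parts, cfg.window, cfg.stride),
        _concat_windows(test_parts, cfg.window, cfg.stride),
        stats,
    )


def unknown_view_windows(
    vd: ViewData, mode: str, stats: NormStats, cfg: ExperimentConfig
) -> WindowedDataset:
    """Window the unseen view with the training normalization statistics."""
    vals = stats.apply(vd.feats[mode].values)
    return window_series(vals, vd.imu.acc, cfg.window, cfg.stride)


@dataclass
class ResultsTable:
    """Long-format metric table plus provenance (seed, config hash)."""

    df: pd.DataFrame
    seed: int
    config_hash: str

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    def to_json(self, path=None) -> str:
        payload = {
            "seed": self.seed,
            "config_hash": self.config_hash,
            "rows": self.df.to_dict(orient="records"),
        }
        s = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(s)
        return s


def _metric_rows(experiment: str, mode: str, kind: str, condition: str,
                 report) -> list[dict]:
    return [
        {
            "experiment": experiment,
            "feature_mode": mode,
            "model": kind,
            "view_condition": condition,
            "axis": ax,
            "rmse": report.rmse[ax],
            "prmse": report.prmse[ax],
            "cmc": report.cmc[ax],
            "cmc_band": report.cmc_band[ax],
        }
        for ax in AXES
    ]


def _train_and_eval(
    kind: str,
    mode: str,
    train_ds: WindowedDataset,
    cfg: ExperimentConfig,
    stats: NormStats,
    model_seed_index: int = 0,
) -> TrainedModel:
    spec = ModelSpec(
        kind=kind,
        input_dim=train_ds.X.shape[2],
        window=cfg.window,
        scale_profile=cfg.profile,
    )
    model = build_model(spec, seed=stage_seed(cfg.seed, "train", model_seed_index))
    log.info("training %s (%s features, %s profile): %d windows, %d parameters",
             kind, mode, cfg.profile, len(train_ds), model.n_params)
    t0 = time.perf_counter()
    trained = train(model, train_ds, cfg.train_config(), norm_stats=stats)
    log.info("trained %s in %.1f s (%d epochs, best val MSE %.5f)",
             kind, time.perf_counter() - t0, len(trained.history),
             min(h["val_mse"] for h in trained.history))
    return trained


def run_experiment1(
    cfg: ExperimentConfig,
    views: list[ViewData] | None = None,
) -> ResultsTable:
    """Model comparison on 3D features at the known views."""
    views = views if views is not None else simulate_train_views(cfg)
    train_ds, test_ds, stats = assemble_datasets(views, "3d", cfg)
    rows: list[dict] = []
    for i, kind in enumerate(cfg.model_kinds):
        trained = _train_and_eval(kind, "3d", train_ds, cfg, stats, model_seed_index=i)
        report = evaluate(test_ds.y, predict(trained, test_ds))
        rows += _metric_rows("exp1", "3d", kind, "known", report)
    return ResultsTable(df=pd.DataFrame(rows), seed=cfg.seed,
                        config_hash=cfg.config_hash())


def run_experiment2(
    cfg: ExperimentConfig,
    views: list[ViewData] | None = None,
    unknown: ViewData | None = None,
    return_artifacts: bool = False,
):
    """2D-vs-3D feature comparison, known and unknown views, DBLSTM only."""
    views = views if views is not None else simulate_train_views(cfg)
    unknown = unknown if unknown is not None else simulate_unknown_view(cfg)
    rows: list[dict] = []
    artifacts: dict = {"views": views, "unknown": unknown}
    for mi, mode in enumerate(cfg.feature_modes):
        train_ds, test_ds, stats = assemble_datasets(views, mode, cfg)
        trained = _train_and_eval("DBLSTM", mode, train_ds, cfg, stats,
                                  model_seed_index=10 + mi)
        known_report = evaluate(test_ds.y, predict(trained, test_ds))
        rows += _metric_rows("exp2", mode, "DBLSTM", "known", known_report)
        unk_ds = unknown_view_windows(unknown, mode, stats, cfg)
        unk_report = evaluate(unk_ds.y, predict(trained, unk_ds))
        rows += _metric_rows("exp2", mode, "DBLSTM", "unknown", unk_report)
        artifacts[mode] = {
            "trained": trained,
            "stats": stats,
            "known_report": known_report,
            "unknown_report": unk_report,
        }
    table = ResultsTable(df=pd.DataFrame(rows), seed=cfg.seed,
                         config_hash=cfg.config_hash())
    return (table, artifacts) if return_artifacts else table


# ---------------------------------------------------------------------------
# on-disk fixture sets


def generate_fixtures(size: str, seed: int, outdir) -> Path:
    """Write a self-contained synthetic dataset directory.

    ``tiny`` (3 cycles/view) serves unit tests; ``demo`` (50 cycles/view)
    serves full-scale runs.  Per-frame point clouds are written as binary
    PLY for a regular subsample of frames (every 50th for tiny, every 200th
    for demo) to keep the directory small; the manifest records exactly
    which frames carry clouds along with row and point counts.
    """
    sizes = {"tiny": (3, 50), "demo": (50, 200)}
    if size not in sizes:
        raise ConfigError(f"size must be one of {sorted(sizes)}, got {size!r}")
    n_cycles, ply_stride = sizes[size]
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = ExperimentConfig(seed=seed)
    manifest: dict = {"size": size, "seed": seed, "views": {}}
    for i, view in enumerate(list(cfg.train_views) + [cfg.test_view]):
        vseed = stage_seed(seed, "fixtures", i)
        params = cfg.reach_params()
        traj, imu = simulate_session(params, n_cycles, vseed,
                                     imu_noise_sd=cfg.imu_noise_sd)
        cam = make_camera(view, distance=cfg.camera_distance)
        j2d = project_joints(traj, cam, pixel_noise_sd=cfg.pixel_noise_sd,
                             seed=stage_seed(vseed, "project"))
        tag = f"view{int(view):02d}"
        trajectory_to_csv(traj, outdir / f"{tag}_trajectory.csv")
        imu_to_csv(imu, outdir / f"{tag}_imu.csv")
        joints2d_to_csv(j2d, outdir / f"{tag}_joints2d.csv", fps=traj.fps)
        render_seeds = np.random.default_rng(stage_seed(vseed, "render")).integers(
            0, 2**31, traj.n_frames
        )
        cloud_dir = outdir / f"{tag}_clouds"
        cloud_dir.mkdir(exist_ok=True)
        clouds = {}
        for fi in range(0, traj.n_frames, ply_stride):
            pos = {j: traj.positions[j][fi] for j in traj.positions}
            frame = render_point_cloud(
                pos, cam, depth_noise_sd=cfg.depth_noise_sd,
                dropout_rate=cfg.dropout_rate, seed=int(render_seeds[fi]),
            )
            ply_path = cloud_dir / f"frame{fi:06d}.ply"
            ply_write(frame, ply_path)
            clouds[str(fi)] = {"file": str(ply_path.relative_to(outdir)),
                               "n_points": frame.n_valid}
        manifest["views"][tag] = {
            "view_angle": view,
            "n_frames": traj.n_frames,
            "trajectory_csv": f"{tag}_trajectory.csv",
            "imu_csv": f"{tag}_imu.csv",
            "joints2d_csv": f"{tag}_joints2d.csv",
            "clouds": clouds,
        }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return outdir
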