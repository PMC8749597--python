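"""Joint features for acceleration regression.

Two feature families are produced from the four tracked joints, both using
the left shoulder (LS) as the reference point:

* 2D features (9 values/frame): the pixel-space vectors RS−LS, LE−LS, LW−LS
  and their three Euclidean norms.
* 3D features (12 values/frame): the same construction on camera-frame
  meter coordinates.

The 3D joint coordinates come from a lifting step ("3D generator"): each 2D
joint estimate picks up a depth from the local distribution of the point
cloud — the median of valid depths in a (2k+1)² pixel window around the
joint — and is back-projected through the intrinsics.  The median makes the
lookup robust to background bleed-through at silhouette edges.

The distances in the 3D features are invariant to the camera viewpoint
(rigid rotations preserve norms), while every component of the 2D features
changes with the view — the geometric reason 3D features generalize to
camera angles unseen in training.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .camera import CameraModel, Joints2D, Joints3D, ToFFrame, back_project
from .errors import EmptyDatasetError, FeatureError, MissingDepthError
from .motion import JOINTS, IMUTarget

__all__ = [
    "NormStats",
    "FeatureSeries",
    "WindowedDataset",
    "lift_frame",
    "lift_to_3d",
    "features_2d",
    "features_3d",
    "window_series",
    "feature_names",
    "features_to_csv",
    "features_from_csv",
]

_REL_JOINTS = ("RS", "LE", "LW")  # relative to LS, in this order


def feature_names(kind: str) -> list[str]:
    """Column names of the per-frame feature vector, in storage order."""
    axes = "xy" if kind == "2d" else "xyz"
    names = [f"rel_{j}_{ax}" for j in _REL_JOINTS for ax in axes]
    names += [f"d_{j}" for j in _REL_JOINTS]
    return names


@dataclass
class NormStats:
    """Per-dimension z-score statistics, fit on training data only."""

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, values: np.ndarray) -> "NormStats":
        std = values.std(axis=0)
        return cls(mean=values.mean(axis=0), std=np.maximum(std, 1e-8))

    def apply(self, values: np.ndarray) -> np.ndarray:
        return (values - self.mean) / self.std

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "std": self.std.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "NormStats":
        return cls(mean=np.asarray(d["mean"], float), std=np.asarray(d["std"], float))


@dataclass
class FeatureSeries:
    """Per-frame feature vectors plus (optional) normalization statistics."""

    values: np.ndarray
    kind: str  # "2d" | "3d"
    stats: NormStats | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = 9 if self.kind == "2d" else 12
        if self.kind not in ("2d", "3d"):
            raise ValueError(f"kind must be '2d' or '3d', got {self.kind!r}")
        if self.values.ndim != 2 or self.values.shape[1] != expected:
            raise FeatureError(
                f"{self.kind} features must be (T, {expected}), got {self.values.shape}"
            )

    @property
    def n_frames(self) -> int:
        return len(self.values)

    @property
    def dim(self) -> int:
        return self.values.shape[1]

    def normalized(self) -> np.ndarray:
        if self.stats is None:
            raise ValueError("no normalization statistics attached")
        return self.stats.apply(self.values)


# ---------------------------------------------------------------------------
# 2D -> 3D lifting


def lift_frame(
    uv: np.ndarray, frame: ToFFrame, cam: CameraModel, k: int = 3
) -> np.ndarray:
    """Lift one frame's (4, 2) pixel joints to (4, 3) camera-frame meters.

    Raises :class:`MissingDepthError` naming the joint if no valid depth
    pixel exists in its window.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    H, W = frame.valid.shape
    out = np.empty((4, 3))
    for idx, joint in enumerate(JOINTS):
        u, v = uv[idx]
        ui, vi = int(round(u)), int(round(v))
        r0, r1 = max(vi - k, 0), min(vi + k + 1, H)
        c0, c1 = max(ui - k, 0), min(ui + k + 1, W)
        if r0 >= r1 or c0 >= c1:
            raise MissingDepthError(f"joint {joint} projected outside the image")
        patch_valid = frame.valid[r0:r1, c0:c1]
        if not patch_valid.any():
            raise MissingDepthError(f"no valid depth around joint {joint}")
        depths = frame.points[r0:r1, c0:c1, 2][patch_valid]
        out[idx] = back_project(u, v, float(np.median(depths)), cam)
    return out


def lift_to_3d(
    j2d: Joints2D,
    frames: Iterable[ToFFrame] | Iterator[ToFFrame],
    cam: CameraModel,
    k: int = 3,
) -> Joints3D:
    """Lift a whole 2D joint series against its per-frame point clouds.

    Frames where a joint has no valid depth are filled by linear temporal
    interpolation of that joint's lifted coordinates (nearest value at the
    series ends).  Raises :class:`MissingDepthError` if a joint has no depth
    on any frame.
    """
    xyz = np.full((j2d.n_frames, 4, 3), np.nan)
    for i, frame in enumerate(frames):
        try:
            xyz[i] = lift_frame(j2d.uv[i], frame, cam, k=k)
        except MissingDepthError:
            pass  # interpolated below
    t = np.arange(len(xyz), dtype=float)
    for jidx in range(4):
        good = np.isfinite(xyz[:, jidx, 0])
        if not good.any():
            raise MissingDepthError(
                f"joint {JOINTS[jidx]} has no depth support on any frame"
            )
        if not good.all():
            for ax in range(3):
                xyz[~good, jidx, ax] = np.interp(t[~good], t[good], xyz[good, jidx, ax])
    return Joints3D(xyz=xyz)


# ---------------------------------------------------------------------------
# feature vectors


def _relative_features(coords: np.ndarray) -> np.ndarray:
    """Shared core: joint-minus-LS vectors and their norms.

    ``coords`` is (T, 4, C) in canonical joint order; the output is
    (T, 3*C + 3) laid out as rel_RS, rel_LE, rel_LW then d_RS, d_LE, d_LW.
    """
    if not np.isfinite(coords).all():
        raise FeatureError("joint coordinates contain non-finite values")
    ls = coords[:, JOINTS.index("LS")]
    rels = [coords[:, JOINTS.index(j)] - ls for j in _REL_JOINTS]
    rel = np.concatenate(rels, axis=1)
    dists = np.stack([np.linalg.norm(r, axis=1) for r in rels], axis=1)
    return np.concatenate([rel, dists], axis=1)


def features_2d(j2d: Joints2D) -> FeatureSeries:
    """9-dim pixel-space features per frame (relative vectors + distances)."""
    return FeatureSeries(values=_relative_features(j2d.uv), kind="2d")


def features_3d(j3d: Joints3D) -> FeatureSeries:
    """12-dim camera-frame features per frame (relative vectors + distances)."""
    return FeatureSeries(values=_relative_features(j3d.xyz), kind="3d")


# ---------------------------------------------------------------------------
# supervised windowing


@dataclass
class WindowedDataset:
    """Overlapping windows of normalized features with center-frame targets.

    ``X`` is (N, window, D); ``y`` is (N, 3) — the acceleration of the
    window's center frame; ``centers`` holds the source frame index of each
    target so provenance of every example is traceable.
    """

    X: np.ndarray
    y: np.ndarray | None
    centers: np.ndarray
    window: int
    stride: int

    def __len__(self) -> int:
        return len(self.X)


def window_series(
    features: FeatureSeries | np.ndarray,
    targets: IMUTarget | np.ndarray | None,
    window: int = 25,
    stride: int = 1,
    normalized: bool = True,
) -> WindowedDataset:
    """Slice a feature series into overlapping supervised windows.

    The number of windows is floor((T − window)/stride) + 1; the regression
    target of each window is the acceleration at its center frame, so a
    bidirectional model sees both the past and the future of the target
    instant.  Raises :class:`EmptyDatasetError` if the series is shorter than
    one window.
    """
    if window < 1 or stride < 1:
        raise ValueError("window and stride must be >= 1")
    if isinstance(features, FeatureSeries):
        vals = features.normalized() if normalized and features.stats else features.values
    else:
        vals = np.asarray(features, dtype=float)
    T = len(vals)
    if T < window:
        raise EmptyDatasetError(f"series of {T} frames is shorter than window {window}")
    n = (T - window) // stride + 1
    starts = np.arange(n) * stride
    idx = starts[:, None] + np.arange(window)[None, :]
    X = vals[idx]
    centers = starts + window // 2
    y = None
    if targets is not None:
        acc = targets.acc if isinstance(targets, IMUTarget) else np.asarray(targets, float)
        y = acc[centers]
    return WindowedDataset(X=X, y=y, centers=centers, window=window, stride=stride)


# ---------------------------------------------------------------------------
# interchange formats


def features_to_csv(series: FeatureSeries, csv_path, sidecar_path=None) -> None:
    """One row per frame, named columns; normalization stats go to a JSON
    sidecar (``<csv>.stats.json`` by default) when present."""
    df = pd.DataFrame(series.values, columns=feature_names(series.kind))
    df.to_csv(csv_path, index=False)
    if series.stats is not None:
        sidecar = sidecar_path or f"{csv_path}.stats.json"
        with open(sidecar, "w") as fh:
            json.dump({"kind": series.kind, **series.stats.to_dict()}, fh)


def features_from_csv(csv_path, sidecar_path=None) -> FeatureSeries:
    df = pd.read_csv(csv_path)
    kind = "2d" if df.shape[1] == 9 else "3d"
    stats = None
    sidecar = sidecar_path or f"{csv_path}.stats.json"
    try:
        with open(sidecar) as fh:
            d = json.load(fh)
        stats = NormStats.from_dict(d)
        kind = d.get("kind", kind)
    except FileNotFoundError:
        pass
    return FeatureSeries(values=df.to_numpy(dtype=float), kind=kind, stats=stats)
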