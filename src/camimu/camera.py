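"""Time-of-flight camera emulation.

Two sensor products are emulated per frame, mirroring what a ToF device
delivers: noisy 2D joint estimates (the stand-in for a 2D pose estimator run
on the amplitude image) and a camera-frame point cloud obtained by casting a
ray through every pixel against a capsule proxy of the subject's body
(three limb capsules RS–LS, LS–LE, LE–LW plus a thicker torso capsule).

Conventions: pixels are 0-based, origin top-left, u right, v down; depth is
the z coordinate along the optical axis (not ray length).  The camera sits on
a circle around the subject at a configurable azimuth ``view_angle`` (0° =
frontal), at fixed distance and height, looking at the torso center, so the
same motion can be rendered from the frontal, 15° and 30° stations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh

from .errors import ProjectionError
from .motion import JOINTS, JointTrajectory

__all__ = [
    "CameraModel",
    "ToFFrame",
    "Joints2D",
    "Joints3D",
    "make_camera",
    "world_to_camera",
    "camera_to_world",
    "project_joints",
    "back_project",
    "render_point_cloud",
    "ply_write",
    "ply_read",
    "joints2d_to_csv",
    "joints2d_from_csv",
]

#: default body-proxy radii, meters
CAPSULE_RADIUS = 0.05
TORSO_RADIUS = 0.12
TORSO_DROP = 0.45


@dataclass
class CameraModel:
    """Pinhole intrinsics plus the circular-rig extrinsics.

    ``rotation`` columns are the camera's right / down / forward axes in
    world coordinates; ``center`` is the camera position in the world frame.
    """

    fx: float = 210.0
    fy: float = 210.0
    cx: float = 111.5
    cy: float = 85.5
    width: int = 224
    height: int = 172
    view_angle: float = 0.0
    distance: float = 2.0
    camera_height: float = 0.4
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ValueError("principal point outside the image")
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.center = np.asarray(self.center, dtype=float)

    @property
    def optical_axis(self) -> np.ndarray:
        """Camera forward (+z) direction in world coordinates."""
        return self.rotation[:, 2]


def view_rotation(view_angle_deg: float) -> np.ndarray:
    """Rotation about the world vertical axis used to place a camera station."""
    a = np.deg2rad(view_angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def make_camera(
    view_angle: float = 0.0,
    distance: float = 2.0,
    camera_height: float = 0.4,
    **intrinsics,
) -> CameraModel:
    """Place a camera on the rig circle at ``view_angle`` degrees of azimuth.

    The camera center is the frontal station rotated about the world vertical
    axis; the camera looks at the torso center on that axis, so the frontal
    station's optical axis is antiparallel to world X.
    """
    if distance <= 0:
        raise ValueError("distance must be > 0")
    cam = CameraModel(view_angle=view_angle, distance=distance,
                      camera_height=camera_height, **intrinsics)
    center = view_rotation(view_angle) @ np.array([distance, 0.0, camera_height])
    look_at = np.array([0.0, 0.0, camera_height])
    forward = look_at - center
    forward = forward / np.linalg.norm(forward)
    up = np.array([0.0, 0.0, 1.0])
    right = np.cross(forward, up)
    right = right / np.linalg.norm(right)
    down = np.cross(forward, right)
    cam.rotation = np.column_stack([right, down, forward])
    cam.center = center
    return cam


def world_to_camera(p: np.ndarray, cam: CameraModel) -> np.ndarray:
    """Rigid transform of world points (..., 3) into the camera frame."""
    return (np.asarray(p, dtype=float) - cam.center) @ cam.rotation


def camera_to_world(p: np.ndarray, cam: CameraModel) -> np.ndarray:
    """Inverse rigid transform; exact round trip with :func:`world_to_camera`."""
    return np.asarray(p, dtype=float) @ cam.rotation.T + cam.center


@dataclass
class Joints2D:
    """Pixel-space joint estimates over T frames, canonical joint order.

    ``uv`` is (T, 4, 2) pixels; ``confidence`` is (T, 4) in [0, 1].  Pixel
    coordinates may fall outside the image; those detections carry reduced
    confidence rather than being dropped.
    """

    uv: np.ndarray
    confidence: np.ndarray

    def __post_init__(self) -> None:
        self.uv = np.asarray(self.uv, dtype=float)
        self.confidence = np.asarray(self.confidence, dtype=float)
        if self.uv.shape[-2:] != (4, 2):
            raise ValueError(f"uv must be (T, 4, 2), got {self.uv.shape}")
        if ((self.confidence < 0) | (self.confidence > 1)).any():
            raise ValueError("confidences must lie in [0, 1]")
        if not np.isfinite(self.uv).all():
            raise ValueError("pixel coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return len(self.uv)

    def frame(self, i: int) -> dict[str, np.ndarray]:
        return {j: self.uv[i, k] for k, j in enumerate(JOINTS)}


@dataclass
class Joints3D:
    """Camera-frame joint positions over T frames; ``xyz`` is (T, 4, 3) m."""

    xyz: np.ndarray

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape[-2:] != (4, 3):
            raise ValueError(f"xyz must be (T, 4, 3), got {self.xyz.shape}")
        if not np.isfinite(self.xyz).all():
            raise ValueError("joint positions must be finite")

    @property
    def n_frames(self) -> int:
        return len(self.xyz)

    def frame(self, i: int) -> dict[str, np.ndarray]:
        return {j: self.xyz[i, k] for k, j in enumerate(JOINTS)}


@dataclass
class ToFFrame:
    """One depth frame: a (H, W, 3) camera-frame point grid, a validity mask
    and an optional amplitude channel."""

    points: np.ndarray
    valid: np.ndarray
    amplitude: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.points.shape[:2] != self.valid.shape:
            raise ValueError("points grid and valid mask disagree in shape")
        if self.valid.any() and (self.points[self.valid][:, 2] <= 0).any():
            raise ValueError("valid points must have positive depth")

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def valid_points(self) -> np.ndarray:
        return self.points[self.valid]


def project_joints(
    traj: JointTrajectory,
    cam: CameraModel,
    pixel_noise_sd: float = 2.0,
    seed: int = 0,
) -> Joints2D:
    """Pinhole-project the four joints of every frame to pixels.

    Emulates an upstream 2D pose estimator: perfect perspective projection
    plus i.i.d. Gaussian pixel noise.  Confidence is 1 for detections inside
    the image and 0.2 for those projected outside.  Raises
    :class:`ProjectionError` if a joint falls behind the camera.
    """
    if pixel_noise_sd < 0:
        raise ValueError("pixel_noise_sd must be >= 0")
    pw = traj.stacked()  # (T, 4, 3)
    pc = world_to_camera(pw.reshape(-1, 3), cam).reshape(pw.shape)
    z = pc[..., 2]
    if (z <= 0).any():
        bad = int(np.argwhere(z <= 0)[0][0])
        raise ProjectionError(f"joint behind camera at frame {bad}")
    u = cam.fx * pc[..., 0] / z + cam.cx
    v = cam.fy * pc[..., 1] / z + cam.cy
    uv = np.stack([u, v], axis=-1)
    if pixel_noise_sd > 0:
        uv = uv + np.random.default_rng(seed).normal(0.0, pixel_noise_sd, uv.shape)
    inside = (
        (uv[..., 0] >= 0) & (uv[..., 0] < cam.width)
        & (uv[..., 1] >= 0) & (uv[..., 1] < cam.height)
    )
    conf = np.where(inside, 1.0, 0.2)
    return Joints2D(uv=uv, confidence=conf)


def back_project(u, v, depth, cam: CameraModel) -> np.ndarray:
    """Invert the pinhole projection: pixel + depth → camera-frame point."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    depth = np.asarray(depth, dtype=float)
    x = (u - cam.cx) / cam.fx * depth
    y = (v - cam.cy) / cam.fy * depth
    return np.stack(np.broadcast_arrays(x, y, depth), axis=-1)


def _body_capsules(frame_positions: dict[str, np.ndarray],
                   capsule_radius: float) -> list[tuple[np.ndarray, np.ndarray, float]]:
    rs, ls = frame_positions["RS"], frame_positions["LS"]
    le, lw = frame_positions["LE"], frame_positions["LW"]
    neck = 0.5 * (rs + ls)
    hip = neck - np.array([0.0, 0.0, TORSO_DROP])
    return [
        (rs, ls, capsule_radius),
        (ls, le, capsule_radius),
        (le, lw, capsule_radius),
        (neck, hip, TORSO_RADIUS),
    ]


def _ray_capsule(dirs: np.ndarray, a: np.ndarray, b: np.ndarray, r: float) -> np.ndarray:
    """Smallest positive ray parameter t for rays from the origin along
    ``dirs`` hitting the capsule (a, b, r); inf where there is no hit.

    Rays are parameterized p(t) = t·d with unnormalized d, so with d_z = 1
    the returned t is directly the z-depth of the hit.
    """
    ba = b - a
    oa = -a
    baba = float(ba @ ba)
    t_best = np.full(len(dirs), np.inf)
    if baba > 1e-18:
        bard = dirs @ ba
        baoa = float(oa @ ba)
        rdoa = dirs @ oa
        rdrd = np.einsum("ij,ij->i", dirs, dirs)
        oaoa = float(oa @ oa)
        A = baba * rdrd - bard**2
        B = baba * rdoa - baoa * bard
        C = baba * oaoa - baoa**2 - r * r * baba
        disc = B**2 - A * C
        ok = (disc >= 0) & (A > 1e-18)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = (-B - np.sqrt(np.where(ok, disc, 0.0))) / A
        y = baoa + t * bard
        body = ok & (t > 0) & (y > 0) & (y < baba)
        t_best = np.where(body, t, np.inf)
    # spherical end caps
    for p in (a, b):
        rdrd = np.einsum("ij,ij->i", dirs, dirs)
        bq = dirs @ (-p)
        cq = float(p @ p) - r * r
        disc = bq**2 - rdrd * cq
        ok = disc >= 0
        with np.errstate(invalid="ignore"):
            t = (-bq - np.sqrt(np.where(ok, disc, 0.0))) / rdrd
        hit = ok & (t > 0)
        t_best = np.minimum(t_best, np.where(hit, t, np.inf))
    return t_best


def render_point_cloud(
    frame_positions: dict[str, np.ndarray],
    cam: CameraModel,
    depth_noise_sd: float = 0.01,
    dropout_rate: float = 0.05,
    seed: int = 0,
    capsule_radius: float = CAPSULE_RADIUS,
    with_amplitude: bool = False,
) -> ToFFrame:
    """Ray-cast the capsule body proxy and return one depth frame.

    Per-pixel rays through the pixel centers are intersected with all body
    capsules; the nearest hit gives the depth.  Gaussian depth noise and a
    Bernoulli pixel dropout emulate ToF sensor error; background pixels are
    invalid.  An empty cloud is returned if the subject is out of frame.
    """
    if not (0.0 <= dropout_rate < 1.0):
        raise ValueError("dropout_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    caps_world = _body_capsules(frame_positions, capsule_radius)
    caps = [
        (world_to_camera(a, cam), world_to_camera(b, cam), r)
        for a, b, r in caps_world
    ]
    H, W = cam.height, cam.width
    points = np.zeros((H, W, 3), dtype=np.float32)
    valid = np.zeros((H, W), dtype=bool)
    amp = np.zeros((H, W), dtype=np.float32) if with_amplitude else None

    # bounding box of the projected capsules, padded by their radii
    ends = np.array([p for a, b, _ in caps for p in (a, b)])
    if (ends[:, 2] <= 0).all():
        return ToFFrame(points=points, valid=valid, amplitude=amp)
    infront = ends[ends[:, 2] > 0]
    maxr = max(r for _, _, r in caps)
    zmin = max(float(infront[:, 2].min()) - maxr, 1e-3)
    us = cam.fx * infront[:, 0] / infront[:, 2] + cam.cx
    vs = cam.fy * infront[:, 1] / infront[:, 2] + cam.cy
    pad_u = maxr * cam.fx / zmin + 2
    pad_v = maxr * cam.fy / zmin + 2
    u0 = max(int(np.floor(us.min() - pad_u)), 0)
    u1 = min(int(np.ceil(us.max() + pad_u)) + 1, W)
    v0 = max(int(np.floor(vs.min() - pad_v)), 0)
    v1 = min(int(np.ceil(vs.max() + pad_v)) + 1, H)
    if u0 >= u1 or v0 >= v1:
        return ToFFrame(points=points, valid=valid, amplitude=amp)

    uu, vv = np.meshgrid(np.arange(u0, u1), np.arange(v0, v1))
    dirs = np.stack(
        [(uu.ravel() - cam.cx) / cam.fx, (vv.ravel() - cam.cy) / cam.fy,
         np.ones(uu.size)], axis=1,
    )
    t = np.full(uu.size, np.inf)
    for a, b, r in caps:
        t = np.minimum(t, _ray_capsule(dirs, a, b, r))
    hit = np.isfinite(t)
    if depth_noise_sd > 0:
        t = t + np.where(hit, rng.normal(0.0, depth_noise_sd, t.shape), 0.0)
    hit &= t > 0
    if dropout_rate > 0:
        hit &= rng.random(t.shape) >= dropout_rate
    pts = dirs * t[:, None]
    sub_pts = np.where(hit[:, None], pts, 0.0).reshape(v1 - v0, u1 - u0, 3)
    points[v0:v1, u0:u1] = sub_pts.astype(np.float32)
    valid[v0:v1, u0:u1] = hit.reshape(v1 - v0, u1 - u0)
    if with_amplitude:
        with np.errstate(divide="ignore"):
            a_img = np.where(hit, 1.0 / np.maximum(t, 1e-6) ** 2, 0.0)
        amp[v0:v1, u0:u1] = a_img.reshape(v1 - v0, u1 - u0).astype(np.float32)
    return ToFFrame(points=points, valid=valid, amplitude=amp)


# ---------------------------------------------------------------------------
# interchange formats


def ply_write(frame: ToFFrame | np.ndarray, path) -> None:
    """Write the valid points of a frame (or a raw (N, 3) array) as binary
    little-endian PLY with float x/y/z properties."""
    pts = frame.valid_points() if isinstance(frame, ToFFrame) else np.asarray(frame)
    trimesh.PointCloud(pts.reshape(-1, 3).astype(np.float64)).export(str(path))


def ply_read(path) -> np.ndarray:
    """Read a PLY point cloud back as an (N, 3) float array."""
    return np.asarray(trimesh.load(str(path)).vertices, dtype=float)


def joints2d_to_csv(j2d: Joints2D, path, fps: float = 50.0) -> None:
    t = np.arange(j2d.n_frames, dtype=float) / fps
    cols: dict[str, np.ndarray] = {"t": t}
    for k, j in enumerate(JOINTS):
        cols[f"{j}_u"] = j2d.uv[:, k, 0]
        cols[f"{j}_v"] = j2d.uv[:, k, 1]
        cols[f"{j}_conf"] = j2d.confidence[:, k]
    pd.DataFrame(cols).to_csv(path, index=False)


def joints2d_from_csv(path) -> Joints2D:
    df = pd.read_csv(path)
    uv = np.stack(
        [df[[f"{j}_u", f"{j}_v"]].to_numpy(dtype=float) for j in JOINTS], axis=1
    )
    conf = np.stack([df[f"{j}_conf"].to_numpy(dtype=float) for j in JOINTS], axis=1)
    return Joints2D(uv=uv, confidence=conf)
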