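"""Synthetic arm-reaching motion and the wrist-acceleration ground truth.

The simulator stands in for a recorded session: a seated subject repeatedly
reaches for a cup on a table, raises it to mouth height and puts it back.
Four upper-body joints are tracked — right shoulder (RS), left shoulder (LS),
left elbow (LE) and left wrist (LW) — in a world frame with Z up, X toward
the frontal camera and origin at the subject's seat center.  Wrist transport
follows a minimum-jerk (quintic) profile, the standard kinematic model of
point-to-point human reaching: zero velocity and acceleration at both ends of
each transport.  The elbow is placed by exact two-segment inverse kinematics
(elbow-down branch), so upper-arm and forearm lengths are conserved to
machine precision on every frame.

The regression target G = (Accx, Accy, Accz) is the tri-axial wrist
acceleration a wrist-worn IMU would report after flat calibration: the pure
kinematic second derivative of the wrist position in world axes (no gravity
component), obtained by second-order finite differences plus optional
Gaussian sensor noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import InsufficientLengthError, UnreachableTargetError

JOINTS = ("RS", "LS", "LE", "LW")

__all__ = [
    "JOINTS",
    "JointTrajectory",
    "ReachParams",
    "IMUTarget",
    "minimum_jerk",
    "minimum_jerk_acc_peak",
    "simulate_reach_cycle",
    "simulate_session",
    "derive_imu_target",
    "trajectory_to_csv",
    "trajectory_from_csv",
    "imu_to_csv",
    "imu_from_csv",
]


@dataclass
class JointTrajectory:
    """World-frame positions of the four tracked joints at fixed frame rate.

    ``positions`` maps each joint name to a ``(T, 3)`` float array in meters;
    ``timestamps`` is ``(T,)`` seconds, spaced exactly ``1/fps``.
    """

    timestamps: np.ndarray
    positions: dict[str, np.ndarray]
    fps: float = 50.0

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.positions = {j: np.asarray(p, dtype=float) for j, p in self.positions.items()}
        for j in JOINTS:
            if j not in self.positions:
                raise ValueError(f"missing joint {j!r}")
            if self.positions[j].shape != (self.n_frames, 3):
                raise ValueError(f"joint {j!r} has shape {self.positions[j].shape}")
            if not np.isfinite(self.positions[j]).all():
                raise ValueError(f"non-finite positions for joint {j!r}")

    @property
    def n_frames(self) -> int:
        return len(self.timestamps)

    def stacked(self) -> np.ndarray:
        """Positions as a ``(T, 4, 3)`` array in canonical joint order."""
        return np.stack([self.positions[j] for j in JOINTS], axis=1)

    def segment_lengths(self) -> dict[str, np.ndarray]:
        """Per-frame upper-arm and forearm lengths (rigid by construction)."""
        return {
            "upperarm": np.linalg.norm(self.positions["LS"] - self.positions["LE"], axis=1),
            "forearm": np.linalg.norm(self.positions["LE"] - self.positions["LW"], axis=1),
        }

    def rotated_about_z(self, angle_deg: float) -> "JointTrajectory":
        """Trajectory rigidly rotated about the world vertical axis."""
        a = np.deg2rad(angle_deg)
        c, s = np.cos(a), np.sin(a)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        return JointTrajectory(
            timestamps=self.timestamps.copy(),
            positions={j: p @ rot.T for j, p in self.positions.items()},
            fps=self.fps,
        )


@dataclass
class IMUTarget:
    """Per-frame wrist acceleration (Accx, Accy, Accz) in m/s², world axes."""

    acc: np.ndarray
    fps: float = 50.0

    def __post_init__(self) -> None:
        self.acc = np.asarray(self.acc, dtype=float)
        if self.acc.ndim != 2 or self.acc.shape[1] != 3:
            raise ValueError(f"acc must be (T, 3), got {self.acc.shape}")
        if not np.isfinite(self.acc).all():
            raise ValueError("non-finite acceleration values")

    @property
    def n_frames(self) -> int:
        return len(self.acc)


@dataclass
class ReachParams:
    """Geometry and timing of one cup-to-mouth reaching cycle.

    Defaults describe a seated adult with the cup within comfortable reach.
    ``hold_start_s`` is the stationary hold at the start of a cycle;
    transports use minimum-jerk profiles of the stated durations, with a
    short dwell at the cup and a hold at mouth height.  ``jitter_sd`` is the
    amplitude (m) of low-pass-filtered positional tremor added to the wrist
    path and shoulders.
    """

    hold_start_s: float = 5.0
    reach_duration_s: float = 1.2
    return_duration_s: float = 1.2
    n_cycles: int = 1
    cup_position: np.ndarray = field(default_factory=lambda: np.array([0.38, 0.18, 0.05]))
    mouth_height: float = 0.55
    shoulder_width: float = 0.36
    upperarm_len: float = 0.30
    forearm_len: float = 0.26
    jitter_sd: float = 0.001
    fps: float = 50.0
    # secondary timing/geometry (cycle cadence; configurable)
    dwell_s: float = 0.2
    mouth_hold_s: float = 0.4
    shoulder_height: float = 0.45
    wrist_rest: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.30, 0.02]))
    raise_fraction: float = 0.7

    def __post_init__(self) -> None:
        self.cup_position = np.asarray(self.cup_position, dtype=float)
        self.wrist_rest = np.asarray(self.wrist_rest, dtype=float)
        for name in ("upperarm_len", "forearm_len", "shoulder_width", "mouth_height"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("hold_start_s", "reach_duration_s", "return_duration_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")

    @property
    def left_shoulder(self) -> np.ndarray:
        return np.array([0.0, self.shoulder_width / 2.0, self.shoulder_height])

    @property
    def right_shoulder(self) -> np.ndarray:
        return np.array([0.0, -self.shoulder_width / 2.0, self.shoulder_height])

    @property
    def mouth_position(self) -> np.ndarray:
        """Where the cup is held at mouth height: raised and pulled inward."""
        return np.array([0.12, self.cup_position[1] - 0.03, self.mouth_height])


def minimum_jerk(tau: np.ndarray) -> np.ndarray:
    """Normalized quintic transport profile s(τ) = 10τ³ − 15τ⁴ + 6τ⁵.

    s(0)=0, s(1)=1 with zero velocity and acceleration at both ends.
    """
    tau = np.clip(np.asarray(tau, dtype=float), 0.0, 1.0)
    return tau**3 * (10.0 - 15.0 * tau + 6.0 * tau**2)


def minimum_jerk_acc_peak(amplitude: float, duration: float) -> float:
    """Peak acceleration of a minimum-jerk transport: (10/√3)·A/T²."""
    return 10.0 / np.sqrt(3.0) * amplitude / duration**2


def _elbow_position(
    shoulder: np.ndarray, wrist: np.ndarray, l1: float, l2: float
) -> np.ndarray:
    """Two-segment inverse kinematics, elbow-down branch.

    Places the elbow so that ‖shoulder−elbow‖ = l1 and ‖elbow−wrist‖ = l2
    exactly, with the elbow on the downward side of the shoulder–wrist axis.
    """
    sw = wrist - shoulder
    d = float(np.linalg.norm(sw))
    if d > l1 + l2 or d < abs(l1 - l2) or d == 0.0:
        raise UnreachableTargetError(
            f"wrist at distance {d:.4f} m from shoulder is outside the "
            f"[{abs(l1 - l2):.4f}, {l1 + l2:.4f}] m workspace"
        )
    u = sw / d
    a = (l1**2 - l2**2 + d**2) / (2.0 * d)
    h = np.sqrt(max(l1**2 - a**2, 0.0))
    down = np.array([0.0, 0.0, -1.0])
    n = down - np.dot(down, u) * u
    nn = np.linalg.norm(n)
    if nn < 1e-9:  # shoulder-wrist axis vertical; tie-break toward -X
        n = np.array([-1.0, 0.0, 0.0]) - u * np.dot([-1.0, 0.0, 0.0], u)
        nn = np.linalg.norm(n)
    return shoulder + a * u + h * (n / nn)


def _elbow_positions(
    shoulders: np.ndarray, wrists: np.ndarray, l1: float, l2: float
) -> np.ndarray:
    out = np.empty_like(wrists)
    for i in range(len(wrists)):
        out[i] = _elbow_position(shoulders[i], wrists[i], l1, l2)
    return out


def _smooth_noise(rng: np.random.Generator, n: int, sd: float, fps: float) -> np.ndarray:
    """Low-pass positional tremor: white noise filtered with a 0.1 s Gaussian
    kernel, rescaled to standard deviation ``sd`` per axis."""
    if sd == 0.0 or n == 0:
        return np.zeros((n, 3))
    sigma = max(fps * 0.1, 1.0)
    half = int(np.ceil(3 * sigma))
    k = np.exp(-0.5 * (np.arange(-half, half + 1) / sigma) ** 2)
    k /= k.sum()
    white = rng.normal(size=(n + 2 * half, 3))
    sm = np.empty((n, 3))
    for ax in range(3):
        sm[:, ax] = np.convolve(white[:, ax], k, mode="valid")[:n]
    # unit-variance filtered noise -> requested sd
    sm *= sd / np.sqrt(np.sum(k**2))
    return sm


def _cycle_wrist_path(params: ReachParams) -> np.ndarray:
    """Noise-free wrist path of one full cycle, sampled at params.fps."""
    rest, cup, mouth = params.wrist_rest, params.cup_position, params.mouth_position
    raise_d = params.raise_fraction * params.reach_duration_s
    lower_d = params.raise_fraction * params.return_duration_s
    phases: list[tuple[str, float, np.ndarray, np.ndarray]] = [
        ("hold", params.hold_start_s, rest, rest),
        ("move", params.reach_duration_s, rest, cup),
        ("hold", params.dwell_s, cup, cup),
        ("move", raise_d, cup, mouth),
        ("hold", params.mouth_hold_s, mouth, mouth),
        ("move", lower_d, mouth, cup),
        ("hold", params.dwell_s, cup, cup),
        ("move", params.return_duration_s, cup, rest),
        ("hold", params.dwell_s, rest, rest),
    ]
    segments = []
    for kind, dur, p0, p1 in phases:
        n = max(int(round(dur * params.fps)), 1)
        if kind == "hold":
            segments.append(np.tile(p0, (n, 1)))
        else:
            # sample τ at k/n, k = 0..n-1; τ = 1 is the first frame of the
            # next phase, which starts at p1, so the profile stays continuous
            tau = np.arange(n, dtype=float) / n
            s = minimum_jerk(tau)
            segments.append(p0 + s[:, None] * (p1 - p0))
    return np.concatenate(segments, axis=0)


def simulate_reach_cycle(params: ReachParams, seed: int) -> JointTrajectory:
    """Simulate one reaching cycle: hold, reach to the cup, raise it to mouth
    height, return it and come back to rest.

    Randomness (tremor only) is fully determined by ``seed``.  Raises
    :class:`UnreachableTargetError` if the cup or mouth target lies outside
    the arm's workspace.
    """
    reach_max = params.upperarm_len + params.forearm_len
    ls = params.left_shoulder
    for name, tgt in (("cup", params.cup_position), ("mouth", params.mouth_position),
                      ("rest", params.wrist_rest)):
        if np.linalg.norm(tgt - ls) > reach_max:
            raise UnreachableTargetError(
                f"{name} target at {np.linalg.norm(tgt - ls):.4f} m exceeds arm "
                f"length {reach_max:.4f} m"
            )
    rng = np.random.default_rng(seed)
    wrist = _cycle_wrist_path(params)
    n = len(wrist)
    wrist = wrist + _smooth_noise(rng, n, params.jitter_sd, params.fps)
    ls_arr = ls + _smooth_noise(rng, n, params.jitter_sd, params.fps)
    rs_arr = params.right_shoulder + _smooth_noise(rng, n, params.jitter_sd, params.fps)
    # keep the jittered wrist strictly inside the workspace
    sw = wrist - ls_arr
    d = np.linalg.norm(sw, axis=1, keepdims=True)
    lim = reach_max - 1e-6
    over = d[:, 0] > lim
    if over.any():
        wrist[over] = ls_arr[over] + sw[over] * (lim / d[over])
    elbow = _elbow_positions(ls_arr, wrist, params.upperarm_len, params.forearm_len)
    t = np.arange(n, dtype=float) / params.fps
    return JointTrajectory(
        timestamps=t,
        positions={"RS": rs_arr, "LS": ls_arr, "LE": elbow, "LW": wrist},
        fps=params.fps,
    )


def simulate_session(
    params: ReachParams,
    n_cycles: int,
    seed: int,
    imu_noise_sd: float = 0.05,
) -> tuple[JointTrajectory, IMUTarget]:
    """Concatenate ``n_cycles`` reaching cycles and derive the aligned IMU
    target, with continuous timestamps at ``params.fps``.

    Tremor is applied as one continuous process over the whole session (a
    per-cycle process would jump at cycle boundaries, and a millimeter-scale
    position step between adjacent frames differentiates into a several-m/s²
    acceleration spike); the elbow is re-solved by inverse kinematics after
    the jitter so segment lengths stay exact.
    """
    if n_cycles < 1:
        raise ValueError(f"n_cycles must be >= 1, got {n_cycles}")
    base = simulate_reach_cycle(replace(params, jitter_sd=0.0), seed=0)
    positions = {j: np.tile(base.positions[j], (n_cycles, 1)) for j in JOINTS}
    n = len(positions["LW"])
    children = np.random.SeedSequence(seed).spawn(2)
    if params.jitter_sd > 0:
        rng = np.random.default_rng(children[0])
        lw = positions["LW"] + _smooth_noise(rng, n, params.jitter_sd, params.fps)
        ls = positions["LS"] + _smooth_noise(rng, n, params.jitter_sd, params.fps)
        rs = positions["RS"] + _smooth_noise(rng, n, params.jitter_sd, params.fps)
        reach_max = params.upperarm_len + params.forearm_len
        sw = lw - ls
        d = np.linalg.norm(sw, axis=1, keepdims=True)
        lim = reach_max - 1e-6
        over = d[:, 0] > lim
        if over.any():
            lw[over] = ls[over] + sw[over] * (lim / d[over])
        le = _elbow_positions(ls, lw, params.upperarm_len, params.forearm_len)
        positions = {"RS": rs, "LS": ls, "LE": le, "LW": lw}
    traj = JointTrajectory(
        timestamps=np.arange(n, dtype=float) / params.fps,
        positions=positions,
        fps=params.fps,
    )
    imu_seed = int(children[1].generate_state(1)[0] % 2**31)
    imu = derive_imu_target(traj, noise_sd=imu_noise_sd, seed=imu_seed)
    return traj, imu


def derive_imu_target(traj: JointTrajectory, noise_sd: float = 0.0, seed: int = 0) -> IMUTarget:
    """Wrist acceleration by finite differences of the LW position.

    Interior frames use the second central difference
    a_i = (p_{i-1} − 2 p_i + p_{i+1})·fps² (exact for cubic trajectories);
    the two endpoints use one-sided second-order stencils so the output has
    the same frame count as the input.  Optional i.i.d. Gaussian sensor noise
    is added per axis.  Gravity is not included: the emulated IMU is
    flat-calibrated with world-aligned axes.
    """
    p = traj.positions["LW"]
    n = len(p)
    if n < 3:
        raise InsufficientLengthError(f"need >= 3 frames, got {n}")
    f2 = traj.fps**2
    acc = np.empty_like(p)
    acc[1:-1] = (p[:-2] - 2.0 * p[1:-1] + p[2:]) * f2
    if n >= 4:
        acc[0] = (2.0 * p[0] - 5.0 * p[1] + 4.0 * p[2] - p[3]) * f2
        acc[-1] = (2.0 * p[-1] - 5.0 * p[-2] + 4.0 * p[-3] - p[-4]) * f2
    else:
        acc[0] = acc[1]
        acc[-1] = acc[1]
    if noise_sd > 0:
        acc = acc + np.random.default_rng(seed).normal(0.0, noise_sd, acc.shape)
    return IMUTarget(acc=acc, fps=traj.fps)


# ---------------------------------------------------------------------------
# CSV interchange


def trajectory_to_csv(traj: JointTrajectory, path) -> None:
    """Write ``t, RS_x .. LW_z`` (meters, world frame), one row per frame."""
    cols = {"t": traj.timestamps}
    for j in JOINTS:
        for k, ax in enumerate("xyz"):
            cols[f"{j}_{ax}"] = traj.positions[j][:, k]
    pd.DataFrame(cols).to_csv(path, index=False)


def trajectory_from_csv(path, fps: float | None = None) -> JointTrajectory:
    df = pd.read_csv(path)
    t = df["t"].to_numpy(dtype=float)
    if fps is None:
        fps = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 50.0
    positions = {
        j: df[[f"{j}_{ax}" for ax in "xyz"]].to_numpy(dtype=float) for j in JOINTS
    }
    return JointTrajectory(timestamps=t, positions=positions, fps=round(fps, 6))


def imu_to_csv(imu: IMUTarget, path) -> None:
    t = np.arange(imu.n_frames, dtype=float) / imu.fps
    pd.DataFrame(
        {"t": t, "acc_x": imu.acc[:, 0], "acc_y": imu.acc[:, 1], "acc_z": imu.acc[:, 2]}
    ).to_csv(path, index=False)


def imu_from_csv(path, fps: float | None = None) -> IMUTarget:
    df = pd.read_csv(path)
    t = df["t"].to_numpy(dtype=float)
    if fps is None:
        fps = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 50.0
    return IMUTarget(acc=df[["acc_x", "acc_y", "acc_z"]].to_numpy(dtype=float), fps=round(fps, 6))
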