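"""Planar 4-link forward kinematics and jump-height feature construction.

The lower body is modeled as four links in the sagittal plane (toe-heel,
heel-shank, shank-thigh, thigh-trunk) with absolute joint angles ``q_i`` and
angular velocities ``qdot_i``.  The vertical back position and velocity are

    p = sum_i l_i sin(q_i)          v = sum_i l_i qdot_i cos(q_i)

and a jump released with state (p, v) peaks at the parabolic height

    h = p + v^2 / (2 g) .

Feature rows for the regression are built from the F time frames ending at
the release frame (the first frame where the vertical toe position exceeds
10% of its within-trial maximum).  Three candidate representations are
supported; with F frames and 4 joints:

1. raw state          ({q_i}, {qdot_i})                         D = 8F
2. kinematic terms    ({sin q_i}, {qdot_i cos q_i})             D = 8F
3. parabolic terms    ({sin q_i}, {a_i a_j}) with
   a_i = qdot_i cos q_i and the 10 ordered pairs i <= j         D = 14F

Candidate 2's features are exactly the per-link summands of p and v, and
candidate 3's span the expanded double-sum form of the parabolic height, so
each candidate embeds the task function at a different level of prior
structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import FeatureColumn, PerformanceVector, TrialMatrix

__all__ = [
    "LinkModel",
    "JointTrajectory",
    "back_position",
    "back_velocity",
    "parabolic_height",
    "jump_height_gradient",
    "detect_release",
    "build_features",
    "trajectory_features",
    "write_trajectories",
    "read_trajectories",
]

N_JOINTS = 4
# printed ordering of the velocity-product pairs in candidate 3
PAIR_ORDER = [(1, 1), (1, 2), (1, 3), (1, 4), (2, 2),
              (2, 3), (2, 4), (3, 3), (3, 4), (4, 4)]


@dataclass(frozen=True)
class LinkModel:
    """Segment lengths (m), toe->trunk, and gravitational acceleration."""

    lengths: tuple[float, float, float, float] = (0.1, 0.4, 0.4, 0.5)
    g: float = 9.8

    def __post_init__(self) -> None:
        if len(self.lengths) != N_JOINTS:
            raise ValueError("exactly four segment lengths required")
        if any(l <= 0 for l in self.lengths) or self.g <= 0:
            raise ValueError("segment lengths and g must be positive")

    @property
    def l(self) -> np.ndarray:
        return np.asarray(self.lengths, float)


@dataclass
class JointTrajectory:
    """Frames x 4 joint angles (rad) and angular velocities (rad/s)."""

    q: np.ndarray
    qdot: np.ndarray
    frame_rate: float = 120.0
    toe_y: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.q = np.atleast_2d(np.asarray(self.q, float))
        self.qdot = np.atleast_2d(np.asarray(self.qdot, float))
        if self.q.shape != self.qdot.shape:
            raise ValueError("q and qdot must have the same shape")
        if self.q.shape[1] != N_JOINTS:
            raise ValueError("trajectories must have 4 joint columns")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.toe_y is not None:
            self.toe_y = np.asarray(self.toe_y, float).ravel()
            if self.toe_y.size != self.q.shape[0]:
                raise ValueError("toe_y length must match the frame count")

    @property
    def n_frames(self) -> int:
        return self.q.shape[0]


def back_position(q_frame, links: LinkModel) -> float:
    """p = sum_i l_i sin(q_i); vectorized over leading frame axes."""
    q = np.asarray(q_frame, float)
    return np.sin(q) @ links.l if q.ndim > 1 else float(np.sin(q) @ links.l)


def back_velocity(q_frame, qdot_frame, links: LinkModel) -> float:
    """v = sum_i l_i qdot_i cos(q_i)."""
    q = np.asarray(q_frame, float)
    qd = np.asarray(qdot_frame, float)
    terms = qd * np.cos(q)
    return terms @ links.l if q.ndim > 1 else float(terms @ links.l)


def parabolic_height(p, v, g: float = 9.8):
    """Peak height h = p + v^2 / (2 g) of the released parabola."""
    return p + np.asarray(v, float) ** 2 / (2.0 * g)


def jump_height_gradient(q_frame, qdot_frame, links: LinkModel) -> np.ndarray:
    """d h / d (q, qdot) at one frame; length-8 vector (q first, then qdot).

    dh/dq_i = l_i cos q_i - (v/g) l_i qdot_i sin q_i
    dh/dqdot_i = (v/g) l_i cos q_i
    """
    q = np.asarray(q_frame, float).ravel()
    qd = np.asarray(qdot_frame, float).ravel()
    v = back_velocity(q, qd, links)
    dq = links.l * np.cos(q) - (v / links.g) * links.l * qd * np.sin(q)
    dqd = (v / links.g) * links.l * np.cos(q)
    return np.concatenate([dq, dqd])


def detect_release(toe_y) -> int:
    """First frame where the vertical toe position exceeds 10% of its max."""
    y = np.asarray(toe_y, float).ravel()
    if y.size == 0:
        raise ValueError("empty toe trajectory")
    ymax = y.max()
    if ymax <= 0:
        raise ValueError("toe trajectory never rises above zero; no release")
    above = np.flatnonzero(y > 0.1 * ymax)
    return int(above[0])


def _window(traj: JointTrajectory, n_frames: int, release_frame: int):
    if release_frame < n_frames - 1:
        raise ValueError(
            f"release frame {release_frame} leaves fewer than {n_frames} frames"
        )
    if release_frame >= traj.n_frames:
        raise ValueError("release frame beyond trajectory end")
    sl = slice(release_frame - n_frames + 1, release_frame + 1)
    return traj.q[sl], traj.qdot[sl]


def build_features(
    traj: JointTrajectory,
    candidate: int,
    n_frames: int,
    release_frame: int | None = None,
):
    """One feature row from the F frames ending at the release frame.

    Returns ``(values, columns)``; frames are ordered oldest -> release
    within each joint block, matching the row layout X_t = ({q_i}, {qdot_i}).
    """
    if candidate not in (1, 2, 3):
        raise ValueError("candidate must be 1, 2 or 3")
    if release_frame is None:
        if traj.toe_y is None:
            raise ValueError("no toe trajectory; pass release_frame explicitly")
        release_frame = detect_release(traj.toe_y)
    qw, qdw = _window(traj, n_frames, release_frame)  # F x 4

    values: list[np.ndarray] = []
    cols: list[FeatureColumn] = []

    def add_block(prefix, quantity, data):
        # data: F x 4 -> joint-major, frame-minor
        for i in range(N_JOINTS):
            for f in range(n_frames):
                values.append(data[f, i])
                cols.append(FeatureColumn(
                    name=f"{prefix}{i + 1}_f{f}", joint=i + 1,
                    quantity=quantity, frame=f))

    if candidate == 1:
        add_block("q", "angle", qw)
        add_block("qd", "angular_velocity", qdw)
    elif candidate == 2:
        add_block("sinq", "derived", np.sin(qw))
        add_block("cqd", "derived", qdw * np.cos(qw))
    else:
        add_block("sinq", "derived", np.sin(qw))
        a = qdw * np.cos(qw)  # F x 4
        for (i, j) in PAIR_ORDER:
            for f in range(n_frames):
                values.append(a[f, i - 1] * a[f, j - 1])
                cols.append(FeatureColumn(
                    name=f"a{i}a{j}_f{f}", quantity="derived", frame=f))
    return np.asarray(values, float), cols


def trajectory_features(
    trajectories,
    candidate: int = 1,
    n_frames: int = 4,
    release_frames=None,
) -> TrialMatrix:
    """Stack per-trial feature rows into an unstandardized TrialMatrix."""
    rows, cols = [], None
    for t, traj in enumerate(trajectories):
        rf = None if release_frames is None else int(release_frames[t])
        row, cols = build_features(traj, candidate, n_frames, rf)
        rows.append(row)
    return TrialMatrix(np.vstack(rows), cols)


# ---------------------------------------------------------------------------
# long-format trajectory I/O (trial, frame, q1..q4, qd1..qd4, toe_y)


def write_trajectories(path, trajectories, frame_rate: float = 120.0, seed=None):
    from . import __version__

    frames = []
    for t, traj in enumerate(trajectories):
        df = pd.DataFrame(traj.q, columns=[f"q{i}" for i in range(1, 5)])
        for i in range(1, 5):
            df[f"qd{i}"] = traj.qdot[:, i - 1]
        df["toe_y"] = traj.toe_y if traj.toe_y is not None else np.nan
        df.insert(0, "frame", np.arange(traj.n_frames))
        df.insert(0, "trial", t)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# motiondecomp v{__version__} trajectories, "
                 f"frame_rate={frame_rate}\n")
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        out.to_csv(fh, index=False)
    return path


def read_trajectories(path, frame_rate: float = 120.0) -> list[JointTrajectory]:
    df = pd.read_csv(path, comment="#")
    needed = {"trial", "frame"} | {f"q{i}" for i in range(1, 5)} \
        | {f"qd{i}" for i in range(1, 5)}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for _, grp in df.groupby("trial", sort=True):
        grp = grp.sort_values("frame")
        toe = grp["toe_y"].to_numpy(float) if "toe_y" in grp else None
        if toe is not None and np.all(np.isnan(toe)):
            toe = None
        out.append(JointTrajectory(
            q=grp[[f"q{i}" for i in range(1, 5)]].to_numpy(float),
            qdot=grp[[f"qd{i}" for i in range(1, 5)]].to_numpy(float),
            frame_rate=frame_rate,
            toe_y=toe,
        ))
    return out
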