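"""Synthetic jump-experiment generator with a planted task direction.

Two generators live here.

``sample_gaussian_tasks`` draws the two-dimensional worked example: three
task clusters sharing one covariance matrix, whose means sit on parallel
constraint lines of the linear task X1 - X2 (weights w = (1, -1)).

``simulate_experiment`` produces full synthetic vertical-jump experiments:
per-trial joint trajectories, realized and displayed jump heights, target
and perturbation schedules, success flags, and trial-by-trial adaptation.
The generative model is

* a latent aim: on trial t the subject aims at target d_t plus an internal
  bias b_t that adapts to the feedback error, b_t = b_{t-1} + eta * e_{t-1}
  with e = target - displayed height (the state-space model
  h_t = h_{t-1} + eta e_{t-1} expressed around a per-trial target);
* a planted task direction: candidate-1 features (joint angles and
  velocities over the F-frame release window) are
  x_t = x_base + a_t * w_true + null-space noise, where w_true is the
  normalized gradient of the parabolic jump height with respect to the
  release-frame features, a_t realizes the aimed height (plus execution
  noise along w_true), and the null-space noise spans the remaining D-1
  directions;
* realized height through forward kinematics: the release-frame state of
  x_t is pushed through p, v and h = p + v^2/(2g), then normalized by the
  standing back height and the maximal-effort range, so the simulated
  heights are exactly consistent with the link model;
* full trajectories: a smooth ramp from standing posture into the planted
  release window, plus a toe-height profile that is zero until release so
  the release-detection rule recovers the intended frame.

Perturbation schedules follow the three experimental designs: probe (one
+/-0.05 perturbation pseudorandomly placed in every complete block of five
trials), gradual (linear ramp to +/-0.05 over ten trials, then held), and
constant (5 null, 15 perturbed, 10 washout, 15 opposite).  An optional
exploration mechanism multiplies the task-relevant execution noise once an
abrupt perturbation step has been experienced, implementing the
interpretation that noticeable perturbations invite exploration along the
task-relevant dimension; it is off (gain 1) by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import null_space

from .data import PerformanceVector, TrialMatrix, standardize
from .kinematics import (
    JointTrajectory,
    LinkModel,
    back_position,
    back_velocity,
    build_features,
    jump_height_gradient,
    parabolic_height,
)

__all__ = [
    "GaussianTaskSpec",
    "PerturbationSchedule",
    "AdaptationParams",
    "JumpExperiment",
    "sample_gaussian_tasks",
    "make_schedule",
    "simulate_experiment",
    "plant_and_recover",
    "TARGET_LEVELS",
    "SUCCESS_TOL",
]

TARGET_LEVELS = (0.40, 0.45, 0.50, 0.55, 0.60)
SUCCESS_TOL = 0.02          # |target - displayed| < 0.02 rings the coin sound
HEIGHT_SCALE = 0.5          # k_max - k_0: maximal-effort back rise (m)

# stylized postures (absolute sagittal angles, rad) and release velocities
Q_STAND = np.array([1.4, 1.5, 1.5, 1.5])
Q_CROUCH = np.array([0.5, 1.0, 0.8, 1.3])
Q_RELEASE = np.array([0.8, 1.3, 1.25, 1.45])
QD_CROUCH = np.array([3.0, 4.0, 4.0, 2.0])
QD_RELEASE = np.array([6.0, 8.0, 8.0, 4.0])


@dataclass
class GaussianTaskSpec:
    """Two-dimensional Gaussian task clusters of the worked example."""

    means: tuple = ((-1.0, 1.0), (0.0, 0.0), (1.0, -1.0))
    cov: tuple = ((0.75, 0.7), (0.7, 0.75))
    n_per_task: int = 1000
    seed: int = 0


@dataclass
class PerturbationSchedule:
    """Displayed-height offset sequence for one experiment.

    kinds: "probe" (one perturbation per complete block of 5), "gradual"
    (10 null trials, ramp to +/-magnitude over 10, then held), "constant"
    (5 null, 15 at +/-m, 10 washout, 15 at -/+m), "none".
    """

    kind: str = "none"
    magnitude: float = 0.05
    n_trials: int | None = None
    sign: int = 1
    seed: int = 0
    phase_lengths: tuple[int, int, int, int] = (5, 15, 10, 15)
    ramp_null: int = 10
    ramp_length: int = 10

    def __post_init__(self) -> None:
        if self.kind not in ("probe", "gradual", "constant", "none"):
            raise ValueError(f"unknown schedule kind {self.kind!r}")
        if self.sign not in (1, -1):
            raise ValueError("sign must be +1 or -1")
        if self.n_trials is None:
            self.n_trials = {"probe": 96, "gradual": 30,
                             "constant": sum(self.phase_lengths),
                             "none": 30}[self.kind]


@dataclass
class AdaptationParams:
    """Trial-by-trial adaptation and execution-noise parameters.

    eta : learning rate of the feedback update (dimensionless, >0)
    exec_noise_rel : SD of execution noise along the planted task direction
        (candidate-1 feature units, i.e. rad / rad/s scale)
    exec_noise_irr : SD of execution noise per null-space direction
    exploration_gain : multiplier on exec_noise_rel once an abrupt
        perturbation step has been experienced (1 = no exploration)
    detect_threshold : minimum |step| in the perturbation sequence that
        counts as noticeable (gradual ramps stay below it)
    """

    eta: float = 0.3
    exec_noise_rel: float = 0.015
    exec_noise_irr: float = 0.05
    exploration_gain: float = 1.0
    detect_threshold: float = 0.025
    seed: int = 0

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError("eta must be > 0")
        if self.exec_noise_rel < 0 or self.exec_noise_irr < 0:
            raise ValueError("noise SDs must be >= 0")


@dataclass
class JumpExperiment:
    """Everything one simulated session produces."""

    trajectories: list[JointTrajectory]
    features: np.ndarray          # T x D raw candidate-1 features
    heights: np.ndarray           # realized normalized jump heights k_t
    displayed: np.ndarray         # k_t + p_t
    targets: np.ndarray
    perturbations: np.ndarray
    success: np.ndarray
    adaptation_state: np.ndarray  # bias b_t entering each trial
    w_true: np.ndarray            # planted unit direction (raw feature space)
    feature_gain: float           # dk per unit feature step along w_true
    release_frame: int
    n_window_frames: int
    links: LinkModel
    base_height: float
    seed: int


def sample_gaussian_tasks(spec: GaussianTaskSpec):
    """Sample the labeled Gaussian task clusters; deterministic per seed."""
    cov = np.asarray(spec.cov, float)
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance matrix must be positive definite") from exc
    rng = np.random.default_rng(spec.seed)
    samples, labels = [], []
    for task, mean in enumerate(spec.means, start=1):
        samples.append(rng.multivariate_normal(np.asarray(mean, float), cov,
                                               size=spec.n_per_task))
        labels.append(np.full(spec.n_per_task, task))
    x = TrialMatrix(np.vstack(samples))
    return x, np.concatenate(labels)


def make_schedule(spec: PerturbationSchedule) -> np.ndarray:
    """Build the perturbation sequence p_t for one experiment."""
    n, m = spec.n_trials, spec.magnitude
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "none":
        return np.zeros(n)
    if spec.kind == "probe":
        p = np.zeros(n)
        n_blocks = n // 5
        if n_blocks == 0:
            raise ValueError("probe schedule needs at least 5 trials")
        # balanced signs first, then seeded ordering and within-block slot
        signs = np.resize([1.0, -1.0], n_blocks)
        rng.shuffle(signs)
        for b in range(n_blocks):
            slot = rng.integers(0, 5)
            p[5 * b + slot] = signs[b] * m
        return p
    if spec.kind == "gradual":
        min_n = spec.ramp_null + spec.ramp_length
        if n < min_n:
            raise ValueError(
                f"gradual schedule needs at least {min_n} trials, got {n}"
            )
        p = np.zeros(n)
        ramp = m * np.arange(1, spec.ramp_length + 1) / spec.ramp_length
        p[spec.ramp_null : spec.ramp_null + spec.ramp_length] = ramp
        p[spec.ramp_null + spec.ramp_length :] = m
        return spec.sign * p
    # constant
    lengths = spec.phase_lengths
    if n != sum(lengths):
        raise ValueError(
            f"constant schedule is {sum(lengths)} trials "
            f"(phases {lengths}); got n_trials={n} -- override phase_lengths "
            "to change the design"
        )
    p = np.concatenate([
        np.zeros(lengths[0]),
        np.full(lengths[1], spec.sign * m),
        np.zeros(lengths[2]),
        np.full(lengths[3], -spec.sign * m),
    ])
    return p


def _blocked_targets(n: int, rng: np.random.Generator) -> np.ndarray:
    """Each target level once per block of five, pseudorandom within block."""
    levels = np.asarray(TARGET_LEVELS)
    reps = int(np.ceil(n / levels.size))
    blocks = [rng.permutation(levels) for _ in range(reps)]
    return np.concatenate(blocks)[:n]


def _resolve_targets(targets, n, kind, rng):
    if targets is None:
        if kind in ("probe", "none"):
            return _blocked_targets(n, rng)
        return np.full(n, 0.5)
    if isinstance(targets, str):
        if targets != "blocked":
            raise ValueError(f"unknown target policy {targets!r}")
        return _blocked_targets(n, rng)
    if np.isscalar(targets):
        return np.full(n, float(targets))
    t = np.asarray(targets, float).ravel()
    if t.size != n:
        raise ValueError("targets length does not match schedule length")
    return t


def _base_window(n_frames: int):
    """F-frame base window interpolating crouch -> release state."""
    frac = np.arange(1, n_frames + 1) / n_frames
    q = Q_CROUCH + frac[:, None] * (Q_RELEASE - Q_CROUCH)
    qd = QD_CROUCH + frac[:, None] * (QD_RELEASE - QD_CROUCH)
    return q, qd


def _decode_window(x: np.ndarray, n_frames: int):
    """Inverse of the candidate-1 layout: features -> (F x 4 q, F x 4 qdot)."""
    q = x[: 4 * n_frames].reshape(4, n_frames).T
    qd = x[4 * n_frames :].reshape(4, n_frames).T
    return q, qd


def _normalized_height(x: np.ndarray, n_frames: int, links: LinkModel,
                       k0_abs: float) -> float:
    q, qd = _decode_window(x, n_frames)
    p = back_position(q[-1], links)
    v = back_velocity(q[-1], qd[-1], links)
    return (parabolic_height(p, v, links.g) - k0_abs) / HEIGHT_SCALE


def _assemble_trajectory(x: np.ndarray, n_frames: int, k_t: float,
                         traj_frames: int, release_index: int,
                         frame_rate: float) -> JointTrajectory:
    q_win, qd_win = _decode_window(x, n_frames)
    n_pre = release_index - n_frames + 1
    q = np.empty((traj_frames, 4))
    qd = np.empty((traj_frames, 4))
    s = np.linspace(0.0, 1.0, n_pre, endpoint=False)
    smooth = (3 * s**2 - 2 * s**3)[:, None]
    q[:n_pre] = Q_STAND + smooth * (q_win[0] - Q_STAND)
    qd[:n_pre] = smooth * qd_win[0]
    q[n_pre : release_index + 1] = q_win
    qd[n_pre : release_index + 1] = qd_win
    q[release_index + 1 :] = q_win[-1]
    qd[release_index + 1 :] = qd_win[-1]
    toe = np.zeros(traj_frames)
    n_flight = traj_frames - release_index
    amp = 0.3 * max(k_t, 0.05)
    toe[release_index:] = amp * np.linspace(0.2, 1.0, n_flight)
    return JointTrajectory(q=q, qdot=qd, frame_rate=frame_rate, toe_y=toe)


def simulate_experiment(
    schedule,
    adapt: AdaptationParams | None = None,
    targets=None,
    links: LinkModel = LinkModel(),
    seed: int = 0,
    n_frames: int = 4,
    traj_frames: int = 40,
    frame_rate: float = 120.0,
    height_model: str = "parabolic",
) -> JumpExperiment:
    """Simulate one session of the jump experiment.

    ``schedule`` is a :class:`PerturbationSchedule` or a ready perturbation
    array.  ``targets`` may be None (kind-appropriate default: blocked
    pseudorandom levels for probe/none, fixed 0.5 otherwise), a scalar, or
    an array.  ``height_model="linear"`` replaces the forward-kinematics
    height with its exact linearization (performance strictly linear in the
    candidate-1 features), useful for planted-structure validation.
    """
    if height_model not in ("parabolic", "linear"):
        raise ValueError("height_model must be 'parabolic' or 'linear'")
    adapt = adapt or AdaptationParams()
    if isinstance(schedule, PerturbationSchedule):
        kind = schedule.kind
        p_sched = make_schedule(schedule)
    else:
        kind = "custom"
        p_sched = np.asarray(schedule, float).ravel()
    n = p_sched.size
    rng = np.random.default_rng(seed)
    targets = _resolve_targets(targets, n, kind, rng)

    # planted geometry -------------------------------------------------
    q_win, qd_win = _base_window(n_frames)
    base_traj = JointTrajectory(q=q_win, qdot=qd_win, frame_rate=frame_rate)
    x_base, _ = build_features(base_traj, 1, n_frames,
                               release_frame=n_frames - 1)
    d_feat = x_base.size
    k0_abs = back_position(Q_STAND, links)

    grad8 = jump_height_gradient(Q_RELEASE, QD_RELEASE, links) / HEIGHT_SCALE
    w_raw = np.zeros(d_feat)
    rel_f = n_frames - 1
    for i in range(4):
        w_raw[i * n_frames + rel_f] = grad8[i]              # dq_i columns
        w_raw[4 * n_frames + i * n_frames + rel_f] = grad8[4 + i]
    gain = float(np.linalg.norm(w_raw))
    w_true = w_raw / gain
    null_basis = null_space(w_true[None, :])  # D x (D-1), orthonormal

    k_base = _normalized_height(x_base, n_frames, links, k0_abs)
    release_index = traj_frames - n_frames
    if release_index < 1:
        raise ValueError("traj_frames too small for the feature window")

    # trial loop --------------------------------------------------------
    feats = np.empty((n, d_feat))
    heights = np.empty(n)
    displayed = np.empty(n)
    bias = np.empty(n)
    trajectories = []
    b = 0.0
    explored = False
    for t in range(n):
        bias[t] = b
        noise_rel_sd = adapt.exec_noise_rel * (
            adapt.exploration_gain if explored else 1.0)
        aim = targets[t] + b
        a = (aim - k_base) / gain + rng.normal(0.0, noise_rel_sd)
        eps = rng.normal(0.0, adapt.exec_noise_irr, size=d_feat - 1)
        x = x_base + a * w_true + null_basis @ eps
        if height_model == "linear":
            k = k_base + float(w_raw @ (x - x_base))
        else:
            k = _normalized_height(x, n_frames, links, k0_abs)
        feats[t] = x
        heights[t] = k
        displayed[t] = k + p_sched[t]
        e = targets[t] - displayed[t]
        b += adapt.eta * e
        trajectories.append(_assemble_trajectory(
            x, n_frames, k, traj_frames, release_index, frame_rate))
        prev_p = p_sched[t - 1] if t > 0 else 0.0
        if abs(p_sched[t] - prev_p) >= adapt.detect_threshold:
            explored = True

    if np.any(heights < 0) or np.any(heights > 1.5):
        warnings.warn("simulated heights left the physical range [0, 1.5]")
    success = np.abs(targets - displayed) < SUCCESS_TOL
    return JumpExperiment(
        trajectories=trajectories,
        features=feats,
        heights=heights,
        displayed=displayed,
        targets=targets,
        perturbations=p_sched,
        success=success,
        adaptation_state=bias,
        w_true=w_true,
        feature_gain=gain,
        release_frame=release_index,
        n_window_frames=n_frames,
        links=links,
        base_height=k_base,
        seed=seed,
    )


def default_windows(perturbations: np.ndarray, window: int = 10):
    """(before, after) trial windows for pre/post-adaptation variances.

    'Before' covers the trials preceding the first nonzero perturbation
    (at most ``window`` of them); 'after' is the last ``window`` trials.
    """
    n = perturbations.size
    nonzero = np.flatnonzero(perturbations != 0)
    onset = int(nonzero[0]) if nonzero.size else n
    before = (max(0, onset - window), onset)
    after = (max(0, n - window), n)
    return before, after


def plant_and_recover(
    schedule,
    adapt: AdaptationParams | None = None,
    targets=None,
    seed: int = 0,
    windows=None,
    lambda_grid=None,
    folds: int = 10,
    height_model: str = "parabolic",
    n_baseline: int = 50,
    **sim_kwargs,
) -> dict:
    """End-to-end validation: simulate, fit, decompose, compare to truth.

    Runs the full pipeline (features -> cross-validated ridge ->
    decomposition) on one simulated session and reports the cosine between
    the fitted and planted task directions plus pre/post-adaptation
    task-relevant and task-irrelevant variabilities.

    A regression needs training data spanning the targets reached before
    and after adaptation, so ``n_baseline`` unperturbed trials with blocked
    pseudorandom targets (the baseline phase of the experimental designs)
    are simulated and pooled with the learning session for standardization
    and fitting; the pre/post windows index the learning trials only.
    """
    from .data import destandardize_weights
    from .decomposition import variance_decomposition
    from .kinematics import trajectory_features
    from .ridge import select_lambda_cv

    sub = np.random.default_rng(seed).integers(2**31, size=2)
    exp = simulate_experiment(schedule, adapt=adapt, targets=targets,
                              seed=seed, height_model=height_model,
                              **sim_kwargs)
    x = trajectory_features(exp.trajectories, candidate=1,
                            n_frames=exp.n_window_frames)
    values, heights = x.values, exp.heights
    if n_baseline > 0:
        base_targets = targets if np.isscalar(targets) else "blocked"
        base = simulate_experiment(
            PerturbationSchedule(kind="none", n_trials=n_baseline,
                                 seed=int(sub[0])),
            adapt=adapt, targets=base_targets,
            seed=int(sub[1]), height_model=height_model, **sim_kwargs)
        xb = trajectory_features(base.trajectories, candidate=1,
                                 n_frames=base.n_window_frames)
        values = np.vstack([xb.values, values])
        heights = np.concatenate([base.heights, heights])
    d = PerformanceVector(heights)
    pooled = TrialMatrix(values, x.columns)
    model = select_lambda_cv(pooled, d, grid=lambda_grid, k=folds, seed=seed)
    wt, _ = destandardize_weights(model.w, model.xparams, model.dparams)
    cosine = float(wt @ exp.w_true
                   / (np.linalg.norm(wt) * np.linalg.norm(exp.w_true)))

    z, _, _, _ = standardize(pooled, d)
    learning = z.values[n_baseline:]
    if windows is None:
        windows = default_windows(exp.perturbations)
    (b0, b1), (a0, a1) = windows
    if b1 <= b0 or a1 <= a0:
        raise ValueError(f"empty analysis window: {windows}")
    pre = variance_decomposition(learning[b0:b1], model.w)
    post = variance_decomposition(learning[a0:a1], model.w)
    return {
        "cosine": cosine,
        "lambda": model.lam,
        "cv_error": model.cv_error,
        "var_rel_before": pre.var_rel_mean,
        "var_rel_after": post.var_rel_mean,
        "var_irr_before": pre.var_irr_mean,
        "var_irr_after": post.var_irr_mean,
        "success_rate": float(exp.success.mean()),
        "windows": ((b0, b1), (a0, a1)),
        "n_trials": len(exp.heights),
        "n_features": x.n_features,
        "experiment": exp,
        "model": model,
    }
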