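"""UCM and GEM variance analyses, and their reduction to the regression form.

Both classical baselines linearize an explicit task mapping around the
trial-mean state and split joint-space deviations into a task-relevant
subspace and its orthogonal (task-equivalent) null space.

* UCM: the task variables are the back position and velocity (p, v) from
  forward kinematics; the 2 x 8 Jacobian d(p, v)/d(q, qdot) at the mean
  state spans the task-relevant row space, its 6-dimensional null space is
  the uncontrolled manifold.  Variances are reported per subspace dimension
  (the standard UCM convention; switchable).
* GEM: the task function is the parabolic height h = p + v^2/(2g); its
  gradient at the mean, (1, v_mean/g), is the goal-relevant direction and
  the orthogonal direction proportional to (v_mean/g, -1) is the
  goal-equivalent one.

Setting the regression weight vector w to a baseline's task-relevant
direction makes the projection decomposition reproduce that baseline's
variances exactly (after matching the per-dimension normalization), which
is the sense in which the data-driven method generalizes both.  Baselines
operate on raw-scale deviations (no z-scoring); the reduction check
harmonizes conventions explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import null_space

from .decomposition import variance_decomposition
from .kinematics import LinkModel, back_position, back_velocity

__all__ = [
    "UCMResult",
    "GEMResult",
    "jump_jacobian",
    "ucm_analysis",
    "gem_analysis",
    "reduction_check",
]


@dataclass
class UCMResult:
    jacobian: np.ndarray
    var_taskrel: float
    var_taskirr: float
    dim_rel: int
    dim_irr: int
    basis_rel: np.ndarray  # dim_rel x D orthonormal rows
    basis_irr: np.ndarray  # dim_irr x D orthonormal rows
    mean_state: np.ndarray


@dataclass
class GEMResult:
    w_gem: np.ndarray          # unnormalized gradient direction (1, v_mean/g)
    var_taskrel: float
    var_taskirr: float
    mean_p: float
    mean_v: float


def jump_jacobian(mean_state: np.ndarray, links: LinkModel, task: str = "pv"):
    """Analytic Jacobian of the task variables at a mean (q, qdot) state.

    task="pv": rows d(p, v)/d(q, qdot), shape 2 x 8 (state = q1..q4, qd1..4)
    task="p":  row dp/dq, shape 1 x 4 (state = q1..q4 only)
    """
    s = np.asarray(mean_state, float).ravel()
    l = links.l
    if task == "p":
        if s.size != 4:
            raise ValueError("task 'p' expects a 4-dimensional (q) state")
        return (l * np.cos(s))[None, :]
    if task != "pv":
        raise ValueError("task must be 'pv' or 'p'")
    if s.size != 8:
        raise ValueError("task 'pv' expects an 8-dimensional (q, qdot) state")
    q, qd = s[:4], s[4:]
    jac = np.zeros((2, 8))
    jac[0, :4] = l * np.cos(q)                       # dp/dq
    jac[1, :4] = -l * qd * np.sin(q)                 # dv/dq
    jac[1, 4:] = l * np.cos(q)                       # dv/dqdot
    return jac


def _subspace_variances(dev: np.ndarray, basis_rel: np.ndarray,
                        basis_irr: np.ndarray, per_dim: bool, ddof: int):
    t = dev.shape[0]
    denom = t - ddof
    coords_rel = dev @ basis_rel.T
    coords_irr = dev @ basis_irr.T
    vr = float((coords_rel**2).sum() / denom)
    vi = float((coords_irr**2).sum() / denom)
    if per_dim:
        vr /= max(basis_rel.shape[0], 1)
        vi /= max(basis_irr.shape[0], 1)
    return vr, vi


def ucm_analysis(
    states,
    links: LinkModel = LinkModel(),
    task: str = "pv",
    per_dim: bool = True,
    ddof: int = 0,
) -> UCMResult:
    """Split state deviations across the Jacobian row space and null space.

    ``states`` is T x 8 (q, qdot at release) for task="pv", or T x 4 (q
    only) for task="p".  Deviations are taken from the trial-mean state;
    variances use the population (1/T) convention and are divided by the
    subspace dimension when ``per_dim`` (UCM convention).
    """
    states = np.atleast_2d(np.asarray(states, float))
    if states.shape[0] < 3:
        raise ValueError("UCM analysis needs at least 3 trials")
    mean_state = states.mean(axis=0)
    jac = jump_jacobian(mean_state, links, task)
    d = states.shape[1]

    # orthonormal row-space basis; rank via SVD
    u, s, vt = np.linalg.svd(jac, full_matrices=False)
    tol = max(jac.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int((s > tol).sum())
    if rank < jac.shape[0]:
        warnings.warn(
            f"rank-deficient Jacobian (rank {rank} < {jac.shape[0]}); "
            "subspace dimensions adjusted"
        )
    basis_rel = vt[:rank]
    basis_irr = null_space(jac).T  # (d - rank) x d, orthonormal rows
    dev = states - mean_state
    vr, vi = _subspace_variances(dev, basis_rel, basis_irr, per_dim, ddof)
    return UCMResult(jacobian=jac, var_taskrel=vr, var_taskirr=vi,
                     dim_rel=rank, dim_irr=d - rank,
                     basis_rel=basis_rel, basis_irr=basis_irr,
                     mean_state=mean_state)


def gem_analysis(p, v, g: float = 9.8, ddof: int = 0) -> GEMResult:
    """Goal-equivalent-manifold split of (p, v) deviations.

    The goal-relevant direction is the gradient of h = p + v^2/(2g) at the
    mean, (1, v_mean/g); deviations along the orthogonal direction
    (v_mean/g, -1) change the height only at second order.
    """
    p = np.asarray(p, float).ravel()
    v = np.asarray(v, float).ravel()
    if p.size != v.size:
        raise ValueError("p and v must have equal length")
    if p.size < 3:
        raise ValueError("GEM analysis needs at least 3 trials")
    vbar = v.mean()
    w = np.array([1.0, vbar / g])
    w_perp = np.array([vbar / g, -1.0])
    dev = np.column_stack([p - p.mean(), v - vbar])
    basis_rel = (w / np.linalg.norm(w))[None, :]
    basis_irr = (w_perp / np.linalg.norm(w_perp))[None, :]
    vr, vi = _subspace_variances(dev, basis_rel, basis_irr, True, ddof)
    return GEMResult(w_gem=w, var_taskrel=vr, var_taskirr=vi,
                     mean_p=float(p.mean()), mean_v=vbar)


def reduction_check(
    w_source: str,
    states=None,
    p=None,
    v=None,
    links: LinkModel = LinkModel(),
) -> dict:
    """Verify that the projection decomposition reproduces a baseline.

    For a 1-dimensional task direction (GEM, or UCM with the scalar task
    variable p), set w to the baseline's task-relevant direction and apply
    the projection decomposition to the same deviation matrix.  The scalar
    summaries relate by the dimension counts:

        Var_rel * D == baseline var_taskrel * dim_rel
        Var_irr * D == baseline var_taskirr * dim_irr

    (the decomposition averages per-feature variances over all D columns
    while the baselines normalize per subspace dimension).  Returns the
    harmonized pairs and their maximum absolute discrepancy.
    """
    if w_source == "gem":
        base = gem_analysis(p, v, links.g)
        dev = np.column_stack([np.asarray(p, float) - base.mean_p,
                               np.asarray(v, float) - base.mean_v])
        w = base.w_gem
        dim_rel, dim_irr = 1, 1
        vr_base, vi_base = base.var_taskrel, base.var_taskirr
    elif w_source == "ucm":
        states = np.atleast_2d(np.asarray(states, float))
        base = ucm_analysis(states, links, task="p")
        dev = states - base.mean_state
        w = base.jacobian[0]
        dim_rel, dim_irr = base.dim_rel, base.dim_irr
        vr_base, vi_base = base.var_taskrel, base.var_taskirr
    else:
        raise ValueError("w_source must be 'gem' or 'ucm'")

    dcomp = variance_decomposition(dev, w)
    d = dev.shape[1]
    rel_pair = (dcomp.var_rel_mean * d, vr_base * dim_rel)
    irr_pair = (dcomp.var_irr_mean * d, vi_base * dim_irr)
    discrepancy = max(abs(rel_pair[0] - rel_pair[1]),
                      abs(irr_pair[0] - irr_pair[1]))
    return {
        "w_source": w_source,
        "projection_rel_total": rel_pair[0],
        "baseline_rel_total": rel_pair[1],
        "projection_irr_total": irr_pair[0],
        "baseline_irr_total": irr_pair[1],
        "max_abs_discrepancy": discrepancy,
    }
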