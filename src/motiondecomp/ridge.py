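"""Closed-form ridge regression with cross-validated regularization.

The task function is estimated as the linear map ``h = X w`` that best
predicts per-trial performance from standardized motion features, where the
weights minimize the penalized least-squares cost

    E(w) = 1/2 |d - X w|^2 + (lambda/2) |w|^2 .

The closed-form minimizer is ``w* = (X^T X + lambda I_D)^{-1} X^T d``; for
T < D the algebraically identical dual form
``w* = X^T (X X^T + lambda I_T)^{-1} d`` is cheaper and is used
automatically.  ``lambda`` is selected by k-fold cross-validation on the
relative squared prediction error, the scale-free metric where 0 means a
perfect prediction and 1 means no better than the mean (zero) predictor.

The L2 penalty is not an arbitrary smoother here: if the motion features
are observed with i.i.d. noise of standard deviation sigma_o per entry, the
expected fitting cost over noise realizations equals the ridge cost with
lambda = T sigma_o^2 (see :func:`noise_equivalence_check`), so shrinkage is
exactly the averaging-over-measurement-noise estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import (
    PerformanceVector,
    StandardizationParams,
    TrialMatrix,
    _as_values,
    standardize,
    apply_standardization,
)

__all__ = [
    "RidgeModel",
    "NoiseModel",
    "NoiseEquivalence",
    "ridge_cost",
    "ridge_fit",
    "predict",
    "prediction_error",
    "default_lambda_grid",
    "select_lambda_cv",
    "noise_equivalence_check",
]


@dataclass
class RidgeModel:
    """Fitted ridge weights in standardized space plus CV diagnostics."""

    w: np.ndarray
    lam: float
    cv_curve: list[tuple[float, float]] | None = None
    xparams: StandardizationParams | None = None
    dparams: StandardizationParams | None = None

    @property
    def cv_error(self) -> float | None:
        """Mean held-out prediction error at the selected lambda."""
        if not self.cv_curve:
            return None
        return min(err for lam, err in self.cv_curve if lam == self.lam)


@dataclass
class NoiseModel:
    """I.i.d. Gaussian observation noise for the equivalence check."""

    sigma_o: float
    n_draws: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_o < 0:
            raise ValueError("sigma_o must be >= 0")
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")


@dataclass
class NoiseEquivalence:
    mc_cost: float
    analytic_cost: float
    mc_se: float
    lambda_equivalent: float


def ridge_cost(w, z, zd, lam: float) -> float:
    """Penalized least-squares cost E(w); the quantity ridge_fit minimizes."""
    w = np.asarray(w, float).ravel()
    r = _as_values(zd).ravel() - _as_values(z) @ w
    return 0.5 * float(r @ r) + 0.5 * lam * float(w @ w)


def ridge_fit(
    z,
    zd,
    lam: float,
    cv_curve=None,
    xparams=None,
    dparams=None,
) -> RidgeModel:
    """Closed-form ridge fit on standardized data.

    For ``lam == 0`` the design must have full column rank; otherwise an
    error advises using a positive ``lam``.
    """
    zv = np.atleast_2d(_as_values(z))
    dv = _as_values(zd).ravel()
    t, d = zv.shape
    if len(dv) != t:
        raise ValueError(f"performance length {len(dv)} != {t} trials")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if lam == 0:
        if np.linalg.matrix_rank(zv) < d:
            raise np.linalg.LinAlgError(
                "design is rank-deficient at lambda=0; use lambda > 0"
            )
        w, *_ = np.linalg.lstsq(zv, dv, rcond=None)
    elif t < d:
        # dual (push-through) form: X^T (X X^T + lam I_T)^{-1} d
        gram = zv @ zv.T
        gram[np.diag_indices(t)] += lam
        w = zv.T @ np.linalg.solve(gram, dv)
    else:
        gram = zv.T @ zv
        gram[np.diag_indices(d)] += lam
        w = np.linalg.solve(gram, zv.T @ dv)
    return RidgeModel(w=w, lam=float(lam), cv_curve=cv_curve,
                      xparams=xparams, dparams=dparams)


def predict(model, z) -> PerformanceVector:
    """Predicted performance h = Z w in standardized space."""
    w = model.w if isinstance(model, RidgeModel) else np.asarray(model, float)
    zv = np.atleast_2d(_as_values(z))
    if zv.shape[1] != len(w):
        raise ValueError(
            f"feature count {zv.shape[1]} does not match weight length {len(w)}"
        )
    return PerformanceVector(zv @ w)


def predict_raw(model: RidgeModel, x_raw) -> np.ndarray:
    """Raw-scale predictions using the stored standardization parameters."""
    from .data import destandardize_weights

    if model.xparams is None or model.dparams is None:
        raise ValueError("model carries no standardization parameters")
    wt, intercept = destandardize_weights(model.w, model.xparams, model.dparams)
    return np.atleast_2d(_as_values(x_raw)) @ wt + intercept


def prediction_error(d_true, d_pred) -> float:
    """Relative squared error sum((d - h)^2) / sum(d^2).

    On standardized targets, 0 is a perfect prediction and 1 matches the
    zero (mean) predictor.
    """
    dt = _as_values(d_true).ravel()
    dp = _as_values(d_pred).ravel()
    if dt.shape != dp.shape:
        raise ValueError("prediction and target lengths differ")
    denom = float(dt @ dt)
    if denom == 0:
        raise ValueError("target vector is identically zero")
    diff = dt - dp
    return float(diff @ diff) / denom


def default_lambda_grid() -> np.ndarray:
    """33 log-spaced regularization values spanning [1e-4, 1e4]."""
    return np.logspace(-4, 4, 33)


def _fold_indices(t: int, k: int, rng: np.random.Generator):
    perm = rng.permutation(t)
    return np.array_split(perm, k)


def select_lambda_cv(
    x,
    d,
    grid=None,
    k: int = 10,
    seed: int = 0,
    global_standardize: bool = False,
    se_rule: float = 1.0,
) -> RidgeModel:
    """Pick lambda by k-fold CV on the held-out prediction error.

    ``x`` and ``d`` are raw (unstandardized) data.  By default the z-scoring
    is re-fitted on each training split and applied to its held-out fold
    (leakage-safe); ``global_standardize=True`` normalizes once on the whole
    dataset, the convention used when a single pooled analysis is intended.

    The selected value is the largest lambda whose mean held-out error is
    within ``se_rule`` standard errors of the curve minimum (the
    one-standard-error convention; heavier shrinkage is the conservative
    choice among statistically indistinguishable fits).  ``se_rule=0``
    reduces to the plain argmin with exact ties broken toward the larger
    lambda.  The returned model is refitted on all trials (globally
    standardized) at the selected lambda.
    """
    xv = np.atleast_2d(_as_values(x))
    dv = _as_values(d).ravel()
    t = xv.shape[0]
    if k < 2:
        raise ValueError("need at least 2 folds")
    if t < k:
        raise ValueError(f"T={t} trials < k={k} folds; use a smaller k")
    grid = default_lambda_grid() if grid is None else np.asarray(grid, float).ravel()
    if grid.size == 0:
        raise ValueError("empty lambda grid")
    if np.any(grid < 0):
        raise ValueError("lambda grid values must be >= 0")
    grid = np.unique(grid)  # sorted ascending, deduplicated

    rng = np.random.default_rng(seed)
    folds = _fold_indices(t, k, rng)

    if global_standardize:
        z_all, zd_all, _, _ = standardize(xv, dv)
        zg, dg = z_all.values, zd_all.values

    errors = np.zeros((grid.size, k))
    for j, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(t), test_idx)
        if global_standardize:
            z_tr, d_tr = zg[train_idx], dg[train_idx]
            z_te, d_te = zg[test_idx], dg[test_idx]
        else:
            z_trm, zd_trm, xp, dp = standardize(xv[train_idx], dv[train_idx])
            z_tr, d_tr = z_trm.values, zd_trm.values
            z_te = apply_standardization(xv[test_idx], xp)
            d_te = (dv[test_idx] - dp.mean[0]) / dp.sd[0]
        gram = z_tr.T @ z_tr
        rhs = z_tr.T @ d_tr
        diag = np.diag_indices(gram.shape[0])
        for i, lam in enumerate(grid):
            if lam == 0:
                w, *_ = np.linalg.lstsq(z_tr, d_tr, rcond=None)
            else:
                g = gram.copy()
                g[diag] += lam
                w = np.linalg.solve(g, rhs)
            errors[i, j] = prediction_error(d_te, z_te @ w)

    mean_err = errors.mean(axis=1)
    i_min = int(np.flatnonzero(mean_err == mean_err.min())[-1])
    se_min = errors[i_min].std(ddof=1) / np.sqrt(k)
    best = int(np.flatnonzero(mean_err <= mean_err[i_min]
                              + se_rule * se_min)[-1])
    curve = list(zip(grid.tolist(), mean_err.tolist()))

    z_all, zd_all, xparams, dparams = standardize(xv, dv)
    return ridge_fit(z_all, zd_all, float(grid[best]), cv_curve=curve,
                     xparams=xparams, dparams=dparams)


def noise_equivalence_check(
    z,
    zd,
    noise: NoiseModel,
    lambda_ref: float = 1.0,
    noise_on: str = "features",
) -> NoiseEquivalence:
    """Compare the Monte-Carlo noise-averaged cost with its closed form.

    The weights are held fixed at the ridge fit for ``lambda_ref``.  With
    ``noise_on="features"`` each draw perturbs the motion matrix entrywise
    with N(0, sigma_o^2) noise; the exact average of the fitting cost is

        1/2 |d - Z w|^2 + (T sigma_o^2 / 2) |w|^2 ,

    the ridge cost with ``lambda_equivalent = T sigma_o^2``.  With
    ``noise_on="performance"`` the draws perturb ``d`` instead, and the
    average is the fitting cost plus the w-independent constant
    ``T sigma_o^2 / 2`` (no shrinkage term arises in that reading).
    """
    zv = np.atleast_2d(_as_values(z))
    dv = _as_values(zd).ravel()
    t, d = zv.shape
    w = ridge_fit(zv, dv, lambda_ref).w
    r = dv - zv @ w
    fit_term = 0.5 * float(r @ r)
    s2 = noise.sigma_o**2

    if noise_on == "features":
        analytic = fit_term + 0.5 * t * s2 * float(w @ w)
        lam_eq = t * s2
    elif noise_on == "performance":
        analytic = fit_term + 0.5 * t * s2
        lam_eq = np.nan
    else:
        raise ValueError("noise_on must be 'features' or 'performance'")

    if noise.sigma_o == 0:
        return NoiseEquivalence(fit_term, analytic, 0.0, lam_eq)

    rng = np.random.default_rng(noise.seed)
    chunk = max(1, int(2_000_000 // max(t * d, 1)))
    costs = np.empty(noise.n_draws)
    done = 0
    while done < noise.n_draws:
        n = min(chunk, noise.n_draws - done)
        if noise_on == "features":
            xi = rng.normal(0.0, noise.sigma_o, size=(n, t, d))
            res = r[None, :] - xi @ w
        else:
            xi = rng.normal(0.0, noise.sigma_o, size=(n, t))
            res = r[None, :] + xi
        costs[done : done + n] = 0.5 * np.einsum("ij,ij->i", res, res)
        done += n
    mc = float(costs.mean())
    se = float(costs.std(ddof=1) / np.sqrt(noise.n_draws)) if noise.n_draws > 1 else np.inf
    return NoiseEquivalence(mc, analytic, se, lam_eq)
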