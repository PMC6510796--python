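"""Projection of motion data onto the fitted task direction.

Given the fitted weight vector ``w``, motion data split exactly into

    X_rel = X w w^T / |w|^2        (task-relevant component)
    X_irr = X - X_rel              (task-irrelevant component)

so that ``X_rel w = X w`` (all predictive information retained) and
``X_irr w = 0`` (fluctuations there leave predicted performance unchanged).
The multiplication by ``w w^T / |w|^2`` is the orthogonal projection of each
trial's feature row onto ``w``; note the projector carries ``1/|w|^2``, not
``1/|w|`` -- only that normalization preserves ``X w``.

Per-feature variances obey the exact identity

    Var(X_i) = Var(X_i^rel) + Var(X_i^irr) + 2 Cov(X_i^rel, X_i^irr)

with the population (1/T) convention; scalar summaries Var_rel and Var_irr
are unweighted means of the per-feature terms across all D dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import StandardizationParams, TrialMatrix, _as_values, apply_standardization

__all__ = [
    "Decomposition",
    "task_relevant",
    "task_irrelevant",
    "variance_decomposition",
]


@dataclass
class Decomposition:
    """Task-relevant/irrelevant split and its variance accounting."""

    x_rel: np.ndarray
    x_irr: np.ndarray
    var_rel: np.ndarray      # per-feature Var(X_i^rel)
    var_irr: np.ndarray      # per-feature Var(X_i^irr)
    cov: np.ndarray          # per-feature Cov(X_i^rel, X_i^irr)
    var_rel_mean: float      # Var_rel: mean over the D features
    var_irr_mean: float
    w_unit: np.ndarray


def _prep(x, w, params: StandardizationParams | None):
    if isinstance(x, TrialMatrix) and not x.standardized and params is None:
        raise ValueError(
            "decomposition operates in the standardized space in which w was "
            "fitted; standardize the data or pass the matching "
            "StandardizationParams"
        )
    xv = np.atleast_2d(_as_values(x))
    if params is not None:
        xv = apply_standardization(xv, params)
    w = np.asarray(w, float).ravel()
    if xv.shape[1] != w.size:
        raise ValueError(f"w has length {w.size} but X has {xv.shape[1]} columns")
    nrm = np.linalg.norm(w)
    if nrm == 0:
        raise ValueError("|w| = 0: decomposition undefined")
    return xv, w, nrm


def task_relevant(x, w, params: StandardizationParams | None = None) -> np.ndarray:
    """X w w^T / |w|^2 -- the component of each trial along w."""
    xv, w, nrm = _prep(x, w, params)
    coeff = (xv @ w) / nrm**2  # length-T projection coefficients
    return np.outer(coeff, w)


def task_irrelevant(x, w, params: StandardizationParams | None = None) -> np.ndarray:
    """X minus its task-relevant component; lies in the null space of w."""
    xv, w, nrm = _prep(x, w, params)
    coeff = (xv @ w) / nrm**2
    return xv - np.outer(coeff, w)


def _population_moments(a: np.ndarray, b: np.ndarray, ddof: int):
    t = a.shape[0]
    am = a - a.mean(axis=0)
    bm = b - b.mean(axis=0)
    denom = t - ddof
    return (
        np.einsum("ti,ti->i", am, am) / denom,
        np.einsum("ti,ti->i", bm, bm) / denom,
        np.einsum("ti,ti->i", am, bm) / denom,
    )


def variance_decomposition(
    x,
    w,
    params: StandardizationParams | None = None,
    ddof: int = 0,
) -> Decomposition:
    """Split per-feature variance into relevant, irrelevant and cross terms.

    ``ddof=0`` (default) is the population 1/T convention matching the
    variance identity; ``ddof=1`` gives the unbiased 1/(T-1) variant.
    Variances are taken about each component's own mean, so the identity
    holds for centered and uncentered inputs alike.
    """
    xv, w, nrm = _prep(x, w, params)
    coeff = (xv @ w) / nrm**2
    x_rel = np.outer(coeff, w)
    x_irr = xv - x_rel
    var_rel, var_irr, cov = _population_moments(x_rel, x_irr, ddof)
    return Decomposition(
        x_rel=x_rel,
        x_irr=x_irr,
        var_rel=var_rel,
        var_irr=var_irr,
        cov=cov,
        var_rel_mean=float(var_rel.mean()),
        var_irr_mean=float(var_irr.mean()),
        w_unit=w / nrm,
    )
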