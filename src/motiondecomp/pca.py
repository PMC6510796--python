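"""SVD/PCA of the motion matrix and per-PC task relevance.

Writing the standardized motion matrix as ``Z = U S V^T``, each principal
component ``v_i`` explains a fraction ``s_i^2 / sum_j s_j^2`` of the total
variance, and its trial-to-trial score ``Z v_i = s_i u_i`` can be
correlated with performance.  The ridge prediction then expands over PCs:

    h_t = sum_i  s_i^2/(s_i^2 + lambda) * Corr(Z v_i, d) * u_{i,t} * c

where ``c = sqrt(T) * sd(d)`` (exactly sqrt(T) for standardized d).  The
scale ``c`` comes from ``u_i^T d = sqrt(T) sd(d) Corr(u_i, d)``, which holds
because column-centered Z forces every ``u_i`` with ``s_i > 0`` to have zero
mean and norm 1.  The expansion makes explicit that ridge regression
weights each PC by *both* its explained variance (through the shrinkage
factor ``s^2/(s^2+lambda)``, saturating in ``s_i``) and its task relevance
(through the correlation) -- whereas variance ranking alone need not find
the performance-relevant direction: the PC most correlated with performance
is not always the first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import PerformanceVector, _as_values

__all__ = [
    "PCRelevance",
    "svd_decompose",
    "pc_task_relevance",
    "ridge_prediction_svd",
    "topn_reconstruction_corr",
]

RANK_TOL = 1e-12  # PCs with s_i < RANK_TOL * s_1 are treated as null


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return np.nan
    return float(a @ b / (na * nb))


@dataclass
class PCRelevance:
    """Singular triplets of Z with per-PC variance and relevance summaries."""

    singular_values: np.ndarray          # descending, >= 0
    u: np.ndarray                        # T x r, orthonormal columns
    v: np.ndarray                        # D x r, orthonormal columns
    explained_fraction: np.ndarray       # s_i^2 / sum s_j^2
    valid: np.ndarray                    # False where s_i ~ 0 (rank-deficient)
    corr: np.ndarray | None = None       # Corr(Z v_i, d); nan where invalid

    def ridge_weights(self, lam: float) -> np.ndarray:
        """Shrinkage factor s_i^2 / (s_i^2 + lambda) per PC."""
        s2 = self.singular_values**2
        return s2 / (s2 + lam)

    @property
    def most_relevant(self) -> int:
        """Index (0-based) of the PC with the largest |correlation|."""
        if self.corr is None:
            raise ValueError("correlations not computed; use pc_task_relevance")
        masked = np.where(self.valid, np.abs(self.corr), -np.inf)
        return int(np.argmax(masked))

    def relevance_ranking(self) -> np.ndarray:
        """Valid PC indices sorted by decreasing |correlation|."""
        if self.corr is None:
            raise ValueError("correlations not computed; use pc_task_relevance")
        idx = np.flatnonzero(self.valid)
        return idx[np.argsort(-np.abs(self.corr[idx]), kind="stable")]


def svd_decompose(z) -> PCRelevance:
    """Thin SVD with a deterministic sign convention.

    Each right vector ``v_i`` is oriented so its largest-magnitude entry is
    positive (ties to the earliest index); ``u_i`` follows, keeping
    ``Z = U S V^T`` intact across linear-algebra backends.
    """
    zv = np.atleast_2d(_as_values(z))
    u, s, vt = np.linalg.svd(zv, full_matrices=False)
    v = vt.T
    for i in range(s.size):
        j = int(np.argmax(np.abs(v[:, i])))
        if v[j, i] < 0:
            v[:, i] = -v[:, i]
            u[:, i] = -u[:, i]
    total = float((s**2).sum())
    frac = s**2 / total if total > 0 else np.zeros_like(s)
    valid = s > (RANK_TOL * s[0] if s.size and s[0] > 0 else 0.0)
    return PCRelevance(singular_values=s, u=u, v=v,
                       explained_fraction=frac, valid=valid)


def pc_task_relevance(z, zd) -> PCRelevance:
    """SVD plus the Pearson correlation of each PC score with performance.

    Scores are ``Z v_i = s_i u_i``; for ``s_i > 0`` the correlation equals
    ``Corr(u_i, d)``.  Rank-deficient PCs get ``corr = nan`` and are
    excluded from relevance rankings.
    """
    zv = np.atleast_2d(_as_values(z))
    dv = _as_values(zd).ravel()
    if len(dv) != zv.shape[0]:
        raise ValueError("performance length does not match trial count")
    pcs = svd_decompose(zv)
    scores = zv @ pcs.v
    corr = np.full(pcs.singular_values.size, np.nan)
    for i in np.flatnonzero(pcs.valid):
        corr[i] = _pearson(scores[:, i], dv)
    pcs.corr = corr
    return pcs


def ridge_prediction_svd(z, zd, lam: float) -> PerformanceVector:
    """Ridge prediction assembled PC by PC; equals the closed form.

    Requires column-centered (standardized) ``z`` and ``lam > 0``.
    """
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    zv = np.atleast_2d(_as_values(z))
    dv = _as_values(zd).ravel()
    pcs = pc_task_relevance(zv, dv)
    t = zv.shape[0]
    scale = np.sqrt(t) * dv.std()  # recovers u_i^T d from the correlation
    f = pcs.ridge_weights(lam)
    h = np.zeros(t)
    for i in np.flatnonzero(pcs.valid):
        h += f[i] * pcs.corr[i] * pcs.u[:, i] * scale
    return PerformanceVector(h)


def topn_reconstruction_corr(z, zd, z_percent: float):
    """Correlation of performance with the top-n PC reconstruction readout.

    ``n_z`` is the smallest number of leading PCs whose cumulative explained
    variance strictly exceeds ``z_percent``/100.  The readout is
    ``d~_t = sum_{i<=n_z} s_i u_{i,t}`` (the rank-n reconstruction summed
    against the PC directions); returns ``(n_z, Corr(d, d~))``.
    """
    if not 0 < z_percent < 100:
        raise ValueError("z_percent must lie strictly between 0 and 100")
    zv = np.atleast_2d(_as_values(z))
    dv = _as_values(zd).ravel()
    pcs = svd_decompose(zv)
    cum = np.cumsum(pcs.explained_fraction)
    above = np.flatnonzero(cum > z_percent / 100.0)
    n_z = int(above[0]) + 1 if above.size else pcs.singular_values.size
    d_tilde = pcs.u[:, :n_z] @ pcs.singular_values[:n_z]
    return n_z, _pearson(dv, d_tilde)
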