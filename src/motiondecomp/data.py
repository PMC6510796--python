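"""Trial-by-feature containers, z-scoring, and delimited-text I/O.

Motion data enter the analysis as a matrix ``X`` with one row per trial and
one column per kinematic feature (a joint angle or angular velocity at a
given time frame within the pre-release window), paired with a per-trial
scalar performance value ``d`` (normalized jump height).  All model fitting
happens in *standardized* space: every column of ``X`` and the performance
vector are z-scored to mean 0 and population standard deviation 1, because
an L2 penalty is only meaningful when the regressors share a scale.  The
helpers here make that transform explicit and exactly invertible, so fitted
weights can always be mapped back to raw units (rad, rad/s, normalized
height).

Conventions
-----------
* Variances and standard deviations use the population (1/T) normalization
  throughout the package, matching the variance identity used by the
  decomposition module.
* Zero-variance columns are an error by default (silently dropping them
  would change ``D`` and the indexing of the weight vector); pass
  ``on_zero_variance="drop"`` to drop with a warning instead.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureColumn",
    "TrialMatrix",
    "PerformanceVector",
    "StandardizationParams",
    "standardize",
    "apply_standardization",
    "destandardize_weights",
    "read_trials",
    "write_trials",
]

SD_TOL = 1e-12
_STD_CHECK_TOL = 1e-10

# column names like "q3_f2" / "qd3_f2" round-trip joint/quantity/frame metadata
_NAME_RE = re.compile(r"^(q|qd)(\d+)_f(\d+)$")


@dataclass(frozen=True)
class FeatureColumn:
    """Descriptor for one column of a trial matrix.

    Parameters
    ----------
    name : str
        Unique column label used in files.
    joint : int or None
        1-based joint index (1 toe-heel, 2 heel-shank, 3 shank-thigh,
        4 thigh-trunk) for kinematic features; None for generic columns.
    quantity : str
        One of ``"angle"``, ``"angular_velocity"``, ``"derived"``.
    frame : int or None
        0-based time-frame index within the feature window (oldest first,
        last frame = release).
    """

    name: str
    joint: int | None = None
    quantity: str = "derived"
    frame: int | None = None


def _auto_columns(d: int) -> list[FeatureColumn]:
    return [FeatureColumn(name=f"x{i + 1}") for i in range(d)]


def column_from_name(name: str) -> FeatureColumn:
    """Rebuild joint/quantity/frame metadata from a conventional name."""
    m = _NAME_RE.match(name)
    if m is None:
        return FeatureColumn(name=name)
    prefix, joint, frame = m.groups()
    quantity = "angle" if prefix == "q" else "angular_velocity"
    return FeatureColumn(name=name, joint=int(joint), quantity=quantity, frame=int(frame))


@dataclass
class TrialMatrix:
    """T trials x D features with per-column metadata.

    ``standardized=True`` asserts that every column has mean 0 and population
    standard deviation 1 (checked on construction to 1e-10).
    """

    values: np.ndarray
    columns: list[FeatureColumn] | None = None
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        t, d = self.values.shape
        if t < 2:
            raise ValueError(f"need at least 2 trials, got {t}")
        if d < 1:
            raise ValueError("need at least 1 feature column")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trial matrix contains non-finite entries")
        if self.columns is None:
            self.columns = _auto_columns(d)
        if len(self.columns) != d:
            raise ValueError(
                f"{len(self.columns)} column descriptors for {d} columns"
            )
        if self.standardized:
            mu = self.values.mean(axis=0)
            sd = self.values.std(axis=0)
            if np.max(np.abs(mu)) > _STD_CHECK_TOL or np.max(np.abs(sd - 1.0)) > _STD_CHECK_TOL:
                raise ValueError(
                    "standardized=True but columns are not z-scored "
                    f"(max |mean| = {np.max(np.abs(mu)):.2e}, "
                    f"max |sd-1| = {np.max(np.abs(sd - 1.0)):.2e})"
                )

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def column_names(self) -> list[str]:
        return [c.name for c in self.columns]


@dataclass
class PerformanceVector:
    """Length-T vector of scalar per-trial performance (normalized height)."""

    values: np.ndarray
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("performance vector contains non-finite entries")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class StandardizationParams:
    """Column means and population standard deviations of the raw data."""

    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).ravel()
        self.sd = np.asarray(self.sd, dtype=float).ravel()
        if self.mean.shape != self.sd.shape:
            raise ValueError("mean and sd must have the same length")
        if np.any(self.sd <= 0):
            raise ValueError("all standard deviations must be positive")


def _as_values(x) -> np.ndarray:
    if isinstance(x, TrialMatrix):
        return x.values
    if isinstance(x, PerformanceVector):
        return x.values
    return np.asarray(x, dtype=float)


def _zscore(values: np.ndarray, names: Sequence[str], on_zero_variance: str):
    mu = values.mean(axis=0)
    sd = values.std(axis=0)  # population convention
    bad = np.flatnonzero(sd <= SD_TOL)
    keep = np.arange(values.shape[1])
    if bad.size:
        bad_names = [names[i] for i in bad]
        if on_zero_variance == "drop":
            warnings.warn(
                f"dropping zero-variance column(s): {bad_names}", stacklevel=3
            )
            keep = np.setdiff1d(keep, bad)
            if keep.size == 0:
                raise ValueError("all columns have zero variance")
            mu, sd = mu[keep], sd[keep]
            values = values[:, keep]
        else:
            raise ValueError(
                f"zero-variance column(s): {bad_names}; cannot standardize"
            )
    return (values - mu) / sd, StandardizationParams(mu, sd), keep


def standardize(
    x: TrialMatrix | np.ndarray,
    d: PerformanceVector | np.ndarray | None = None,
    on_zero_variance: str = "error",
):
    """Z-score motion data and performance to mean 0, population SD 1.

    Returns ``(Z, zd, xparams, dparams)`` when ``d`` is given, else
    ``(Z, xparams)``.  The parameters allow exact inversion of the transform
    (see :func:`destandardize_weights`).
    """
    if on_zero_variance not in ("error", "drop"):
        raise ValueError("on_zero_variance must be 'error' or 'drop'")
    xv = _as_values(x)
    xv = np.atleast_2d(xv)
    columns = x.columns if isinstance(x, TrialMatrix) else _auto_columns(xv.shape[1])
    zv, xparams, keep = _zscore(xv, [c.name for c in columns], on_zero_variance)
    z = TrialMatrix(zv, [columns[i] for i in keep], standardized=True)
    if d is None:
        return z, xparams
    dv = _as_values(d).ravel()
    if len(dv) != xv.shape[0]:
        raise ValueError(
            f"performance length {len(dv)} does not match {xv.shape[0]} trials"
        )
    dsd = dv.std()
    if dsd <= SD_TOL:
        raise ValueError("performance vector has zero variance; cannot standardize")
    dmu = dv.mean()
    dparams = StandardizationParams([dmu], [dsd])
    zd = PerformanceVector((dv - dmu) / dsd, standardized=True)
    return z, zd, xparams, dparams


def apply_standardization(values, params: StandardizationParams) -> np.ndarray:
    """Transform raw values with previously fitted means/SDs."""
    v = np.asarray(values, dtype=float)
    return (v - params.mean) / params.sd


def destandardize_weights(
    w: np.ndarray,
    xparams: StandardizationParams,
    dparams: StandardizationParams,
):
    """Map weights fitted in standardized space back to raw units.

    For the standardized model ``zd = Z w`` with ``Z_i = (x_i - m_i)/s_i``
    and ``zd = (d - m_d)/s_d``, raw-scale predictions are
    ``d = sum_i wt_i x_i + intercept`` with ``wt_i = s_d w_i / s_i`` and
    ``intercept = m_d - sum_i wt_i m_i``.  Returns ``(wt, intercept)``.
    """
    w = np.asarray(w, dtype=float).ravel()
    if w.shape != xparams.sd.shape:
        raise ValueError("weight length does not match standardization params")
    s_d = float(dparams.sd[0])
    m_d = float(dparams.mean[0])
    wt = s_d * w / xparams.sd
    intercept = m_d - float(wt @ xparams.mean)
    return wt, intercept


# ---------------------------------------------------------------------------
# delimited-text I/O


def _detect_sep(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_trials(
    path,
    performance_col: str = "performance",
    trial_col: str = "trial",
    sep: str | None = None,
):
    """Read a trial table (header row, one row per trial) from CSV/TSV.

    The performance column is split off into a :class:`PerformanceVector`;
    every other non-id column becomes a feature.  Comment lines starting
    with ``#`` (provenance headers) are ignored.
    """
    path = Path(path)
    sep = sep or _detect_sep(path)
    df = pd.read_csv(path, sep=sep, comment="#")
    if df.columns.str.match(r"^Unnamed").any() or len(df.columns) == 0:
        raise ValueError(f"{path}: missing or malformed header row")
    if performance_col not in df.columns:
        raise ValueError(
            f"{path}: performance column {performance_col!r} absent from header "
            f"{list(df.columns)}"
        )
    if trial_col in df.columns:
        ids = df[trial_col]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"{path}: duplicate trial id {dup!r}")
        df = df.drop(columns=[trial_col])
    feature_cols = [c for c in df.columns if c != performance_col]
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: non-numeric cell at row {row}, column {col!r}: "
                f"{df[col].iloc[row]!r}"
            )
        if numeric.isna().any():
            row = int(np.flatnonzero(numeric.isna().to_numpy())[0])
            raise ValueError(f"{path}: missing value at row {row}, column {col!r}")
        df[col] = numeric
    x = TrialMatrix(
        df[feature_cols].to_numpy(float),
        [column_from_name(c) for c in feature_cols],
    )
    d = PerformanceVector(df[performance_col].to_numpy(float))
    return x, d


def write_trials(
    path,
    x: TrialMatrix,
    d: PerformanceVector | None = None,
    performance_col: str = "performance",
    trial_col: str = "trial",
    sep: str | None = None,
    seed: int | None = None,
):
    """Write a trial table with a provenance comment header."""
    from . import __version__

    path = Path(path)
    sep = sep or _detect_sep(path)
    df = pd.DataFrame(x.values, columns=x.column_names)
    if d is not None:
        if len(d) != x.n_trials:
            raise ValueError("performance length does not match trial count")
        df[performance_col] = d.values
    df.insert(0, trial_col, np.arange(x.n_trials))
    with open(path, "w") as fh:
        fh.write(f"# motiondecomp v{__version__} trial table\n")
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        df.to_csv(fh, sep=sep, index=False)
    return path
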