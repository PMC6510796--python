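"""End-to-end orchestration: candidate comparison and adaptation reports.

These are the library-level entry points the CLI wraps.  They chain the
stages (features -> cross-validated ridge -> decomposition -> PC relevance
-> UCM/GEM baselines) and return plain dicts / DataFrames that serialize
to JSON and CSV.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .baselines import gem_analysis, ucm_analysis
from .data import PerformanceVector, standardize
from .kinematics import LinkModel, back_position, back_velocity, trajectory_features
from .pca import pc_task_relevance
from .ridge import select_lambda_cv
from .simulate import (
    AdaptationParams,
    PerturbationSchedule,
    default_windows,
    plant_and_recover,
    simulate_experiment,
)

__all__ = [
    "load_config",
    "release_states",
    "run_candidate_comparison",
    "run_adaptation_analysis",
]

# ratio beyond which a pre/post variance change is flagged in reports
CHANGE_RATIO = 1.5


def load_config(path) -> dict:
    """Read a YAML (or JSON) run configuration."""
    text = Path(path).read_text()
    return yaml.safe_load(text)


def run_candidate_comparison(
    trajectories,
    performance,
    candidates=(1, 2, 3),
    frames=(1, 2, 3, 4),
    folds: int = 10,
    seed: int = 0,
    lambda_grid=None,
) -> pd.DataFrame:
    """Grid of mean CV prediction errors over candidates x window lengths.

    Cells that cannot be computed (e.g. a window longer than the available
    frames) are recorded with an error message and the run continues.
    """
    rows = []
    d = PerformanceVector(np.asarray(performance, float))
    for cand in candidates:
        for f in frames:
            try:
                x = trajectory_features(trajectories, candidate=cand,
                                        n_frames=f)
                model = select_lambda_cv(x, d, grid=lambda_grid, k=folds,
                                         seed=seed)
                rows.append({"candidate": cand, "frames": f,
                             "cv_error": model.cv_error,
                             "lambda": model.lam, "error": ""})
            except (ValueError, np.linalg.LinAlgError) as exc:
                rows.append({"candidate": cand, "frames": f,
                             "cv_error": np.nan, "lambda": np.nan,
                             "error": str(exc)})
    return pd.DataFrame(rows)


def release_states(exp):
    """T x 8 (q, qdot) at the release frame, from the stored features."""
    f = exp.n_window_frames
    rel = f - 1
    q_cols = [i * f + rel for i in range(4)]
    qd_cols = [4 * f + i * f + rel for i in range(4)]
    return exp.features[:, q_cols + qd_cols]


def run_adaptation_analysis(
    kind: str = "constant",
    adapt: AdaptationParams | None = None,
    schedule: PerturbationSchedule | None = None,
    seed: int = 0,
    windows=None,
    lambda_grid=None,
    folds: int = 10,
    out_dir=None,
    **sim_kwargs,
) -> dict:
    """Simulate one session and report variability before/after adaptation.

    The ridge weights are fitted on ALL pooled trials (spanning the targets
    before and after adaptation -- a regression needs training data that
    covers both regimes), then the task-relevant/irrelevant variabilities
    are computed inside the pre and post windows.  The report also carries
    the per-PC relevance summary and the UCM/GEM baseline variances on the
    raw release states.
    """
    schedule = schedule or PerturbationSchedule(kind=kind, seed=seed)
    report = plant_and_recover(schedule, adapt=adapt, seed=seed,
                               windows=windows, lambda_grid=lambda_grid,
                               folds=folds, **sim_kwargs)
    exp = report.pop("experiment")
    model = report.pop("model")

    (b0, b1), (a0, a1) = report["windows"]
    onset = np.flatnonzero(exp.perturbations != 0)
    if onset.size and b1 > onset[0]:
        warnings.warn(
            f"pre-adaptation window ({b0}, {b1}) overlaps the perturbation "
            f"onset at trial {onset[0]}"
        )

    # per-PC relevance on the pooled standardized data
    from .kinematics import trajectory_features

    x = trajectory_features(exp.trajectories, candidate=1,
                            n_frames=exp.n_window_frames)
    z, zd, _, _ = standardize(x, PerformanceVector(exp.heights))
    pcs = pc_task_relevance(z, zd)
    n_top = min(5, int(pcs.valid.sum()))
    pc_table = pd.DataFrame({
        "pc": np.arange(1, pcs.singular_values.size + 1),
        "explained_fraction": pcs.explained_fraction,
        "correlation": pcs.corr,
        "ridge_weight": pcs.ridge_weights(model.lam),
    })

    states = release_states(exp)
    ucm = ucm_analysis(states, exp.links)
    p = back_position(states[:, :4], exp.links)
    v = back_velocity(states[:, :4], states[:, 4:], exp.links)
    gem = gem_analysis(p, v, exp.links.g)

    rel_ratio = report["var_rel_after"] / report["var_rel_before"]
    irr_ratio = report["var_irr_after"] / report["var_irr_before"]
    report.update({
        "kind": schedule.kind if isinstance(schedule, PerturbationSchedule)
                else "custom",
        "var_rel_ratio": rel_ratio,
        "var_irr_ratio": irr_ratio,
        "var_rel_increased": bool(rel_ratio > CHANGE_RATIO),
        "var_rel_changed": bool(rel_ratio > CHANGE_RATIO
                                or rel_ratio < 1 / CHANGE_RATIO),
        "var_irr_changed": bool(irr_ratio > CHANGE_RATIO
                                or irr_ratio < 1 / CHANGE_RATIO),
        "most_relevant_pc": int(pcs.most_relevant) + 1,
        "top_pcs": pc_table.head(n_top).to_dict("records"),
        "ucm": {"var_taskrel": ucm.var_taskrel,
                "var_taskirr": ucm.var_taskirr},
        "gem": {"var_taskrel": gem.var_taskrel,
                "var_taskirr": gem.var_taskirr},
        "seed": seed,
    })

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        pc_table.to_csv(out_dir / "pc_relevance.csv", index=False)
        serializable = {k: v for k, v in report.items() if k != "top_pcs"}
        serializable["windows"] = [list(w) for w in report["windows"]]
        (out_dir / "adaptation_report.json").write_text(
            json.dumps(serializable, indent=2, default=float))
    return report
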