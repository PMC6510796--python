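"""Fit the task function by cross-validated ridge and rank PC relevance.

Simulates a probe-perturbation jump session, builds the joint-angle /
angular-velocity features of the four frames before release, selects the
ridge penalty by 10-fold cross-validation, and expands the prediction over
principal components.  The PC with the largest variance need not be the one
most correlated with jump height -- the per-PC table makes that visible.
"""

import numpy as np

from motiondecomp import (
    PerformanceVector,
    PerturbationSchedule,
    pc_task_relevance,
    select_lambda_cv,
    simulate_experiment,
    standardize,
    trajectory_features,
)

exp = simulate_experiment(PerturbationSchedule(kind="probe", seed=1), seed=1)
x = trajectory_features(exp.trajectories, candidate=1, n_frames=4)
d = PerformanceVector(exp.heights)

model = select_lambda_cv(x, d, seed=1)
print(f"selected lambda = {model.lam:g}, "
      f"held-out prediction error = {model.cv_error:.3f}")
print("(error 0 = perfect prediction, 1 = no better than the mean height)")

z, zd, _, _ = standardize(x, d)
pcs = pc_task_relevance(z, zd)
print("\n pc  explained   corr(score, height)   ridge weight")
for i in range(5):
    print(f"  {i + 1}    {pcs.explained_fraction[i]:.3f}        "
          f"{pcs.corr[i]:+.3f}              "
          f"{pcs.ridge_weights(model.lam)[i]:.3f}")
print(f"\nmost task-relevant PC: {pcs.most_relevant + 1} "
      f"(highest |correlation|, not necessarily the highest variance)")
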