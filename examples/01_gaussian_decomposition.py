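"""Decompose the two-dimensional Gaussian worked example.

Three task clusters require the linear combination X1 - X2 to equal -2, 0
and +2 (weights w = (1, -1)).  Projecting each sample onto w isolates the
task-relevant component; the orthogonal remainder is task-irrelevant.  The
cluster means separate cleanly in the relevant coordinate and collapse in
the irrelevant one, and the per-feature variances match the analytic
propagation of the shared covariance matrix.
"""

import numpy as np

from motiondecomp import (
    GaussianTaskSpec,
    sample_gaussian_tasks,
    task_irrelevant,
    task_relevant,
    variance_decomposition,
)

spec = GaussianTaskSpec(n_per_task=100_000, seed=0)
x, labels = sample_gaussian_tasks(spec)
w = np.array([1.0, -1.0])

rel_score = task_relevant(x.values, w) @ w / np.linalg.norm(w)
irr_score = task_irrelevant(x.values, w) @ np.array([1.0, 1.0]) / np.sqrt(2)

print("cluster means along the task-relevant / task-irrelevant coordinate:")
for task in (1, 2, 3):
    m = labels == task
    print(f"  task {task}: rel {rel_score[m].mean():+.3f}   "
          f"irr {irr_score[m].mean():+.3f}")
print("(rel means sit at the constraint levels -2/0/+2 divided by |w|=sqrt2;"
      " irr means are all ~0: only the relevant component separates tasks)")

dec = variance_decomposition(x.values[labels == 2], w)
print(f"\nsingle-cluster variance split: Var_rel={dec.var_rel_mean:.4f} "
      f"Var_irr={dec.var_irr_mean:.4f}")
print("(analytic values 0.025 and 0.725 from the covariance "
      "[[0.75, 0.7], [0.7, 0.75]]: Var(X1-X2)=0.1 -> 0.025 per feature)")
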