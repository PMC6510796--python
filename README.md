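# motiondecomp

Data-driven decomposition of time-varying motion into **task-relevant** and
**task-irrelevant** components, for motor-control and biomechanics analyses
of goal-directed movements.

## The problem

Human movements vary from trial to trial, and that variability has two
well-documented structures: it is smaller along directions that matter for
the task than along directions that do not (the observation behind the
uncontrolled-manifold, UCM, and goal-equivalent-manifold, GEM, analyses),
and it concentrates in a low-dimensional subspace (synergies / principal
components). Classical tools quantify one structure or the other, and both
UCM and GEM require an explicit task function or forward-kinematics model
linearized at the trial-mean posture — which breaks down when the mean
kinematics themselves change, as they do before, during and after motor
adaptation.

`motiondecomp` implements a regression-based alternative that needs only a
trial-by-feature motion matrix **X** ∈ ℝ^{T×D} (e.g. joint angles and
angular velocities over the time frames preceding release) and a per-trial
scalar performance **d** ∈ ℝ^T (e.g. normalized jump height):

1. **Fit the task function from data.** Ridge regression on standardized
   data minimizes E(w) = ½|d − Xw|² + (λ/2)|w|², with λ chosen by 10-fold
   cross-validation; the closed form is w* = (XᵀX + λI)⁻¹Xᵀd.
2. **Project.** X_rel = X wwᵀ/|w|² carries all predictive information
   (X_rel w = Xw); X_irr = X − X_rel satisfies X_irr w = 0. Per-feature
   variances obey Var(X_i) = Var(X_i^rel) + Var(X_i^irr) + 2Cov, and the
   scalar summaries Var_rel, Var_irr average across the D features.
3. **Rank principal components by task relevance.** Writing X = USVᵀ, the
   ridge prediction expands as
   h_t = Σᵢ [sᵢ²/(sᵢ² + λ)] · Corr(Xvᵢ, d) · u_{i,t} · √T·sd(d),
   so every PC is weighted by *both* its explained variance and its
   correlation with performance — the most task-relevant PC need not be
   the highest-variance one.

With w set to the GEM gradient (1, v̄/g) of the parabolic height
h = p + v²/2g, or to a UCM Jacobian row, the projection reproduces those
baselines exactly: they are special cases of the same decomposition.

The package also ships a synthetic vertical-jump laboratory
(`motiondecomp.simulate`): 4-link planar forward kinematics, release
detection, target and perturbation schedules (probe / gradual / constant),
trial-by-trial adaptation h_t = h_{t−1} + η·e_{t−1}, and a planted task
direction in feature space — so every claim the package makes is testable
against known ground truth without any recorded motion-capture data.

## Worked example

```python
import numpy as np
from motiondecomp import (GaussianTaskSpec, sample_gaussian_tasks,
                          variance_decomposition)

spec = GaussianTaskSpec(n_per_task=100_000, seed=0)   # three 2-D clusters
x, labels = sample_gaussian_tasks(spec)
dec = variance_decomposition(x.values[labels == 2], np.array([1.0, -1.0]))
print(dec.var_rel_mean, dec.var_irr_mean)
```

prints `0.02509... 0.72671...`: for a cluster with covariance
[[0.75, 0.7], [0.7, 0.75]] and task X₁ − X₂ (weights (1, −1)), the variance
of the task level is 0.75 + 0.75 − 2·0.7 = 0.1, i.e. 0.025 per feature in
the task-relevant component, leaving 0.725 per feature task-irrelevant —
the projection recovers the analytic split. Each script in `examples/`
walks one capability the same way:

* `01_gaussian_decomposition.py` — the 2-D worked example above; cluster
  means separate only in the task-relevant coordinate.
* `02_ridge_and_pc_relevance.py` — cross-validated ridge on a simulated
  jump session and the per-PC relevance table (on this session the most
  relevant PC is the 24th, not the 1st).
* `03_adaptation_variability.py` — constant-schedule adaptation with
  exploration multiplies Var_rel (geometric mean ×11.6 over four sessions)
  while Var_irr stays near ×1.2; the gradual schedule moves neither
  (×0.93 / ×1.01).
* `04_ucm_gem_baselines.py` — UCM/GEM variances on raw release states and
  the exact reduction of both to the projection decomposition (~1e-17).

A thin CLI mirrors the library (`motiondecomp simulate | features | fit |
decompose | pca | baselines | compare-candidates | adapt-report`); run
`motiondecomp --help`.

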