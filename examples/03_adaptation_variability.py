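"""Task-relevant variability before vs after motor adaptation.

Simulates the constant-perturbation design (5 null trials, 15 perturbed,
10 washout, 15 opposite) with an exploration mechanism that doubles the
execution noise along the task-relevant direction once the abrupt
perturbation is noticed, and the gradual design (ramp over 10 trials)
without exploration.  Because the pre/post windows contain only 5-10
trials, single-session variance ratios fluctuate; averaging the log-ratio
over a few sessions shows the planted signature: exploration raises
Var_rel while Var_irr stays put, and the gradual schedule changes neither.
"""

import numpy as np

from motiondecomp import AdaptationParams, PerturbationSchedule, plant_and_recover

SEEDS = range(4)

for kind, gain in [("constant", 2.0), ("gradual", 1.0)]:
    rel, irr, cos = [], [], []
    for seed in SEEDS:
        rep = plant_and_recover(
            PerturbationSchedule(kind=kind, seed=seed),
            adapt=AdaptationParams(exploration_gain=gain, seed=seed),
            seed=seed)
        rel.append(rep["var_rel_after"] / rep["var_rel_before"])
        irr.append(rep["var_irr_after"] / rep["var_irr_before"])
        cos.append(rep["cosine"])
    geo = lambda r: float(np.exp(np.mean(np.log(r))))
    print(f"{kind} schedule (exploration gain {gain}, "
          f"{len(list(SEEDS))} sessions):")
    print(f"  per-session Var_rel post/pre ratios: {np.round(rel, 2)}")
    print(f"  geometric mean: Var_rel x{geo(rel):.2f}, "
          f"Var_irr x{geo(irr):.2f}")
    print(f"  fitted vs planted task direction: "
          f"cosine >= {min(cos):.4f}\n")

print("Exploration under the abrupt (constant) schedule multiplies the")
print("task-relevant variability severalfold while the task-irrelevant")
print("variability stays near x1; the gradual schedule moves neither.")
print("Weights are fitted on pooled baseline + learning trials so the")
print("regression spans the targets both before and after adaptation.")
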