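# Methods

## Model

The method treats one experimental session as T trials of a movement
described by D features per trial — here joint angles q₁..q₄ (toe-heel,
heel-shank, shank-thigh, thigh-trunk, absolute sagittal-plane angles, rad)
and angular velocities q̇₁..q̇₄ (rad/s) over the F time frames ending at the
release frame — paired with a scalar performance d_t (jump height in
units normalized per subject: 0 = standing, 1 = maximal effort).

All fitting happens on standardized data: every feature column and the
performance vector are z-scored to mean 0 and **population** (1/T)
standard deviation 1. Standardization is not cosmetic: the L2 penalty
λ|w|² charges all coefficients equally, so without a common scale the
features with small raw variance would absorb inflated weights. The
transform is exactly invertible (`destandardize_weights`), so fitted
weights and predictions map back to raw units; the 1/T convention is used
for every variance in the package (a ddof switch exposes 1/(T−1)).

### Ridge regression

w minimizes E(w) = ½|d − Xw|² + (λ/2)|w|², solved in closed form as
w* = (XᵀX + λI_D)⁻¹Xᵀd, or through the algebraically identical dual form
Xᵀ(XXᵀ + λI_T)⁻¹d when T < D (used automatically; both are verified
against a generic numerical minimizer in the tests). λ = 0 requires full
column rank and otherwise errors with advice to regularize.

The penalty has a noise interpretation: if each motion-feature entry is
observed with i.i.d. noise of SD σ₀, the expected fitting cost over noise
draws is exactly ½|d − Xw|² + (Tσ₀²/2)|w|², i.e. the ridge cost with
λ = Tσ₀². `noise_equivalence_check` verifies this by Monte Carlo. Note
the correspondence requires the noise to perturb the *motion data*: noise
added to the performance vector alone averages to a w-independent constant
Tσ₀²/2 and produces no shrinkage term (exposed as
`noise_on="performance"` for completeness).

### Cross-validated regularization

λ is selected on a grid of 33 log-spaced values in [10⁻⁴, 10⁴] by k-fold
CV (default k = 10): trials are randomly permuted (seeded) into near-equal
folds; by default standardization is re-fitted on each training split and
applied to its held-out fold, so no held-out statistics leak into the fit
(`global_standardize=True` restores single-pass whole-dataset
normalization for pooled analyses). The error metric is the relative
squared prediction error Σ(d − ĥ)²/Σd², which is 0 for a perfect
prediction and 1 for the mean (zero) predictor on standardized targets.

The selected λ is the **largest value within one standard error of the
curve minimum** (the one-standard-error convention). Among statistically
indistinguishable fits heavier shrinkage is the conservative choice, and
under pure noise this almost always selects the heaviest shrinkage the
grid offers, as it should; a plain argmin instead picks essentially at
random among the flat top decades of the curve. `se_rule=0` restores the
argmin with exact ties broken toward larger λ.

### Decomposition

X_rel = X·wwᵀ/|w|² and X_irr = X − X_rel. The multiplier wwᵀ/|w|² is the
orthogonal projector onto w — the normalization is 1/|w|², the only choice
for which X_rel·w = X·w holds, which is the defining requirement (the
task-relevant part keeps every feature of the data that the fitted task
function can see; the task-irrelevant part is exactly annihilated,
X_irr·w = 0). Per-feature variances are taken about each component's own
mean, so the identity Var(X_i) = Var_rel,i + Var_irr,i + 2Cov_i holds for
centered and uncentered inputs alike; the cross-covariances are computed
and reported, not assumed zero. Scalar summaries Var_rel and Var_irr are
unweighted means over the D features. The decomposition refuses raw-scale
`TrialMatrix` inputs unless the matching standardization parameters are
supplied, because w only means something in the space it was fitted in.

### PC relevance

With the thin SVD X = USVᵀ (deterministic sign convention: each vᵢ is
oriented so its largest-magnitude entry is positive), the ridge prediction
expands as h_t = Σᵢ f(sᵢ)·Corr(Xvᵢ, d)·u_{i,t}·c with shrinkage factor
f(sᵢ) = sᵢ²/(sᵢ² + λ) and scale c = √T·sd(d). The scale follows from
uᵢᵀd = √T·sd(d)·Corr(uᵢ, d), which is exact because column-centered X
forces every left vector with sᵢ > 0 to have zero mean and unit norm; the
equivalence with the closed form is verified to 1e-8 rather than assumed.
PCs with sᵢ < 10⁻¹²·s₁ are flagged rank-deficient, get an undefined
correlation, and are excluded from relevance rankings; the "most relevant
PC" maximizes |Corr|, with signed values reported. The explained-variance
curve uses n_z = min{n : Σᵢ≤n sᵢ²/Σ sᵢ² > z/100} and the readout
d̃_t = Σᵢ≤n_z sᵢ u_{i,t}.

## Kinematics and feature candidates

Back position p = Σ lᵢ sin qᵢ and velocity v = Σ lᵢ q̇ᵢ cos qᵢ for segment
lengths lᵢ (defaults 0.1, 0.4, 0.4, 0.5 m — foot, shank, thigh, trunk of a
stylized adult); a jump released with state (p, v) peaks at h = p + v²/2g,
g = 9.8 m/s². The release frame is the first frame where the vertical toe
position strictly exceeds 10% of its within-trial maximum (the simulator
emits toe trajectories already baseline-zeroed, so no standing-height
subtraction is applied). Feature windows are the closed interval
[release − F + 1, release], ordered oldest → release, joint-major within
each quantity block; no angle wrapping is applied (trajectories are
assumed continuous). The three candidate representations (raw state,
per-link kinematic terms, parabolic expansion terms with the ten ordered
velocity-product pairs) have D = 8F, 8F and 14F; candidate 2's features
are exactly the per-link summands of p and v, and candidate-3 features
span the expanded quadratic form of h, both checked in the tests.

## UCM and GEM baselines

UCM: deviations of the T×8 release states from their trial mean are split
across the row space of the analytic Jacobian ∂(p, v)/∂(q, q̇) evaluated
at the mean state (2 task dimensions) and its 6-dimensional null space;
variances are normalized per subspace dimension, the standard UCM
convention (switchable). A 1-D variant uses the task variable p alone.
GEM: deviations of (p, v) are split along the gradient (1, v̄/g) of the
parabolic height at the mean and its orthogonal complement — movement
along (v̄/g, −1) changes the height only at second order. Both baselines
operate on raw-scale deviations (no z-scoring), deliberately: their own
conventions are preserved, and `reduction_check` harmonizes the
normalizations explicitly (projection averages over all D features;
baselines divide by subspace dimension) before verifying that the
projection decomposition with w set from the baseline direction reproduces
the baseline variances exactly.

## The synthetic jump laboratory

No public motion-capture dataset accompanies the method, so the simulator
is a first-class module that plants every quantity the pipeline is
supposed to recover.

**Geometry.** A base F-frame release window interpolates a crouched state
to a release state (q = (0.8, 1.3, 1.25, 1.45) rad, q̇ = (6, 8, 8, 4)
rad/s) whose forward-kinematic peak sits near 0.52 in normalized units
(standing back height subtracted, maximal-effort range 0.5 m). The planted
task direction w_true is the normalized gradient of the normalized jump
height with respect to the candidate-1 features; it is supported on the
release-frame columns because the parabolic height depends only on the
release state.

**Trial generation.** On trial t the subject aims at target d_t plus an
internal bias b_t; the feature vector is
x_t = x_base + a_t·w_true + N·ε_t, where a_t realizes the aimed height
through the local gain |∇k| plus execution noise along w_true (SD 0.015
feature units ≈ 0.03 in height units, matching a realistic ~3% jump-height
SD), N is an orthonormal basis of the null space of w_true, and ε_t has SD
0.05 per direction — an order of magnitude more total task-irrelevant than
task-relevant variability, the structure the method exists to detect. The
realized height is pushed through the forward kinematics exactly (a
`height_model="linear"` switch replaces it with its exact linearization
for planted-linearity oracles), the full trajectory is a smooth ramp from
standing posture into the planted window, and the toe profile is zero
until the release frame so the detection rule recovers it.

**Adaptation.** b_t = b_{t−1} + η·e_{t−1} with feedback error
e = target − displayed height and learning rate η = 0.3 (single-rate
state-space adaptation; mid-range of rates reported for trial-by-trial
motor adaptation, and large enough to adapt a 0.05 perturbation within the
15-trial phases of the constant design). Displayed height adds the
perturbation p_t of the schedule: probe (one ±0.05 perturbation
pseudorandomly placed per complete block of five trials; balanced signs),
gradual (10 null trials, linear ramp to ±0.05 over 10 trials, then held;
30 trials), constant (5 null, 15 at ±0.05, 10 washout, 15 opposite; 45
trials). Targets are drawn blocked-pseudorandom from
{0.40, 0.45, 0.50, 0.55, 0.60} for probe/no-perturbation sessions and
fixed at 0.50 for gradual/constant ones. A trial is successful when
|target − displayed| < 0.02.

**Exploration.** An optional mechanism multiplies the task-relevant
execution noise by `exploration_gain` once a perturbation step of at least
0.025 has been experienced (the constant schedule's 0.05 jumps trigger it;
the gradual ramp's 0.005 steps never do), implementing the interpretation
that noticeable errors invite exploration along the dimension that
matters. Default gain is 1 (off); it is a modeling option, not a claim
about any particular dataset.

**What the simulator does not emulate:** muscle/torque dynamics, realistic
inter-joint coordination, measurement noise of a motion-capture system,
trial-to-trial correlations in execution noise, fatigue, or savings across
sessions. Passing tests therefore demonstrate that the pipeline recovers
planted structure under its own generative assumptions — linear task
structure plus isotropic null-space noise — not that any specific human
dataset behaves this way.

## Analysis conventions

For adaptation analyses the ridge weights are fitted on **pooled trials**:
50 simulated baseline trials with blocked pseudorandom targets plus the
learning session. A regression can only interpolate within the target
range it was trained on, so the training data must span the heights
reached both before and after adaptation; fitting on a fixed-target
learning session alone leaves w unidentified against the null-space noise
(observed as cosine ≈ 0.2 vs ≈ 1.0 with pooling). Pre/post variability is
then computed inside trial windows of the learning session: "before"
defaults to the trials preceding the first nonzero perturbation (at most
10 — the constant design only has 5) and "after" to the last 10 trials,
both configurable. Reports flag a variance change when the post/pre ratio
leaves [1/1.5, 1.5]; with 5–10-trial windows single-session ratios are
noisy, so the examples and validation suite aggregate geometric means over
several sessions rather than leaning on one draw.

## Numerical choices and edge cases

- Zero-variance columns error by default (dropping silently would shift
  weight indexing); an explicit drop-with-warning mode exists.
- Linear systems are solved with dense `numpy.linalg.solve` on the
  regularized Gram matrix; D is a few dozen in the intended regime.
- |w| = 0 makes the projection undefined and errors.
- Monte-Carlo noise checks are chunked to bound memory and report the
  standard error of the estimate alongside the comparison.
- All randomness flows from `numpy.random.default_rng` seeded per run;
  identical configurations and seeds reproduce outputs bitwise. Derived
  sub-seeds (e.g. for the pooled baseline session) stay below 2³¹.
- Simulated heights outside [0, 1.5] normalized units raise a warning,
  not an error: large planted noise legitimately produces them.

## Known limitations

One-dimensional performance only (w is a single column); multi-dimensional
task variables would require choosing a performance coordinate system.
The UCM/GEM reduction is exact only after the documented convention
harmonization. The exploration mechanism is deliberately minimal (a single
noise gain with a step detector); richer reinforcement-style exploration
models are out of scope. The candidate-comparison utility reports CV error
per (candidate, window length) cell but leaves model choice to the user.
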