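# Methods

## Model

The plant is a unit point mass translating in the horizontal plane, with
the y-axis along the reach and the x-axis transverse; the axes are
dynamically independent.  Three forces act: viscous drag −G ṗ, a
controlled force F that follows the command u through first-order
low-pass dynamics with time constant τ (a linear stand-in for muscle
dynamics), and a constant external force F_ext used to model mechanical
perturbations (a perturbation sets F_ext once; the identity dynamics of
that state carry it forward).  The continuous equations are
Euler-discretized at dt = 10 ms.  All units are SI.

The state vector per axis is (p, ṗ, F, F_ext); both axes together give an
8-vector.  Two augmentations make the control problem homogeneous and
delayed:

* a *goal block* of the same shape holds the target's position (and zero
  target velocity/forces), so terminal costs are quadratic forms in the
  difference between the physical and goal blocks;
* the 16-vector is stacked over h + 1 delay slots (newest first) and the
  observation selects the oldest slot: y_t = x_{t−h} + ω_t.  h = 5 steps
  (50 ms) models the long-latency sensorimotor loop.

State estimation is a time-varying Kalman filter in predictor form,
x̂_{t+1} = A x̂_t + B u_t + K_t (y_t − H x̂_t), with gains from the standard
covariance recursion, computed once per horizon and cached per batch.  The
filter is target-independent: candidate goals never enter the estimator,
only the cost.

Control is finite-horizon LQG.  The backward recursion produces gains L_t,
cost matrices S_t and scalar offsets s_t (accumulating tr(S Σ_m), the
expected cost of future noise) from the terminal condition S_N = Q_N,
s_N = r_N.  The expected cost-to-go v̂(x̂, t) = x̂ᵀ S_t x̂ + s_t is both the
value of the current plan and the decision variable compared across goals.
The offset update is the backward accumulation s_{t−1} = s_t + tr(S_t Σ_m),
the direction compatible with the terminal boundary condition.

Time-varying task parameters are handled by model-predictive replanning:
at every step the recursion is re-solved over the remaining horizon with
the currently known terminal cost and the decremented horizon (total
movement time stays fixed), and only the first command is applied.  With
time-invariant parameters this reproduces the offline LQG trajectory
exactly (tested to 1e−9), so replanning is free of side effects.  Any
change in target *structure or reward* becomes visible to the controller
only after a hard update delay of 15 steps (150 ms), separate from and in
addition to the h-step sensory delay; the per-step cost-to-go comparison
itself is not gated by this delay.

Decisions: each candidate goal i has its own terminal bias r_N^i and
(shared- or per-option) control solution.  Each step, v̂^i is evaluated for
every option on the same current estimate — with option i's goal values
substituted into the goal block — and the option with the smallest value
supplies the command.  Exact ties keep the current option (this prevents
chattering; an optional hysteresis margin, default 0, can strengthen
that).  Reward is encoded inversely: the bias r_N is a *cost* added to
less-rewarding options, so low bias = high reward.  For a redundant
rectangular target the reward profile s0(x) along the redundant axis
(piecewise quadratics, clamped at zero) is discretized into K = 21 point
goals spanning the rectangle, each biased by its local s0; endpoint
statistics are insensitive to K ≥ 11.

## Parameters

| parameter | default | meaning |
|---|---|---|
| m, G | 1 kg, 1 N·s/m | standardized plant |
| τ | 60 ms | muscle low-pass constant |
| dt, N | 10 ms, 60 steps | step and movement horizon (600 ms) |
| h | 5 steps | sensory feedback delay (50 ms) |
| update delay | 15 steps | task-structure update delay (150 ms) |
| w1 | 1000 | forward / narrow-target accuracy weight |
| w2 | 0 (wide) … 1000 (narrow) | transverse accuracy weight, possibly time-varying |
| v_w | 10 | terminal velocity weight |
| R | 1e−4 · I | command cost |
| Σ_m | sd 0.1 N on F rows | additive motor noise |
| Σ_s | sd (1 cm, 5 cm/s, 0.5 N) per channel class | sensory noise |
| s0 scale | 5·10⁻² | reward (cost) bias of less-rewarded targets |

The quadratic weights are one overall scale times a fixed relative
structure (transverse narrow weight : velocity weight = 100 : 1, effort
cost 1e−5 per unit scale).  The overall scale (×10) is chosen so that
typical cost-to-go values during a reach are of the same order as the
reward biases s0 ~ 2.5–5·10⁻² — the regime in which reward can bias
online decisions at all; the closed loop itself is invariant to this
scale.  With these weights an unperturbed noiseless reach terminates
within 0.3 mm of the target with terminal speed below 1 cm/s.

Motor noise is calibrated so the unperturbed endpoint x-SD on a wide
(unconstrained) target is ≈ 1 cm, matching the scale of human endpoint
scatter.  The filter's internal process-noise model adds a random-walk
term (sd 1 N/step) on the external-force rows: force steps are
deterministic jumps outside the additive-noise model, and without this
term the filter's gain on those components collapses and perturbations
are never credited to F_ext.  This is a filter design parameter, not
plant noise.

Width schedules: the transverse weight of a changing target follows
w2_slow(t) = 0.001 · w2 / (1 + exp((10 − t)/3)) and w2_fast = 10 × slow,
with t in steps since the (delayed) change onset; an instantaneous switch
steps between the wide (0) and narrow (w2) values.  The sigmoid midpoint
(10 steps = 100 ms) and slope (3 steps) are interpreted in integration
steps.

Scenario geometry (not fixed by the experiments being emulated, chosen
once): reach distance 0.25 m; triple-target laterals at ±0.12 m at the
same depth (the center is nearer); rectangle half-width 0.05 m (the roots
of the reward quadratics); perturbation onset at step 15 (150 ms);
structure-change onset at step 10, except the reward-switch scenario where
the reward changes at movement onset so that the delayed controller update
(150 ms) arrives before the reach commits to the initially favored end.

## What the synthetic batches do and do not show

Batches draw per-trial seeds deterministically from a master seed, so runs
are bit-reproducible and conditions can share noise realizations (paired
comparisons).  The simulations emulate the *structure* of the reference
experiments — geometry, force levels, reward manipulations, delays — with
additive Gaussian noise only.  They do not model signal-dependent motor
noise, short-latency reflexes, reaction-time or pre-movement processes,
EMG, movement-duration re-optimization, or between-participant
variability.  Decision statistics are therefore meaningful as *orderings*
(switch proportion grows with force, shrinks with the central-reward
advantage; decision time grows with reward difference and shrinks with
force), not as quantitative predictions of human onset times: the
simulated detection floor (~210 ms = 150 ms force onset + 50 ms sensory
delay + filter rise) and the human values need not coincide.  At 10 N the
simulated decision saturates (every trial switches near the detection
floor), so the force contrast on decision time is measured from switch
times, and the ROC onset contrast is measured across reward-difference
levels at 5 N, where both final-target groups are populated.

## Numerical choices

* The Riccati recursion, gains and cost-to-go are supported on the leading
  16-dim block (delay slots carry no cost and never feed back), so
  replanning runs on the 16-dim core; the full augmented matrices exist
  and are tested against the contracts.  Per-step gain tapes depend on
  time only, never on the state, and are computed once per condition and
  reused across trials.
* Innovation covariances may be singular (noise-free channels); the filter
  uses a pseudo-inverse so the noiseless limit is exact.
* The terminal reward bias is added to the offsets as one final vector
  addition, making the bias-separation property bit-exact.
* S matrices are re-symmetrized each recursion step against round-off.
* The tie rule for equal cost-to-go values keeps the current option; the
  symmetric rectangle therefore resolves its two-extremity tie
  deterministically (to the option ordering) in noiseless runs.
* Divergence guard: a trial whose state norm exceeds 1e3 raises a
  diagnostic error rather than returning garbage.
* ROC onsets use the nonparametric rank-sum AUC (ties half-weighted) and
  require 5 consecutive samples at or above threshold 0.75; the sustain
  length is a convention choice, config-exposed.

## Known limitations

Linear point-mass limb, additive noise only, fixed movement duration, and
a decision rule that is purely the instantaneous cost-to-go argmin (no
evidence accumulation); commitments are effectively absorbing because the
selected option's controller immediately moves the state toward that
goal.  The 10 N condition saturates the decision statistics (see above).
The ROC group definition requires both final-target groups to be
non-empty within a condition; conditions that saturate cannot be analyzed
this way.
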