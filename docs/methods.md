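# Methods

This note documents the models implemented in `apeo`, the defaults they
ship with, the numerical choices behind them, and what the synthetic
study conditions can and cannot show about real data.

## Synthetic cohort

Participants are drawn once per cohort from fixed trait distributions:
body mass N(58, 9²) kg, baseline aerobic capacity N(41, 5²) mL·kg⁻¹·min⁻¹
(floored at physiologically sensible minima), adaptation time constant
LogNormal(1.6, 0.3) steps, enjoyment Beta(2, 2), perceived effort and
skill requirement Uniform(0.3, 0.9), and standard-normal social
embeddings (dimension 4).  These are desk-scale choices for an adolescent
school cohort; no distribution here is an empirical claim.  Any trait can
be fixed to a scalar or re-distributed through the config.

Each participant owns an RNG stream derived from the master seed through
a `SeedSequence` spawn key indexed by participant position, so enlarging
a cohort never perturbs existing participants — the property the
bit-reproducibility tests rely on.

Disturbance streams are zero-mean Gaussian by default, with an AR(1)
option (same stationary sd) for serially correlated perturbations such
as accumulating tiredness.

The physical-literacy model is a forward generator only: L = W·X + ε
with Gaussian ε.  Estimating W by maximum-likelihood factor analysis is
out of scope; the tests instead verify that ordinary least squares on
simulated (X, L) pairs recovers each loading within three standard
errors at n = 5000.

## EEG synthesis and the emotion rule engine

Band definitions are the conventional theta 4–8, alpha 8–13, beta
13–30 Hz (configurable).  Band powers are integrated Welch PSDs (2 s Hann
windows, 50 % overlap, half-open bands so adjacent bands never share a
bin), averaged over channels.  Filtering is a 4th-order Butterworth
band-pass applied forward-backward (`sosfiltfilt`), so band power is not
phase-distorted and stopband attenuation doubles.

"Up"/"down" relative to the resting baseline default to power ratios
above 1.5 or below 0.67.  Rule precedence is fixed: the θ/α-ratio
(fatigue) rule fires first because it is the safety-critical one, then
beta (stress), theta (focus), alpha (relaxation), and the joint
beta-and-alpha drop (lack of interest).  If nothing fires, a neutral
sentinel is returned with a warning rather than a forced label.

The synthetic generator plants per-band sinusoids (theta 6, alpha 10,
beta 20 Hz — bin centers of the 2 s Welch grid) with random per-channel
phases plus broadband Gaussian noise at a configurable SNR.  One
interaction deserves note: a *pure* alpha elevation of ≥1.5× baseline
mechanically drives the θ/α ratio below 0.67× baseline and would be
captured by the fatigue rule.  The alpha-dominant signature therefore
carries a mild theta elevation (theta 1.4×, alpha 2.0× baseline power,
θ/α = 0.70), consistent with relaxed wakefulness raising theta along
with alpha.  With this signature the noiseless pipeline's confusion
matrix is exactly diagonal, which validates internal consistency of the
generator/classifier pair — not classification accuracy on recorded EEG,
where baselines drift, bands overlap and artifacts dominate.

## State dynamics and PID control

The controlled update S(t+1) = S(t) + W_s·u + D_s·d and the autonomous
relaxation dS/dt = −(S − S\*)/τ are two overlapping evolution laws; the
package exposes the relaxation exactly (closed form, used as the Euler
oracle) and uses the linear controlled update inside the simulator.
Engagement and adherence are clamped to [0, 1] after every update;
downstream formulas (sigmoid targets, rewards) presume bounded
engagement, so silent excursions would be worse than the clamp, which is
flagged on the state.

The PID integral uses the rectangle rule and the derivative a backward
difference, with dt explicit.  The integral term can be clamped
(anti-windup) because real prescriptions are box-constrained; an
unbounded integral would be meaningless.  Identifiability of (W_s, D_s)
from noise-free transitions by least squares is exact to 1e-6 — the test
keeps inputs small enough that no clamp activates, since clamped steps
are not linear.

## Biomechanics

Forces are F = m·a per joint; torques τ = I·q̈ + C(q, q̇) + G(q); the
single-link pendulum model used in tests has I = m·l², no Coriolis term,
and gravity torque m·g·l·sin θ, verified against a finite-difference
potential-energy gradient.  Mechanical energy is kinetic plus
trapezoidal work accumulation.  Force optimization is plain gradient
descent on ‖F − F_opt‖², which contracts per step by |1 − 2η|; the
per-joint energy cap is enforced by halving the step until feasible
(projection), and the iterate simply stops moving if it is pinned to the
boundary.  Optimal force profiles have no defining formula here; the
package accepts them as explicit input, with a helper that linearly
rescales a reference template by body mass — a documented synthetic
stand-in, not a biomechanical norm.

## Engagement, gamification, and the RNN

The combiner f(M, S, C) is realized as a logistic-linear read-out and is
pluggable.  Influence weights are a softmax over embedding dot products,
computed with max-subtraction; positivity, unit sum and shift invariance
are property-tested.  Engagement decay E(t+1) = αE + (1−α)R matches its
geometric closed form to 1e-12 over 50 steps.

The engagement predictor is a tanh RNN with a sigmoid head trained by
full-unroll backpropagation through time and plain gradient descent — no
adaptive optimizers, so training is bit-deterministic given a seed.  The
gradient is vectorized across equal-length sequences but identical to
the per-sequence recursion (checked against central finite differences
to 1e-5 relative).  The descent step is scaled by the number of observed
points, making the learning rate a per-sample quantity whose stability
does not depend on dataset size; the default (5.0 per-sample) was chosen
for stable convergence on desk-scale sets.  Parameter-recovery tests
train on 200 length-8 sequences from a known 3-hidden-unit generator
with observation noise sd 0.02 and require held-out MSE within twice the
noise floor.

## Personalization and group RL

Q-learning is tabular with an explicit discretization: engagement and
scalarized fitness in five uniform bins each, actions on an
intensity × duration × modality grid inside the box constraints (default
modalities: aerobic, team, skill, relaxation, high-energy).  The
vector-valued fitness inside the scalar reward is reduced by the mean of
its standardized components.  Exploration is ε-greedy with exponential
decay; ties in the argmax break to the lowest action index so training
is deterministic per seed.  On every deterministic MDP up to 5 × 5 in
the test battery, repeated sweeps of the update reach the
value-iteration fixed point within 1e-6.

Group optimization reuses the same update with group-mean state bins and
the reward −L_group + α₁E_group + α₂F_group (collective values are
arithmetic means).  Constraint handling is action masking: actions whose
one-step outcome violates the engagement/fitness floors are excluded
from both the behavior policy and the greedy argmax, and an empty
feasible set raises an infeasibility error rather than silently
relaxing.  Two cohesion measures coexist — dispersion around the group
mean, and mean pairwise squared difference over graph edges; on a
complete graph the latter equals 2L/(N−1) for scalar states, used as a
cross-consistency oracle.  Graph edges are directed (w_ij ≠ w_ji
allowed), matching the asymmetric attention weights.

## Feedback

The threshold classifier leaves a gap between the ε-band and the
κ-tolerance; rather than mislabeling it, an explicit MARGINAL class maps
to "monitor, no adjustment" (ε ≤ κ is enforced at construction).  The
motivational function h is the least-squares slope of the last five
performance points (pluggable); fatigue-risk inputs H and V are expected
z-scored against a rolling baseline so the weights are scale-free.  The
intensity gate A ← A − ρ·D activates only above the risk threshold and
clamps into the intensity box.

## The closed loop

Each step renders the participant's latent affective condition (driven
by internal fatigue, stress and engagement) as synthetic EEG, classifies
it against the participant's resting baseline, and lets the policy
choose an activity.  Task performance rewards choosing the modality and
intensity suited to the latent state (the same pairing the rule table
prescribes), degraded by accumulated fatigue; the gamified reward,
normalized by its maximum attainable value, drives engagement decay;
fitness follows the linear controlled update plus disturbances;
fatigue accumulates with intensity and recovers during relaxation.

The online learner shares one Q-table across participants: the mapping
from observed emotion to suitable activity is common structure, and
sharing quadruples the experience per step at desk scale.  Per-participant
preference learning lives in the dedicated personalization environment
instead.  The gate's adjustment rate default (ρ = 0.8) is set so that at
typical performance deviations the gated intensity falls below the
fatigue-recovery break-even point — a gate too weak to permit recovery
would never discharge the risk it detects.  The fatigue gate can also be
switched on orthogonally to the policy (`gating: true`), which is how
its effect is measured cleanly: comparing `rl+feedback` against `rl`
confounds the gate with what the learner experiences.

The mental-health index is an occupancy-weighted average over observed
emotional states with focus/relaxation weighted high and
stress/overload low.  It is an explicit placeholder for a validated
mapping from emotion occupancy to clinical symptom scores, which does
not exist in this package.

## Study conditions and problem sizes

The closed-loop comparisons use 20 seeded runs of 4 participants over
100 steps (EEG: 4 s at 256 Hz per participant-step, SNR 10), chosen as
desk-scale conditions that let the online learner converge while keeping
a full run under a second.  Recovery checks use 1000 transitions, 5000
literacy observations, and 200 training sequences.  Reported policy
contrasts are paired by seed and tested one-sided at α = 0.05.

## Limitations

Synthetic EEG is stationary band-limited sinusoids plus white noise; it
has no 1/f background, no artifacts, no inter-channel covariance
structure, and its baseline never drifts — passing the rule-engine tests
says nothing about classification accuracy on recorded EEG.  The
participant environment's task-score and fatigue laws are invented
plumbing whose only role is to make the closed loop well-posed and
learnable.  The biomechanical module is single-joint; multi-link
dynamics, muscle models and motion-capture formats are out of scope, as
are artifact rejection, spatial filtering and real EEG file formats.
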