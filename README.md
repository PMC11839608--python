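# apeo

A closed-loop simulator for **EEG-informed adaptive physical-education
interventions**.  It models a cohort of adolescent participants whose
affective state is read out from EEG band powers, classified by a rule
engine, and fed back into activity prescriptions through PID control,
tabular Q-learning, gamified engagement dynamics, biomechanical force
optimization, and group-level scheduling — all on fully synthetic data,
so every pipeline can be validated against known ground truth.

## Who it is for

Researchers prototyping adaptive-intervention logic (monitor → classify →
act) who need a reproducible, inspectable sandbox before touching real
EEG or wearable data: every generator is seeded, every statistic in a run
report can be recomputed from the emitted CSV, and every core operation
is checked against an independent oracle (value iteration, closed forms,
least-squares recovery, finite differences).

## The model in brief

**Emotion read-out.**  Theta (4–8 Hz), alpha (8–13 Hz) and beta
(13–30 Hz) band powers are extracted by Welch PSD from 1–50 Hz band-passed
traces.  Relative to a resting baseline, rules fire in fixed precedence:
θ/α ratio ↓ → overload/fatigue; β ↑ → stress/anxiety; θ ↑ → focus; α ↑ →
relaxed/low engagement; β and α ↓ → lack of interest.  Each state maps to
an activity adjustment (relaxation, team sports, rest, skill tasks,
high-energy) with a target outcome.

**Dynamics and control.**  Participant state S = [F, E, A] (fitness,
engagement, adherence) evolves as S(t+1) = S(t) + W·u + D·d under
interventions u and disturbances d, with engagement/adherence clamped to
[0, 1]; a first-order relaxation S(t) = S\* + (S₀ − S\*)e^(−t/τ) provides
the closed-form oracle.  A discrete PID law u = Kₚe + Kᵢ∫e + K_d ė tracks
fitness targets.

**Engagement and gamification.**  E = f(M, S, C) with intrinsic
motivation M = enjoyment/effort, social influence S = Σⱼ wᵢⱼEⱼ (softmax
attention over participant embeddings), competency C = skill gain /
requirement; rewards R = β₁T + β₂E + γ·max(0, T − T_th) drive geometric
engagement decay E(t+1) = αE + (1−α)R.  A tanh RNN with sigmoid head,
trained by backpropagation through time, predicts engagement sequences.

**Personalization and groups.**  Tabular Q-learning
Q(s,a) ← Q + η[r + γ max Q(s′,·) − Q] selects (intensity, duration,
modality) triples inside box constraints; reward r = α₁E + α₂F − β(γ₁I² +
γ₂D).  Group scheduling minimizes the cohesion loss Σᵢ‖Sᵢ − Ḡ‖² with
constraint-violating actions masked, and a graph measure
(1/|E|)Σ‖Sᵢ − Sⱼ‖² cross-checks it on complete graphs.

**Feedback.**  Fatigue risk αH + βV − ζR gates intensity down
(A ← A − ρ·D) whenever it exceeds a threshold, before the prescription is
applied.

## Worked example

```sh
python examples/closed_loop.py
```

prints (seed 7, 100 steps, 4 participants):

```
policy          mean E  risk steps  cum. reward  MH index
random           0.196         261        492.1     0.186
random+gate      0.234         177        428.5     0.264
pid_only         0.488          92        605.9     0.582
rl               0.287          57        404.7     0.392
rl+feedback      0.258         151        433.0     0.339
```

`mean E` is the average engagement over all logged steps, `risk steps`
counts steps whose fatigue risk exceeded the gating threshold, and
`MH index` is the occupancy-weighted mental-health read-out of the
observed emotional states (1 = always focused, 0 = always stressed or
fatigued).  Policies that exploit the emotion read-out raise engagement
and the mental-health index over random prescription, and turning on the
fatigue gate under a fixed policy (`random` vs `random+gate`) cuts risk
exposure.  Other examples in `examples/` demonstrate the EEG classifier,
PID tracking, single-participant personalization, RNN training, and
group scheduling, each printing the numbers it computes.

A thin CLI wraps the same library:

```sh
apeo simulate --out run/ --seed 1 --policy rl
apeo classify-eeg --input trace.csv --baseline rest.csv
apeo report --timeseries run/timeseries.csv --out summary.json
```

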