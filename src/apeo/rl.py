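"""Tabular Q-learning personalization of activity parameters.

Actions are (intensity, duration, modality) triples on a discretized grid
inside their box constraints; states are discretized (engagement,
scalarized fitness) bins.  The per-step reward balances engagement and
fitness improvement against an effort cost quadratic in intensity and
linear in duration.  The update is the standard Bellman-backup rule
Q(s,a) ← Q(s,a) + eta·[r + gamma·max_a' Q(s',a') − Q(s,a)], with
epsilon-greedy exploration and deterministic tie-breaking (lowest action
index).
"""

from __future__ import annotations

import csv
from collections.abc import Callable, Sequence
from dataclasses import dataclass, field

import numpy as np

from apeo.errors import ConfigError, ConstraintError, DomainError

__all__ = [
    "ActivityBounds",
    "ActivityParams",
    "RewardWeights",
    "ActionGrid",
    "QTable",
    "EpsilonSchedule",
    "ParticipantEnv",
    "activity_loss",
    "effort_cost",
    "step_reward",
    "scalarize_fitness",
    "q_update",
    "train_policy",
    "qtable_to_csv",
    "qtable_from_csv",
]

DEFAULT_MODALITIES = ("aerobic", "team", "skill", "relaxation", "high_energy")


@dataclass(frozen=True)
class ActivityBounds:
    """Box constraints for intensity (unitless) and duration (minutes)."""

    I_min: float = 0.0
    I_max: float = 1.0
    D_min: float = 10.0
    D_max: float = 60.0
    modalities: tuple[str, ...] = DEFAULT_MODALITIES

    def __post_init__(self) -> None:
        if self.I_min >= self.I_max or self.D_min >= self.D_max:
            raise DomainError("bounds must satisfy min < max")
        if not self.modalities:
            raise DomainError("at least one modality required")


DEFAULT_BOUNDS = ActivityBounds()


@dataclass(frozen=True)
class ActivityParams:
    """One intervention triple, validated against its box constraints."""

    intensity: float
    duration: float
    modality: str
    bounds: ActivityBounds = DEFAULT_BOUNDS

    def __post_init__(self) -> None:
        b = self.bounds
        if not b.I_min <= self.intensity <= b.I_max:
            raise ConstraintError(
                f"intensity {self.intensity} outside [{b.I_min}, {b.I_max}]")
        if not b.D_min <= self.duration <= b.D_max:
            raise ConstraintError(
                f"duration {self.duration} outside [{b.D_min}, {b.D_max}]")
        if self.modality not in b.modalities:
            raise ConstraintError(
                f"modality {self.modality!r} not in {b.modalities}")


@dataclass(frozen=True)
class RewardWeights:
    alpha1: float = 1.0      # engagement weight
    alpha2: float = 1.0      # fitness weight
    beta_effort: float = 0.5  # effort penalty
    gamma1: float = 1.0      # intensity (quadratic) effort scale
    gamma2: float = 0.01     # duration (linear) effort scale

    def __post_init__(self) -> None:
        if min(self.alpha1, self.alpha2, self.beta_effort,
               self.gamma1, self.gamma2) < 0:
            raise DomainError("reward weights must be >= 0")


@dataclass(frozen=True)
class ActionGrid:
    """Cartesian action grid: I points × D points × modalities.

    Action index enumerates modality-major, then intensity, then duration,
    giving a stable, documented ordering.
    """

    bounds: ActivityBounds = DEFAULT_BOUNDS
    n_intensity: int = 5
    n_duration: int = 5

    def __post_init__(self) -> None:
        if self.n_intensity < 1 or self.n_duration < 1:
            raise DomainError("grid needs at least one point per axis")

    @property
    def intensities(self) -> np.ndarray:
        return np.linspace(self.bounds.I_min, self.bounds.I_max,
                           self.n_intensity)

    @property
    def durations(self) -> np.ndarray:
        return np.linspace(self.bounds.D_min, self.bounds.D_max,
                           self.n_duration)

    def __len__(self) -> int:
        return len(self.bounds.modalities) * self.n_intensity * self.n_duration

    def action(self, index: int) -> ActivityParams:
        if not 0 <= index < len(self):
            raise IndexError(f"action index {index} outside [0, {len(self)})")
        per_mod = self.n_intensity * self.n_duration
        m, rest = divmod(index, per_mod)
        i, d = divmod(rest, self.n_duration)
        return ActivityParams(
            intensity=float(self.intensities[i]),
            duration=float(self.durations[d]),
            modality=self.bounds.modalities[m],
            bounds=self.bounds,
        )

    def actions(self) -> list[ActivityParams]:
        return [self.action(k) for k in range(len(self))]


@dataclass
class QTable:
    """Sparse state-action value table; unseen pairs read as
    ``initial_value``."""

    n_actions: int
    eta_lr: float = 0.1
    gamma_discount: float = 0.9
    initial_value: float = 0.0
    values: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.eta_lr <= 1:
            raise DomainError(f"eta_lr must be in (0,1], got {self.eta_lr}")
        if not 0 <= self.gamma_discount < 1:
            raise DomainError(
                f"gamma_discount must be in [0,1), got {self.gamma_discount}")

    def get(self, s, a: int) -> float:
        return self.values.get((s, a), self.initial_value)

    def max_value(self, s, allowed: Sequence[int] | None = None) -> float:
        idx = range(self.n_actions) if allowed is None else allowed
        return max(self.get(s, a) for a in idx)

    def greedy(self, s, allowed: Sequence[int] | None = None) -> int:
        """Best action; ties break to the lowest index (deterministic)."""
        idx = range(self.n_actions) if allowed is None else allowed
        best, best_a = -np.inf, None
        for a in idx:
            v = self.get(s, a)
            if v > best:
                best, best_a = v, a
        if best_a is None:
            raise DomainError("no allowed actions")
        return best_a


def activity_loss(
    F_target: np.ndarray,
    F_actual_fn: Callable[[ActivityParams], np.ndarray],
    activities: Sequence[ActivityParams],
) -> float:
    """Sum over activities of ||F_target − F_actual(I, D, M)||²."""
    F_target = np.atleast_1d(np.asarray(F_target, dtype=float))
    total = 0.0
    for act in activities:  # constructing ActivityParams enforced the boxes
        diff = F_target - np.atleast_1d(np.asarray(F_actual_fn(act), float))
        total += float(diff @ diff)
    return total


def effort_cost(params: ActivityParams | Sequence[ActivityParams],
                weights: RewardWeights) -> float:
    """Effort cost gamma1·I² + gamma2·D summed over concurrent activities."""
    acts = [params] if isinstance(params, ActivityParams) else list(params)
    return sum(weights.gamma1 * a.intensity**2 + weights.gamma2 * a.duration
               for a in acts)


def step_reward(E: float, F_scalar: float, C_effort: float,
                weights: RewardWeights) -> float:
    """Immediate reward r = alpha1·E + alpha2·F − beta·C_effort."""
    for name, v in (("E", E), ("F_scalar", F_scalar), ("C_effort", C_effort)):
        if not np.isfinite(v):
            raise DomainError(f"{name} must be finite")
    return (weights.alpha1 * E + weights.alpha2 * F_scalar
            - weights.beta_effort * C_effort)


def scalarize_fitness(F: np.ndarray) -> float:
    """Reduce a fitness vector to a scalar: mean of its components (they
    are standardized scores, so the mean is scale-consistent)."""
    return float(np.mean(np.atleast_1d(np.asarray(F, dtype=float))))


def q_update(Q: QTable, s, a: int, r: float, s_next,
             terminal: bool = False) -> QTable:
    """In-place Bellman backup on the (s, a) entry; returns Q."""
    if not 0 <= a < Q.n_actions:
        raise IndexError(f"action index {a} outside [0, {Q.n_actions})")
    target = r if terminal else r + Q.gamma_discount * Q.max_value(s_next)
    current = Q.get(s, a)
    Q.values[(s, a)] = current + Q.eta_lr * (target - current)
    return Q


@dataclass(frozen=True)
class EpsilonSchedule:
    """Exponentially decaying exploration rate
    eps(episode) = max(end, start·decay^episode)."""

    start: float = 1.0
    end: float = 0.05
    decay: float = 0.97

    def __post_init__(self) -> None:
        if not (0 <= self.end <= self.start <= 1):
            raise ConfigError("need 0 <= end <= start <= 1")
        if not 0 < self.decay <= 1:
            raise ConfigError(f"decay must be in (0,1], got {self.decay}")

    def __call__(self, episode: int) -> float:
        return max(self.end, self.start * self.decay**episode)


class ParticipantEnv:
    """Simulated single-participant environment for policy training.

    Hidden state: engagement E in [0,1] and a scalar fitness score.  Each
    action is an index into an :class:`ActionGrid`.  Task performance is
    highest when intensity is near the participant's preferred intensity
    and the modality matches their preference; engagement then relaxes
    toward the gamified reward and fitness accrues with a dose-response
    that saturates at high effort.  Episodes have a fixed horizon.
    """

    def __init__(
        self,
        grid: ActionGrid | None = None,
        weights: RewardWeights | None = None,
        preferred_modality: str = "team",
        preferred_intensity: float = 0.5,
        horizon: int = 20,
        alpha_decay: float = 0.7,
        n_bins: int = 5,
        noise_sd: float = 0.0,
        seed: int | None = None,
    ) -> None:
        self.grid = grid if grid is not None else ActionGrid()
        self.weights = weights if weights is not None else RewardWeights()
        if preferred_modality not in self.grid.bounds.modalities:
            raise ConfigError(
                f"preferred_modality {preferred_modality!r} not in grid")
        self.preferred_modality = preferred_modality
        self.preferred_intensity = preferred_intensity
        self.horizon = horizon
        self.alpha_decay = alpha_decay
        self.n_bins = n_bins
        self.noise_sd = noise_sd
        self.rng = np.random.default_rng(seed)
        self.reset()

    @property
    def n_actions(self) -> int:
        return len(self.grid)

    def _discretize(self) -> tuple[int, int]:
        eb = min(int(self.E * self.n_bins), self.n_bins - 1)
        fb = min(int(np.clip(self.F, 0.0, 1.0 - 1e-9) * self.n_bins),
                 self.n_bins - 1)
        return eb, fb

    def reset(self):
        self.E = 0.5
        self.F = 0.2
        self.t = 0
        return self._discretize()

    def task_score(self, act: ActivityParams) -> float:
        match = 1.0 if act.modality == self.preferred_modality else 0.4
        fit = 1.0 - (act.intensity - self.preferred_intensity) ** 2
        return max(0.0, match * fit)

    def step(self, action_index: int):
        act = self.grid.action(action_index)
        T = self.task_score(act)
        if self.noise_sd > 0:
            T = max(0.0, T + self.rng.normal(0.0, self.noise_sd))
        # gamified reward drives engagement relaxation
        R_game = min(1.0, 0.5 * T + 0.5 * self.E)
        self.E = min(1.0, max(0.0, self.alpha_decay * self.E
                              + (1 - self.alpha_decay) * R_game))
        # saturating fitness dose-response in intensity x duration
        dose = act.intensity * act.duration / self.grid.bounds.D_max
        self.F = min(1.0, self.F + 0.05 * dose * (1.0 - self.F))
        C = effort_cost(act, self.weights)
        r = step_reward(self.E, self.F, C, self.weights)
        self.t += 1
        done = self.t >= self.horizon
        return self._discretize(), r, done


def train_policy(
    env,
    episodes: int,
    epsilon_schedule: EpsilonSchedule | Callable[[int], float] | None = None,
    seed: int | None = None,
    eta_lr: float = 0.1,
    gamma_discount: float = 0.9,
) -> tuple[QTable, list[float]]:
    """Epsilon-greedy Q-learning on an environment.

    ``env`` must expose ``n_actions``, ``reset() -> state`` and
    ``step(a) -> (state, reward, done)``.  Deterministic per seed.
    Returns the learned table and the per-episode return trace.
    """
    if episodes < 1:
        raise DomainError(f"episodes must be >= 1, got {episodes}")
    if epsilon_schedule is None:
        epsilon_schedule = EpsilonSchedule()
    elif not callable(epsilon_schedule):
        raise ConfigError("epsilon_schedule must be callable or None")
    rng = np.random.default_rng(seed)
    Q = QTable(n_actions=env.n_actions, eta_lr=eta_lr,
               gamma_discount=gamma_discount)
    returns = []
    for ep in range(episodes):
        eps = float(epsilon_schedule(ep))
        if not 0 <= eps <= 1:
            raise ConfigError(f"epsilon schedule produced {eps} at episode {ep}")
        s = env.reset()
        done, total = False, 0.0
        while not done:
            if rng.random() < eps:
                a = int(rng.integers(env.n_actions))
            else:
                a = Q.greedy(s)
            s_next, r, done = env.step(a)
            q_update(Q, s, a, r, s_next, terminal=done)
            s = s_next
            total += r
        returns.append(total)
    return Q, returns


def qtable_to_csv(Q: QTable, path) -> None:
    """Rows (state, action_index, value); states serialized with repr."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["state", "action_index", "value"])
        for (s, a), v in sorted(Q.values.items(), key=lambda kv: (repr(kv[0][0]), kv[0][1])):
            w.writerow([repr(s), a, repr(v)])


def qtable_from_csv(path, n_actions: int, **kwargs) -> QTable:
    import ast

    Q = QTable(n_actions=n_actions, **kwargs)
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            Q.values[(ast.literal_eval(row["state"]), int(row["action_index"]))] = \
                float(row["value"])
    return Q
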