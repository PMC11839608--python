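"""Group-level aggregation, cohesion, constraints, social graph dynamics,
and group reinforcement learning.

Two cohesion measures coexist: the dispersion of member states around the
group mean (sum of squared deviations) and the mean pairwise squared
difference over the edges of a social graph.  On a complete graph the two
are proportional, which the tests exploit as a cross-consistency oracle.
Group activity selection reuses the tabular Q-learning update with
group-state bins; actions violating the engagement/fitness floors are
masked out of both the behavior policy and the greedy argmax.
"""

from __future__ import annotations

import csv
from collections.abc import Sequence
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from apeo.dynamics import ParticipantState
from apeo.errors import DomainError, InfeasibleError, ShapeError
from apeo.rl import ActionGrid, EpsilonSchedule, QTable, q_update

__all__ = [
    "GroupState",
    "GroupConstraints",
    "SocialGraph",
    "group_state",
    "cohesion_loss",
    "check_constraints",
    "group_reward",
    "graph_cohesion",
    "distribute_group_rewards",
    "update_influence",
    "optimize_group_activity",
    "joint_objective",
]


@dataclass
class GroupState:
    """Mean state of a group plus the member states it was computed from."""

    mean_state: ParticipantState
    member_states: list[ParticipantState]


@dataclass(frozen=True)
class GroupConstraints:
    """Engagement floor (scalar in [0,1]) and per-component fitness floor."""

    E_min: float = 0.0
    F_min: np.ndarray | float = -np.inf

    def __post_init__(self) -> None:
        if not 0 <= self.E_min <= 1:
            raise DomainError(f"E_min must be in [0,1], got {self.E_min}")
        object.__setattr__(self, "F_min",
                           np.atleast_1d(np.asarray(self.F_min, dtype=float)))


class SocialGraph:
    """Directed participant graph with nonnegative influence weights.

    Thin wrapper around ``networkx.DiGraph``; edge (i, j) carries w_ij,
    the influence of peer j on participant i.  Self-edges are rejected.
    """

    def __init__(self) -> None:
        self._g = nx.DiGraph()

    @property
    def graph(self) -> nx.DiGraph:
        return self._g

    def add_node(self, i) -> None:
        self._g.add_node(i)

    def add_edge(self, i, j, weight: float) -> None:
        if i == j:
            raise DomainError(f"self-edge ({i}, {i}) not allowed")
        if not np.isfinite(weight) or weight < 0:
            raise DomainError(f"weight must be finite and >= 0, got {weight}")
        self._g.add_edge(i, j, weight=float(weight))

    def weight(self, i, j) -> float:
        return self._g.edges[i, j]["weight"]

    def edges(self):
        return [(i, j, d["weight"]) for i, j, d in self._g.edges(data=True)]

    @classmethod
    def from_edge_csv(cls, path) -> "SocialGraph":
        g = cls()
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                g.add_edge(row["src"], row["dst"], float(row["weight"]))
        return g

    def to_edge_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["src", "dst", "weight"])
            for i, j, wt in self.edges():
                w.writerow([i, j, repr(wt)])


def _check_layouts(states: Sequence[ParticipantState]) -> int:
    dims = {s.dim for s in states}
    if len(dims) > 1:
        raise ShapeError(f"member state layouts differ: dims {dims}")
    return dims.pop()


def group_state(states: Sequence[ParticipantState]) -> GroupState:
    """Component-wise mean of member states."""
    states = list(states)
    if not states:
        raise DomainError("group must have at least one participant")
    _check_layouts(states)
    mean_vec = np.mean([s.as_vector() for s in states], axis=0)
    return GroupState(
        mean_state=ParticipantState.from_vector(mean_vec, t=states[0].t),
        member_states=states,
    )


def cohesion_loss(states: Sequence[ParticipantState],
                  G: GroupState | None = None) -> float:
    """Dispersion around the group mean: sum_i ||S_i − mean||².

    Equals N·(population variance) for scalar states; zero iff all member
    states are identical.
    """
    states = list(states)
    if G is None:
        G = group_state(states)
    else:
        mean_vec = np.mean([s.as_vector() for s in states], axis=0)
        if not np.allclose(mean_vec, G.mean_state.as_vector(), atol=1e-9):
            raise DomainError("provided group state is not the mean of states")
    g = G.mean_state.as_vector()
    return float(sum(np.sum((s.as_vector() - g) ** 2) for s in states))


def check_constraints(
    states: Sequence[ParticipantState],
    constraints: GroupConstraints,
) -> list[tuple[int, str, float]]:
    """Violation report: (participant index, quantity, value) for every
    member strictly below a floor (boundary values satisfy the >= floors)."""
    report = []
    for idx, s in enumerate(states):
        if s.engagement < constraints.E_min:
            report.append((idx, "engagement", s.engagement))
        F_min = constraints.F_min
        fit = s.fitness
        if F_min.size not in (1, fit.size):
            raise ShapeError(
                f"F_min size {F_min.size} incompatible with fitness size "
                f"{fit.size}")
        floors = np.broadcast_to(F_min, fit.shape)
        for k, (f, fl) in enumerate(zip(fit, floors)):
            if f < fl:
                report.append((idx, f"fitness[{k}]", float(f)))
    return report


def group_reward(L_group: float, E_group: float, F_group: float,
                 alpha1: float = 1.0, alpha2: float = 1.0) -> float:
    """Per-step group reward term −L_group + alpha1·E_group + alpha2·F_group."""
    if alpha1 < 0 or alpha2 < 0:
        raise DomainError("weights must be >= 0")
    return -L_group + alpha1 * E_group + alpha2 * F_group


def graph_cohesion(graph: SocialGraph,
                   states: dict) -> float:
    """Mean pairwise squared state difference over graph edges:
    (1/|E|)·sum_(i,j) ||S_i − S_j||².  Raises on an empty edge set rather
    than returning a silent 0."""
    edges = graph.edges()
    if not edges:
        raise DomainError("graph cohesion undefined on an empty edge set")
    total = 0.0
    for i, j, _w in edges:
        if i not in states or j not in states:
            raise DomainError(f"edge ({i}, {j}) endpoint missing a state")
        si = np.atleast_1d(np.asarray(
            states[i].as_vector() if isinstance(states[i], ParticipantState)
            else states[i], dtype=float))
        sj = np.atleast_1d(np.asarray(
            states[j].as_vector() if isinstance(states[j], ParticipantState)
            else states[j], dtype=float))
        total += float(np.sum((si - sj) ** 2))
    return total / len(edges)


def distribute_group_rewards(T_scores: Sequence[float],
                             E_levels: Sequence[float],
                             alpha: float = 1.0,
                             beta: float = 1.0) -> float:
    """Collective reward (1/N)·sum_i (alpha·T_i + beta·E_i)."""
    if alpha < 0 or beta < 0:
        raise DomainError("weights must be >= 0")
    T = np.asarray(T_scores, dtype=float)
    E = np.asarray(E_levels, dtype=float)
    if T.shape != E.shape:
        raise ShapeError(f"T shape {T.shape} != E shape {E.shape}")
    if T.size == 0:
        raise DomainError("need at least one participant")
    return float(np.mean(alpha * T + beta * E))


def update_influence(w_ij: float, E_i: float, E_j: float,
                     eta_w: float) -> tuple[float, bool]:
    """Influence adaptation w_ij ← w_ij + eta·(E_j − E_i), floored at 0.

    Returns (new weight, clamped flag)."""
    if eta_w < 0:
        raise DomainError(f"eta_w must be >= 0, got {eta_w}")
    raw = w_ij + eta_w * (E_j - E_i)
    return (0.0, True) if raw < 0 else (raw, False)


class GroupEnv:
    """Environment over group states for group-level Q-learning.

    ``member_response(act) -> list[ParticipantState]`` advances every
    member under a common activity; the reward is
    −L_group + alpha1·E_group + alpha2·F_group.
    """

    def __init__(self, member_response, initial_states,
                 grid: ActionGrid, constraints: GroupConstraints | None = None,
                 horizon: int = 10, alpha1: float = 1.0, alpha2: float = 1.0,
                 n_bins: int = 5) -> None:
        self.member_response = member_response
        self.initial_states = list(initial_states)
        self.grid = grid
        self.constraints = constraints
        self.horizon = horizon
        self.alpha1, self.alpha2 = alpha1, alpha2
        self.n_bins = n_bins
        self.reset()

    @property
    def n_actions(self) -> int:
        return len(self.grid)

    def _bin(self) -> tuple[int, int]:
        G = group_state(self.states).mean_state
        eb = min(int(G.engagement * self.n_bins), self.n_bins - 1)
        f = float(np.clip(np.mean(G.fitness), 0.0, 1.0 - 1e-9))
        return eb, min(int(f * self.n_bins), self.n_bins - 1)

    def reset(self):
        self.states = list(self.initial_states)
        self.t = 0
        return self._bin()

    def allowed_actions(self) -> list[int]:
        """Actions whose one-step outcome satisfies the group floors."""
        if self.constraints is None:
            return list(range(self.n_actions))
        ok = []
        for k in range(self.n_actions):
            nxt = self.member_response(self.grid.action(k), self.states)
            if not check_constraints(nxt, self.constraints):
                ok.append(k)
        return ok

    def step(self, action_index: int):
        act = self.grid.action(action_index)
        self.states = self.member_response(act, self.states)
        G = group_state(self.states)
        L = cohesion_loss(self.states, G)
        r = group_reward(L, G.mean_state.engagement,
                         float(np.mean(G.mean_state.fitness)),
                         self.alpha1, self.alpha2)
        self.t += 1
        return self._bin(), r, self.t >= self.horizon


def optimize_group_activity(
    env: GroupEnv,
    episodes: int = 50,
    epsilon_schedule: EpsilonSchedule | None = None,
    seed: int | None = None,
    eta_lr: float = 0.2,
    gamma_discount: float = 0.9,
) -> tuple[QTable, list[ActivityParamsSchedule]]:
    """Group-level Q-learning with constraint masking.

    Infeasible actions (those violating the group floors) are excluded
    from both exploration and the greedy argmax.  Returns the learned
    table and the greedy schedule replayed from the initial group state.
    """
    if epsilon_schedule is None:
        epsilon_schedule = EpsilonSchedule()
    rng = np.random.default_rng(seed)
    Q = QTable(n_actions=env.n_actions, eta_lr=eta_lr,
               gamma_discount=gamma_discount)
    for ep in range(episodes):
        eps = epsilon_schedule(ep)
        s = env.reset()
        done = False
        while not done:
            allowed = env.allowed_actions()
            if not allowed:
                raise InfeasibleError(
                    "no activity satisfies the group constraints")
            if rng.random() < eps:
                a = int(allowed[rng.integers(len(allowed))])
            else:
                a = Q.greedy(s, allowed=allowed)
            s_next, r, done = env.step(a)
            q_update(Q, s, a, r, s_next, terminal=done)
            s = s_next
    # replay greedily for the recommended schedule
    schedule = []
    s = env.reset()
    done = False
    while not done:
        allowed = env.allowed_actions()
        if not allowed:
            raise InfeasibleError("no activity satisfies the group constraints")
        a = Q.greedy(s, allowed=allowed)
        act = env.grid.action(a)
        s, r, done = env.step(a)
        G = group_state(env.states)
        schedule.append(ActivityParamsSchedule(
            t=env.t, intensity=act.intensity, duration=act.duration,
            modality=act.modality,
            L_group=cohesion_loss(env.states, G), R_group=r))
    return Q, schedule


@dataclass(frozen=True)
class ActivityParamsSchedule:
    """One row of a recommended group schedule."""

    t: int
    intensity: float
    duration: float
    modality: str
    L_group: float
    R_group: float


def joint_objective(
    E_levels: Sequence[float],
    progress: Sequence[float],
    lambda1: float,
    lambda2: float,
    C_balance: float,
    tau_balance: float,
) -> tuple[float, bool]:
    """Joint engagement-progress objective sum_i (l1·E_i + l2·progress_i)
    with feasibility C_balance <= tau (boundary feasible)."""
    if lambda1 < 0 or lambda2 < 0:
        raise DomainError("lambda weights must be >= 0")
    E = np.asarray(E_levels, dtype=float)
    P = np.asarray(progress, dtype=float)
    if E.shape != P.shape:
        raise ShapeError(f"E shape {E.shape} != progress shape {P.shape}")
    value = float(np.sum(lambda1 * E + lambda2 * P))
    return value, C_balance <= tau_balance
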