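"""Group aggregation, cohesion measures, social dynamics, and group RL."""

import itertools

import numpy as np
import pytest

from apeo.dynamics import ParticipantState
from apeo.errors import DomainError, ShapeError
from apeo.group import (
    GroupConstraints,
    GroupEnv,
    SocialGraph,
    check_constraints,
    cohesion_loss,
    distribute_group_rewards,
    graph_cohesion,
    group_reward,
    group_state,
    joint_objective,
    optimize_group_activity,
    update_influence,
)
from apeo.rl import ActionGrid, ActivityBounds


def st_scalar(f, e=0.5, a=0.5):
    return ParticipantState(fitness=np.array([f]), engagement=e, adherence=a)


class TestGroupState:
    def test_scalar_mean(self):
        G = group_state([st_scalar(0.0), st_scalar(2.0)])
        assert G.mean_state.fitness[0] == pytest.approx(1.0)

    def test_identical_states(self):
        G = group_state([st_scalar(0.3, 0.4, 0.5)] * 3)
        assert np.allclose(G.mean_state.as_vector(), [0.3, 0.4, 0.5])

    def test_empty_group_rejected(self):
        with pytest.raises(DomainError):
            group_state([])

    def test_mismatched_layouts_rejected(self):
        a = st_scalar(1.0)
        b = ParticipantState(fitness=np.array([1.0, 2.0]), engagement=0.5,
                             adherence=0.5)
        with pytest.raises(ShapeError):
            group_state([a, b])


class TestCohesionLoss:
    def test_zero_for_identical_states(self):
        assert cohesion_loss([st_scalar(0.4)] * 4) == 0.0

    def test_scalar_hand_computed(self):
        # fitness {0, 2}: (0-1)^2 + (2-1)^2 = 2
        assert cohesion_loss([st_scalar(0.0), st_scalar(2.0)]) == \
            pytest.approx(2.0)

    def test_permutation_invariant(self, rng):
        states = [st_scalar(float(v), float(e), 0.5)
                  for v, e in rng.uniform(0, 1, size=(5, 2))]
        base = cohesion_loss(states)
        for perm in itertools.permutations(states):
            assert cohesion_loss(list(perm)) == pytest.approx(base)

    def test_adding_member_at_mean_leaves_loss_unchanged(self):
        states = [st_scalar(0.0, 0.2, 0.4), st_scalar(2.0, 0.8, 0.6)]
        L = cohesion_loss(states)
        mean = group_state(states).mean_state
        assert cohesion_loss(states + [mean]) == pytest.approx(L)

    def test_equals_n_times_population_variance(self, rng):
        vals = rng.uniform(0, 1, size=6)
        states = [ParticipantState(fitness=np.array([v]), engagement=0.0,
                                   adherence=0.0) for v in vals]
        assert cohesion_loss(states) == pytest.approx(
            len(vals) * np.var(vals))


class TestConstraints:
    def test_flags_below_floor(self):
        states = [st_scalar(1.0, 0.5, 0.5), st_scalar(1.0, 0.7, 0.5)]
        report = check_constraints(states, GroupConstraints(E_min=0.6))
        assert report == [(0, "engagement", 0.5)]

    def test_empty_report_when_satisfied(self):
        states = [st_scalar(1.0, 0.9, 0.5)]
        assert check_constraints(states, GroupConstraints(E_min=0.6)) == []

    def test_boundary_value_not_flagged(self):
        states = [st_scalar(1.0, 0.6, 0.5)]
        assert check_constraints(states, GroupConstraints(E_min=0.6)) == []

    def test_fitness_floor_component_named(self):
        states = [ParticipantState(fitness=np.array([0.5, 0.1]),
                                   engagement=0.9, adherence=0.9)]
        report = check_constraints(
            states, GroupConstraints(E_min=0.0, F_min=np.array([0.2, 0.2])))
        assert report == [(0, "fitness[1]", pytest.approx(0.1))]


class TestGroupReward:
    def test_hand_computed(self):
        assert group_reward(2.0, 1.0, 1.0, 1.0, 1.0) == pytest.approx(0.0)

    def test_cohesive_group_zero_weights(self):
        assert group_reward(0.0, 0.9, 0.9, 0.0, 0.0) == 0.0

    def test_monotone_decreasing_in_dispersion(self):
        r1 = group_reward(1.0, 0.5, 0.5)
        r2 = group_reward(2.0, 0.5, 0.5)
        assert r2 < r1


class TestGraphCohesion:
    def test_single_edge_hand_computed(self):
        g = SocialGraph()
        g.add_edge("a", "b", 1.0)
        c = graph_cohesion(g, {"a": np.array([0.0]), "b": np.array([2.0])})
        assert c == pytest.approx(4.0)

    def test_zero_when_states_equal(self):
        g = SocialGraph()
        g.add_edge(1, 2, 1.0)
        g.add_edge(2, 3, 1.0)
        states = {k: np.array([0.7]) for k in (1, 2, 3)}
        assert graph_cohesion(g, states) == 0.0

    def test_reversing_edges_leaves_cohesion_unchanged(self):
        fwd, both = SocialGraph(), SocialGraph()
        states = {1: np.array([0.1]), 2: np.array([0.9]), 3: np.array([0.4])}
        for i, j in [(1, 2), (2, 3)]:
            fwd.add_edge(i, j, 1.0)
            both.add_edge(i, j, 1.0)
            both.add_edge(j, i, 1.0)
        assert graph_cohesion(both, states) == \
            pytest.approx(graph_cohesion(fwd, states))

    def test_empty_edge_set_flagged(self):
        g = SocialGraph()
        g.add_node(1)
        with pytest.raises(DomainError):
            graph_cohesion(g, {1: np.array([0.0])})

    def test_self_edge_rejected(self):
        g = SocialGraph()
        with pytest.raises(DomainError):
            g.add_edge(1, 1, 0.5)

    def test_complete_graph_crosschecks_mean_dispersion(self, rng):
        """On a complete directed graph the edge measure equals
        2/(N-1) times the dispersion around the mean (scalar states)."""
        for n in (3, 4, 6):
            vals = rng.uniform(0, 1, size=n)
            states = [ParticipantState(fitness=np.array([v]), engagement=0.0,
                                       adherence=0.0) for v in vals]
            g = SocialGraph()
            for i, j in itertools.permutations(range(n), 2):
                g.add_edge(i, j, 1.0)
            c = graph_cohesion(g, {i: states[i] for i in range(n)})
            L = cohesion_loss(states)
            assert c == pytest.approx(2.0 * L / (n - 1), rel=1e-9)


class TestInfluenceUpdate:
    def test_equal_engagement_is_fixed_point(self):
        assert update_influence(0.3, 0.5, 0.5, 0.1) == (0.3, False)

    def test_hand_computed_increment(self):
        w, clamped = update_influence(0.3, 0.2, 0.7, 0.1)
        assert w == pytest.approx(0.35)
        assert not clamped

    def test_clamped_at_zero(self):
        w, clamped = update_influence(0.01, 0.9, 0.1, 1.0)
        assert w == 0.0
        assert clamped


class TestJointObjective:
    def test_engagement_only(self):
        v, ok = joint_objective([0.5, 0.5], [0, 0], 1.0, 0.0, 0.0, 1.0)
        assert v == pytest.approx(1.0)
        assert ok

    def test_boundary_is_feasible(self):
        _, ok = joint_objective([0.5], [0.5], 1.0, 1.0, 0.7, 0.7)
        assert ok

    def test_exceeding_threshold_is_infeasible(self):
        _, ok = joint_objective([0.5], [0.5], 1.0, 1.0, 0.71, 0.7)
        assert not ok


class TestGroupOptimization:
    @staticmethod
    def _env(horizon=4, constraints=None):
        """Two members with opposite intensity responses: the group loss
        is minimized at the middle intensity."""
        init = [st_scalar(0.4, 0.5, 0.5), st_scalar(0.6, 0.5, 0.5)]

        def respond(act, members):
            a, b = members
            return [
                st_scalar(float(a.fitness[0] + 0.1 * act.intensity),
                          a.engagement, a.adherence),
                st_scalar(float(b.fitness[0] - 0.1 * act.intensity + 0.05),
                          b.engagement, b.adherence),
            ]

        grid = ActionGrid(bounds=ActivityBounds(), n_intensity=3,
                          n_duration=1)
        # pure-cohesion objective: the oracle below compares L_group only
        return GroupEnv(respond, init, grid, constraints=constraints,
                        horizon=horizon, alpha1=0.0, alpha2=0.0)

    def test_learned_schedule_beats_every_fixed_action(self):
        from apeo.rl import EpsilonSchedule

        env = self._env()
        Q, schedule = optimize_group_activity(
            env, episodes=200,
            epsilon_schedule=EpsilonSchedule(start=1.0, end=0.2, decay=0.99),
            seed=0, eta_lr=0.3)
        learned_L = schedule[-1].L_group

        def fixed_action_L(k):
            env.reset()
            done = False
            while not done:
                _, _, done = env.step(k)
            states = env.states
            return cohesion_loss(states)

        best_fixed = min(fixed_action_L(k) for k in range(env.n_actions))
        assert learned_L <= best_fixed + 1e-9

    def test_same_seed_same_schedule(self):
        _, s1 = optimize_group_activity(self._env(), episodes=30, seed=4)
        _, s2 = optimize_group_activity(self._env(), episodes=30, seed=4)
        assert s1 == s2

    def test_schedule_actions_stay_inside_boxes(self):
        env = self._env()
        _, schedule = optimize_group_activity(env, episodes=30, seed=1)
        b = env.grid.bounds
        for row in schedule:
            assert b.I_min <= row.intensity <= b.I_max
            assert b.D_min <= row.duration <= b.D_max
            assert row.modality in b.modalities


def test_distribute_group_rewards():
    assert distribute_group_rewards([0.4, 0.6], [0.0, 0.0],
                                    alpha=1.0, beta=0.0) == pytest.approx(0.5)
    assert distribute_group_rewards([0.4, 0.6], [0.2, 0.2],
                                    alpha=1.0, beta=1.0) == pytest.approx(0.7)
    assert distribute_group_rewards([0.0], [0.0]) == 0.0
    with pytest.raises(ShapeError):
        distribute_group_rewards([0.1, 0.2], [0.1])


def test_edge_csv_round_trip(tmp_path):
    g = SocialGraph()
    g.add_edge("a", "b", 0.25)
    g.add_edge("b", "a", 0.75)
    path = tmp_path / "edges.csv"
    g.to_edge_csv(path)
    back = SocialGraph.from_edge_csv(path)
    assert sorted(back.edges()) == sorted(g.edges())
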