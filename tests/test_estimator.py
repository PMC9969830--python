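"""Parameter grouping, ranking, group-wise simplex and fit bookkeeping."""

import numpy as np
import pytest

from netkin.compiler import Element, Form, Reaction, ReactionSystem, compile_network
from netkin.estimator import (
    Condition,
    ObjectiveEvaluator,
    ParameterGroup,
    Schedule,
    fit,
    group_parameters,
    initial_parameters,
    optimize_group,
    rank_groups,
)
from netkin.fixtures import FixtureSpec, make_network, make_truth_and_data, _measured_layers
from netkin.compiler import build_aggregation
from netkin.ode import build

from conftest import make_net, random_reaction_system


def tiny_system(reactions, n_elements, n_parameters):
    elements = [Element(index=i, form=Form.PROTEIN, gene=f"E{i}")
                for i in range(n_elements)]
    return ReactionSystem(elements=elements, reactions=reactions,
                          n_parameters=n_parameters,
                          parameter_names=[f"k{i}" for i in range(n_parameters)])


class TestGrouping:
    def test_synthesis_and_degradation_share_a_group(self):
        sys_ = tiny_system([Reaction((), (0,), 0, None, "0->A"),
                            Reaction((0,), (), 1, None, "A->0")], 1, 2)
        groups = group_parameters(build(sys_), sys_)
        assert len(groups) == 1
        assert groups[0].members == [0, 1]

    def test_catalyst_joins_substrate_groups(self):
        # B + A -> B + A_p: B's group holds the slot (B in the rate product)
        sys_ = tiny_system([Reaction((0, 1), (0, 2), 0, None, "cat")], 3, 1)
        groups = {g.state_variable: g.members
                  for g in group_parameters(build(sys_), sys_)}
        assert groups[0] == [0] and groups[1] == [0] and groups[2] == [0]

    def test_membership_matches_brute_force_scan(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            sys_ = random_reaction_system(rng, n_reactions=12)
            ode = build(sys_)
            groups = {g.state_variable: set(g.members)
                      for g in group_parameters(ode, sys_)}
            # oracle: scan every reaction role per element
            for i in range(sys_.n_elements):
                expected = set()
                for r in sys_.reactions:
                    net = (sum(p == i for p in r.products)
                           - sum(q == i for q in r.reactants))
                    in_rate = i in r.reactants or (
                        r.kb_index is not None and i in r.products)
                    if net != 0 or in_rate:
                        expected.add(r.kf_index)
                        if r.kb_index is not None:
                            expected.add(r.kb_index)
                assert groups.get(i, set()) == expected


class TestRanking:
    def test_hub_ranks_before_leaf(self):
        reactions = [Reaction((0,), (j,), j - 1, None, f"r{j}")
                     for j in range(1, 6)]        # element 0 in 5 reactions
        sys_ = tiny_system(reactions, 6, 5)
        sched = rank_groups(group_parameters(build(sys_), sys_))
        assert sched.groups[0].state_variable == 0
        assert sched.groups[0].repetition_count == 5

    def test_ties_break_by_element_id(self):
        sys_ = tiny_system([Reaction((0,), (1,), 0, None, "a"),
                            Reaction((2,), (3,), 1, None, "b")], 4, 2)
        sched = rank_groups(group_parameters(build(sys_), sys_))
        assert [g.state_variable for g in sched.groups] == [0, 1, 2, 3]

    def test_ranking_invariant_under_reaction_permutation(self):
        rng = np.random.default_rng(31)
        sys_ = random_reaction_system(rng, n_reactions=10)
        ref = rank_groups(group_parameters(build(sys_), sys_))
        perm = list(rng.permutation(sys_.n_reactions))
        permuted = ReactionSystem(
            elements=sys_.elements,
            reactions=[sys_.reactions[i] for i in perm],
            n_parameters=sys_.n_parameters,
            parameter_names=sys_.parameter_names)
        other = rank_groups(group_parameters(build(permuted), permuted))
        assert ([g.state_variable for g in ref.groups]
                == [g.state_variable for g in other.groups])


class TestOptimizeGroup:
    def quadratic(self, center):
        def f(K):
            return float(np.sum((np.log10(K) - center) ** 2))
        return f

    def test_recovers_1d_minimum_within_budget(self):
        f = self.quadratic(np.array([0.5]))
        group = ParameterGroup(state_variable=0, members=[0])
        K, S, nev = optimize_group(f, group, np.array([1.0]), budget=200)
        # oracle: grid search over log10 k in [-2, 2]
        grid = 10.0 ** np.linspace(-2, 2, 2001)
        best = min(f(np.array([k])) for k in grid)
        assert S <= best + 1e-4
        assert np.log10(K[0]) == pytest.approx(0.5, abs=1e-2)

    def test_zero_budget_is_a_noop(self):
        f = self.quadratic(np.array([1.0]))
        group = ParameterGroup(state_variable=0, members=[0])
        K0 = np.array([3.0])
        K, S, nev = optimize_group(f, group, K0, budget=0)
        assert K[0] == 3.0 and nev == 0

    def test_objective_never_increases(self):
        rng = np.random.default_rng(4)
        center = rng.normal(size=3)
        f = self.quadratic(center)
        group = ParameterGroup(state_variable=0, members=[0, 1, 2])
        K0 = np.ones(3)
        S0 = f(K0)
        K, S, _ = optimize_group(f, group, K0, budget=50)
        assert S <= S0

    def test_frozen_slots_are_bit_identical(self):
        def f(K):
            return float((np.log10(K[0]) - 1.0) ** 2 + K[1] + K[2])
        group = ParameterGroup(state_variable=0, members=[0])
        K0 = np.array([1.0, 0.7071067811865476, 3.141592653589793])
        K, _, _ = optimize_group(f, group, K0, budget=100)
        assert K[1] == K0[1] and K[2] == K0[2]

    def test_nonpositive_parameters_rejected(self):
        group = ParameterGroup(state_variable=0, members=[0])
        with pytest.raises(ValueError):
            optimize_group(lambda K: 0.0, group, np.array([-1.0]), budget=10)


class TestConditions:
    def test_inhibition_scales_catalytic_forward_constants(self):
        net = make_net([("B", "A", "phosphorylation", "activation"),
                        ("A", "B", "binding", "activation")])
        sys_ = compile_network(net)
        cond = Condition("drug", inhibit={"B": 0.0})
        idx, fac = cond.parameter_scaling(sys_)
        targeted = {sys_.parameter_names[i] for i in idx}
        assert targeted == {"kF[phosphorylation:B->A]"}
        K = np.ones(sys_.n_parameters)
        K_eff = cond.apply(K, sys_)
        assert K_eff[idx[0]] == 0.0
        assert np.sum(K_eff != K) == 1

    def test_control_condition_changes_nothing(self):
        net = make_net([("B", "A", "phosphorylation", "activation")])
        sys_ = compile_network(net)
        K = np.arange(1.0, sys_.n_parameters + 1)
        np.testing.assert_array_equal(Condition("control").apply(K, sys_), K)


class TestInitialParameters:
    def test_seeded_draw_is_reproducible_and_within_bounds(self):
        a = initial_parameters(50, "random", seed=9)
        b = initial_parameters(50, "random", seed=9)
        np.testing.assert_array_equal(a, b)
        assert np.all((a >= 1e-3) & (a <= 1e3))

    def test_ones_policy(self):
        np.testing.assert_array_equal(initial_parameters(4, "ones"), np.ones(4))


@pytest.fixture(scope="module")
def setup(small_fixture, small_agg):
    sys_ = small_fixture["system"]
    ode = small_fixture["ode"]
    ev = ObjectiveEvaluator(ode, sys_, small_agg, small_fixture["dataset"],
                            [Condition("control")])
    groups = group_parameters(ode, sys_)
    return small_fixture, ev, groups


class TestFitSmallSystem:
    """End-to-end fit behavior on the 4-gene noise-free fixture (fast)."""

    def test_single_cycle_when_tolerance_is_infinite(self, setup):
        fx, ev, groups = setup
        sched = rank_groups(groups, cycle_tolerance=float("inf"),
                            max_cycles=50, budget_per_param=5)
        res = fit(ev, sched, K0=fx["K_true"].copy())
        assert res.n_cycles == 1

    def test_seeded_fit_is_deterministic(self, setup):
        fx, ev, groups = setup
        sched = rank_groups(groups, max_cycles=1, budget_per_param=5,
                            cycle_tolerance=float("inf"))
        r1 = fit(ev, sched, init_policy="random", seed=11)
        r2 = fit(ev, sched, init_policy="random", seed=11)
        np.testing.assert_array_equal(r1.K_hat, r2.K_hat)
        assert r1.final_Stotal == r2.final_Stotal

    def test_trace_stotal_non_increasing(self, setup):
        fx, ev, groups = setup
        sched = rank_groups(groups, max_cycles=2, budget_per_param=8,
                            cycle_tolerance=0.0)
        rng = np.random.default_rng(5)
        K0 = fx["K_true"] * 10 ** rng.uniform(-0.5, 0.5, len(fx["K_true"]))
        res = fit(ev, sched, K0=K0)
        s = res.trace["Stotal"].to_numpy()
        assert np.all(np.diff(s) <= 1e-12)
        assert res.final_Stotal <= res.initial_Stotal

    def test_nonfinite_initial_objective_is_an_error(self, setup):
        fx, ev, groups = setup
        sched = rank_groups(groups, max_cycles=1, budget_per_param=1)
        K_bad = np.full(ev.ode.n_parameters, np.inf)  # unintegrable kinetics
        with pytest.raises(ValueError, match="initial"):
            fit(ev, sched, K0=K_bad)
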