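import itertools

import numpy as np
import pytest

from mapalign.feature_io import Feature, Run
from mapalign.map_core import CostParams, Solution, check_feasibility, matching_cost, solution_cost
from mapalign.relation_graph import ToleranceConfig
from mapalign.solvers import (
    VlsnsConfig,
    align_bipartite_baseline,
    init_solutions,
    solve_exact,
    solve_greedy,
    solve_lap,
    solve_vlsns,
)
from conftest import brute_force_best_cost, make_component, random_component

PARAMS = CostParams(w_c=1.0, w_p=1.0, bonus=0.5)


def exhaustive_lap(matrix):
    """Oracle: (cardinality, min cost) by enumerating all injective row->col maps."""
    m = np.asarray(matrix, dtype=float)
    n_rows, n_cols = m.shape
    for k in range(min(n_rows, n_cols), 0, -1):
        best = np.inf
        for rows in itertools.combinations(range(n_rows), k):
            for cols in itertools.permutations(range(n_cols), k):
                cost = sum(m[r, c] for r, c in zip(rows, cols))
                if np.isfinite(cost) and cost < best:
                    best = cost
        if np.isfinite(best):
            return k, best
    return 0, 0.0


class TestSolveLap:
    def test_identity_cheap_diagonal(self):
        m = np.ones((3, 3)) - np.eye(3)
        res = solve_lap(m)
        assert res.assignment == {0: 0, 1: 1, 2: 2}
        assert res.total_cost == 0.0

    def test_rectangular(self):
        res = solve_lap(np.array([[1.0, 9, 9], [9, 1, 9]]))
        assert res.assignment == {0: 0, 1: 1}
        assert res.total_cost == 2.0

    def test_all_infinite_row_unassigned(self):
        m = np.array([[np.inf, np.inf], [1.0, np.inf]])
        res = solve_lap(m)
        assert res.assignment == {1: 0}

    def test_all_infinite_matrix_empty_assignment(self):
        res = solve_lap(np.full((2, 2), np.inf))
        assert res.assignment == {}

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(40):
            shape = (int(rng.integers(1, 5)), int(rng.integers(1, 5)))
            m = rng.random(shape)
            m[rng.random(shape) < 0.3] = np.inf
            res = solve_lap(m)
            card, cost = exhaustive_lap(m)
            assert card == len(res.assignment)
            assert res.total_cost == pytest.approx(cost)


class TestSolveExact:
    def test_two_linked_features_beat_singletons(self):
        comp = make_component((1, 1), {((0, 0), (1, 0)): 0.1})
        # feasible options: pair+empty (0.1 + w_c - b + w_p*2) vs two singletons
        sol = solve_exact(comp, PARAMS)
        assert (0, 0) in sol.matchings
        assert sol.total_cost == pytest.approx(0.1 + 1.0 - 0.5 + 2.0)

    def test_single_node_component(self):
        comp = make_component((1,), {})
        sol = solve_exact(comp, PARAMS)
        assert sorted(sol.matchings) == [(0,), (1,)]

    def test_matches_bruteforce_on_random_components(self, rng):
        for _ in range(30):
            comp = random_component(rng, max_partites=3, max_nodes=3)
            sol = solve_exact(comp, PARAMS)
            ok, v = check_feasibility(comp, sol)
            assert ok, v
            assert sol.total_cost == pytest.approx(brute_force_best_cost(comp, PARAMS))

    def test_matches_scipy_ilp_set_partitioning(self, rng):
        """Independent cross-check: the same set-partitioning model handed to
        an ILP backend (HiGHS) yields the same optimal cost."""
        from scipy.optimize import LinearConstraint, milp
        from mapalign.map_core import enumerate_linkages, real_picks

        for _ in range(15):
            comp = random_component(rng, max_partites=3, max_nodes=3)
            m, p = comp.n_partites, comp.p
            pad = PARAMS.w_p * m
            linkages, costs, cols = [], [], []
            node_list = comp.all_local_nodes()
            pos = {nd: i for i, nd in enumerate(node_list)}
            for lk in enumerate_linkages(comp):
                picks = real_picks(comp, lk)
                if not picks:
                    continue
                linkages.append(lk)
                costs.append(matching_cost(comp, lk, PARAMS).total - pad)
                col = np.zeros(len(node_list))
                for nd in picks:
                    col[pos[nd]] = 1
                cols.append(col)
            a_cover = np.array(cols).T
            constraints = [
                LinearConstraint(a_cover, 1, 1),
                LinearConstraint(np.ones(len(linkages)), 0, p),
            ]
            res = milp(
                c=np.array(costs),
                integrality=np.ones(len(linkages)),
                bounds=(0, 1),
                constraints=constraints,
            )
            assert res.success
            ilp_cost = res.fun + p * pad
            assert solve_exact(comp, PARAMS).total_cost == pytest.approx(ilp_cost)

    def test_deterministic_tie_break(self):
        # two symmetric optima; the lexicographically smallest multiset wins
        comp = make_component((1, 1), {((0, 0), (1, 0)): 0.0})
        s1 = solve_exact(comp, PARAMS)
        s2 = solve_exact(comp, PARAMS)
        assert s1.canonical_key() == s2.canonical_key()


class TestSolveGreedy:
    def test_disjoint_cheapest_matchings_equal_exact(self):
        comp = make_component(
            (2, 2),
            {((0, 0), (1, 0)): 0.05, ((0, 1), (1, 1)): 0.06},
        )
        gr = solve_greedy(comp, PARAMS)
        ex = solve_exact(comp, PARAMS)
        assert gr.total_cost == pytest.approx(ex.total_cost)

    def test_adversarial_instance_strictly_suboptimal(self):
        # cheapest pair (a0,b0) forces the unconnected remainder (a1,b1);
        # the optimum uses the two cross pairs instead
        comp = make_component(
            (2, 2),
            {((0, 0), (1, 0)): 0.05, ((0, 0), (1, 1)): 0.3, ((0, 1), (1, 0)): 0.3},
        )
        gr = solve_greedy(comp, PARAMS)
        ex = solve_exact(comp, PARAMS)
        # hand enumeration: greedy = (0.05+0.5) + 2*w_c + w_p*2 = 4.55
        assert gr.total_cost == pytest.approx(4.55)
        # exact = 2 * (0.3 + w_c - b) + w_p*2 = 3.6
        assert ex.total_cost == pytest.approx(3.6)
        assert gr.total_cost > ex.total_cost

    def test_empty_component_all_placeholders(self):
        comp = make_component((), {})
        sol = solve_greedy(comp, PARAMS)
        assert sol.matchings == [()]
        assert sol.total_cost == 0.0

    def test_outputs_feasible(self, rng):
        for _ in range(25):
            comp = random_component(rng)
            sol = solve_greedy(comp, PARAMS)
            ok, v = check_feasibility(comp, sol)
            assert ok, v


class TestInitSolutions:
    def test_deterministic_given_seed(self):
        comp = make_component((2, 2), {((0, 0), (1, 0)): 0.1})
        cfg = VlsnsConfig(n_starts=1, seed=5)
        a = init_solutions(comp, "msr", cfg)
        b = init_solutions(comp, "msr", cfg)
        assert a == b

    def test_msg_grid_factor_one_equals_msr_base(self):
        comp = make_component((2, 2), {((0, 0), (1, 0)): 0.1})
        cfg = VlsnsConfig(n_starts=3, grid_factor=1, seed=9)
        msr = init_solutions(comp, "msr", cfg)
        msg = init_solutions(comp, "msg", cfg)
        assert msr == msg

    def test_msg_full_grid_produces_distinct_rolls(self):
        comp = make_component((2, 2), {((0, 0), (1, 0)): 0.1})
        p = comp.p
        cfg = VlsnsConfig(n_starts=1, grid_factor=p, seed=0)
        starts = init_solutions(comp, "msg", cfg)
        assert len(starts) == p
        assert len({tuple(map(tuple, s)) for s in starts}) == p

    def test_all_starts_feasible(self, rng):
        from mapalign.solvers import _perms_to_matchings

        for _ in range(10):
            comp = random_component(rng, max_partites=3, max_nodes=3)
            for method in ("msr", "msg"):
                for perms in init_solutions(comp, method, VlsnsConfig(n_starts=2, seed=1)):
                    sol = Solution(_perms_to_matchings(perms), 0.0)
                    ok, v = check_feasibility(comp, sol)
                    assert ok, v


class TestSolveVlsns:
    def test_never_below_exact_and_usually_equal(self, rng):
        hits = 0
        n = 40
        for i in range(n):
            comp = random_component(rng, max_partites=3, max_nodes=2)
            ex = solve_exact(comp, PARAMS)
            vl = solve_vlsns(comp, PARAMS, VlsnsConfig(seed=i))
            ok, v = check_feasibility(comp, vl)
            assert ok, v
            assert vl.total_cost >= ex.total_cost - 1e-9
            if vl.total_cost == pytest.approx(ex.total_cost):
                hits += 1
        assert hits >= 0.95 * n

    def test_max_iterations_zero_returns_best_start(self):
        comp = make_component((2, 2), {((0, 0), (1, 0)): 0.1, ((0, 1), (1, 1)): 0.1})
        cfg = VlsnsConfig(n_starts=4, max_iterations=0, seed=3)
        sol = solve_vlsns(comp, PARAMS, cfg)
        from mapalign.solvers import _perms_to_matchings

        starts = init_solutions(comp, cfg.init_method, cfg)
        start_costs = [
            solution_cost(comp, Solution(sorted(_perms_to_matchings(s)), 0.0), PARAMS)
            for s in starts
        ]
        assert sol.total_cost == pytest.approx(min(start_costs))

    def test_global_optimum_is_fixed_point(self, rng):
        for i in range(10):
            comp = random_component(rng, max_partites=3, max_nodes=2)
            ex = solve_exact(comp, PARAMS)
            vl = solve_vlsns(comp, PARAMS, VlsnsConfig(n_starts=8, seed=i))
            if vl.total_cost == pytest.approx(ex.total_cost):
                # running again from the optimum must not change the cost
                vl2 = solve_vlsns(comp, PARAMS, VlsnsConfig(n_starts=8, seed=i))
                assert vl2.total_cost == pytest.approx(vl.total_cost)


class TestBipartiteBaseline:
    def run_of(self, coords, name, acq):
        return Run(
            name=name, acquisition_index=acq,
            features=[Feature(m, r, a, f"{name}{i}") for i, (m, r, a) in enumerate(coords)],
        )

    def test_identical_runs_pair_perfectly(self):
        coords = [(100.0, 1.0, 5.0), (200.0, 2.0, 5.0)]
        runs = [self.run_of(coords, "a", 0), self.run_of(coords, "b", 1)]
        clusters = align_bipartite_baseline(runs, ToleranceConfig(0.01, 0.1))
        full = [c for c in clusters if len(c) == 2]
        assert len(full) == 2

    def test_disjoint_runs_all_singletons(self):
        runs = [
            self.run_of([(100.0, 1.0, 5.0)], "a", 0),
            self.run_of([(500.0, 5.0, 5.0)], "b", 1),
        ]
        clusters = align_bipartite_baseline(runs, ToleranceConfig(0.01, 0.1))
        assert sorted(len(c) for c in clusters) == [1, 1]

    def test_never_beats_exact_on_chained_instance(self):
        # three runs where pairwise-to-reference matching is order-dependent
        runs = [
            self.run_of([(100.0, 1.0, 10.0), (100.004, 1.04, 10.0)], "a", 0),
            self.run_of([(100.002, 1.02, 10.0)], "b", 1),
            self.run_of([(100.004, 1.04, 10.0)], "c", 2),
        ]
        tol = ToleranceConfig(0.01, 0.1)
        from mapalign.relation_graph import build_components

        comps = build_components(runs, tol)
        assert len(comps) == 1
        ex = solve_exact(comps[0], PARAMS)
        clusters = align_bipartite_baseline(runs, tol)
        # price the baseline clustering through the same cost model
        comp = comps[0]
        loc = {}
        for k, part in enumerate(comp.nodes):
            for i, nd in enumerate(part):
                loc[(nd.run, nd.idx)] = (k, i)
        matchings = []
        for cl in clusters:
            picks = {loc[(r, f)][0]: loc[(r, f)][1] for r, f in cl.items()}
            matchings.append(
                tuple(picks.get(k, comp.sizes[k]) for k in range(comp.n_partites))
            )
        from mapalign.map_core import pad_solution

        sol = Solution(pad_solution(comp, matchings), 0.0)
        baseline_cost = solution_cost(comp, sol, PARAMS)
        assert baseline_cost >= ex.total_cost - 1e-9
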