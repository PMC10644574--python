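"""Shared fixtures: hand-built components, random instances, brute-force oracles."""
from __future__ import annotations

import numpy as np
import pytest

from mapalign.map_core import CostParams, matching_cost
from mapalign.relation_graph import Component, NodeRef


def make_component(sizes, edges, areas=None, mzs=None, rts=None, run_indices=None) -> Component:
    """Build a Component directly from partite sizes and weighted local edges.

    ``edges`` maps ((k1, i1), (k2, i2)) -> weight. Coordinates default to a
    synthetic grid (they matter only for I/O, not for the cost model).
    """
    sizes = tuple(sizes)
    run_indices = tuple(run_indices) if run_indices else tuple(range(len(sizes)))
    nodes = tuple(
        tuple(NodeRef(run_indices[k], i) for i in range(n)) for k, n in enumerate(sizes)
    )
    if mzs is None:
        mzs = tuple(tuple(100.0 + 0.001 * i for i in range(n)) for n in sizes)
    if rts is None:
        rts = tuple(tuple(5.0 + 0.01 * i for i in range(n)) for n in sizes)
    if areas is None:
        areas = tuple(tuple(1.0 for _ in range(n)) for n in sizes)
    canon = {}
    for (a, b), w in edges.items():
        key = (a, b) if a < b else (b, a)
        assert key[0][0] != key[1][0], "no intra-partite edges"
        canon[key] = float(w)
    comp = Component(
        run_indices=run_indices,
        nodes=nodes,
        mz=tuple(tuple(map(float, p)) for p in mzs),
        rt=tuple(tuple(map(float, p)) for p in rts),
        area=tuple(tuple(map(float, p)) for p in areas),
        edges=canon,
        normed_area={(k, i): 1.0 for k, n in enumerate(sizes) for i in range(n)},
    )
    return comp


def random_component(rng: np.random.Generator, max_partites=4, max_nodes=4, edge_prob=0.6) -> Component:
    """A random multipartite instance with uniform edge weights in (0, 1)."""
    n_partites = int(rng.integers(2, max_partites + 1))
    sizes = [int(rng.integers(1, max_nodes + 1)) for _ in range(n_partites)]
    edges = {}
    for ka in range(n_partites):
        for kb in range(ka + 1, n_partites):
            for ia in range(sizes[ka]):
                for ib in range(sizes[kb]):
                    if rng.random() < edge_prob:
                        edges[((ka, ia), (kb, ib))] = float(rng.random())
    return make_component(sizes, edges)


def brute_force_best_cost(component: Component, params: CostParams) -> float:
    """Exhaustive minimum over all feasible solutions.

    Enumerates every partition of the real nodes into at most ``p`` groups
    with at most one node per partite per group (canonical restricted-growth
    order, so each partition is visited exactly once), prices groups through
    the matching cost model, and pads with all-placeholder matchings. This
    is a deliberately different search from the solver's branch-and-bound.
    """
    sizes = component.sizes
    m = component.n_partites
    p = component.p
    pad = params.w_p * m
    nodes = component.all_local_nodes()
    if not nodes:
        return pad * p if p else 0.0

    cost_memo: dict[tuple, float] = {}

    def group_cost(group: tuple) -> float:
        c = cost_memo.get(group)
        if c is None:
            picks = dict(group)
            linkage = tuple(picks.get(k, sizes[k]) for k in range(m))
            c = matching_cost(component, linkage, params).total
            cost_memo[group] = c
        return c

    best = np.inf
    groups: list[list] = []
    group_runs: list[set] = []

    def rec(j: int, partial: float):
        nonlocal best
        if j == len(nodes):
            total = partial + (p - len(groups)) * pad
            if total < best:
                best = total
            return
        node = nodes[j]
        run = node[0]
        for gi in range(len(groups)):
            if run in group_runs[gi]:
                continue
            old = tuple(sorted(groups[gi]))
            groups[gi].append(node)
            group_runs[gi].add(run)
            new = tuple(sorted(groups[gi]))
            delta = group_cost(new) - group_cost(old)
            rec(j + 1, partial + delta)
            groups[gi].pop()
            group_runs[gi].discard(run)
        if len(groups) < p:
            groups.append([node])
            group_runs.append({run})
            rec(j + 1, partial + group_cost((node,)))
            groups.pop()
            group_runs.pop()

    rec(0, 0.0)
    return float(best)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def random_instances():
    """The shared pool of random MAP instances used across solver tests."""
    rng = np.random.default_rng(12345)
    return [random_component(rng) for _ in range(200)]


@pytest.fixture(scope="session")
def exact_solutions(random_instances):
    from mapalign.solvers import solve_exact

    params = CostParams()
    return [solve_exact(c, params) for c in random_instances]
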