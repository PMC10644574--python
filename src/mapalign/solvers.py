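"""Solvers for the unbalanced multidimensional assignment problem.

Three solvers share the cost model of :mod:`mapalign.map_core`:

* :func:`solve_exact` — globally optimal, branch-and-bound over node-set
  partitions (the MAP as a set-partitioning problem). Any two optima are
  disambiguated by the lexicographically smallest matching multiset.
* :func:`solve_greedy` — repeatedly commits the cheapest remaining matching,
  invalidating linkages that reuse its nodes.
* :func:`solve_vlsns` — very large-scale neighborhood search: from multiple
  start solutions, repeatedly re-optimize a single partite's assignment of
  nodes to matchings by solving a linear assignment problem (LAP), applying
  the best-improving partite until a local optimum.

Also here: the LAP wrapper used everywhere, and the local bipartite baseline
(iterative run-to-reference matching) used for comparison.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import SizeLimitError
from .feature_io import Run
from .map_core import (
    CostCache,
    CostParams,
    Linkage,
    Solution,
    count_linkages,
    empty_linkage,
    enumerate_linkages,
    matching_cost,
    pad_solution,
    real_picks,
    solution_cost,
)
from .relation_graph import Component, ToleranceConfig
from .rt_alignment import select_reference

log = logging.getLogger(__name__)

_EPS = 1e-9


@dataclass
class LapResult:
    """A maximum-cardinality, minimum-cost rectangular assignment."""

    assignment: dict[int, int]
    total_cost: float


@dataclass(frozen=True)
class VlsnsConfig:
    """Multi-start neighborhood-search settings.

    ``init_method`` is ``"msr"`` (independent random permutations) or
    ``"msg"`` (random bases, each expanded into ``grid_factor`` cyclically
    rolled variants).
    """

    n_starts: int = 8
    init_method: str = "msg"
    grid_factor: int = 4
    max_iterations: int = 100
    seed: int = 42

    def __post_init__(self):
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.max_iterations < 0:
            raise ValueError("max_iterations must be >= 0")
        if self.init_method not in ("msr", "msg"):
            raise ValueError("init_method must be 'msr' or 'msg'")
        if self.grid_factor < 1:
            raise ValueError("grid_factor must be >= 1")


def solve_lap(cost_matrix: np.ndarray) -> LapResult:
    """Maximum-cardinality, minimum-cost assignment on a rectangular matrix.

    Infinite cells are forbidden: rows/columns that can only be covered by
    infinite cells stay unassigned. Backed by scipy's modified
    Jonker–Volgenant algorithm via a big-M reduction.
    """
    c = np.asarray(cost_matrix, dtype=float)
    if c.ndim != 2 or c.size == 0:
        raise ValueError("cost matrix must be non-empty and 2-D")
    finite = np.isfinite(c)
    if not finite.any():
        return LapResult(assignment={}, total_cost=0.0)
    span = float(np.abs(c[finite]).sum()) + 1.0
    big = span * (min(c.shape) + 1)
    filled = np.where(finite, c, big)
    rows, cols = linear_sum_assignment(filled)
    assignment: dict[int, int] = {}
    total = 0.0
    for r, col in zip(rows, cols):
        if finite[r, col]:
            assignment[int(r)] = int(col)
            total += float(c[r, col])
    return LapResult(assignment=assignment, total_cost=total)


# ---------------------------------------------------------------------------
# exact solver: branch and bound over node-set partitions
# ---------------------------------------------------------------------------

def _linkage_of_group(component: Component, group: Sequence[tuple[int, int]]) -> Linkage:
    sizes = component.sizes
    picks = dict(group)
    return tuple(picks.get(k, sizes[k]) for k in range(component.n_partites))


def solve_exact(
    component: Component, params: CostParams, max_linkages: Optional[int] = 200_000
) -> Solution:
    """Globally optimal solution by branch-and-bound set partitioning.

    Every linkage is a candidate group (its real picks); a feasible solution
    is a partition of the real nodes into at most ``p`` groups. The search
    enumerates partitions in lexicographic group order with an admissible
    per-node lower bound for pruning, so the returned optimum carries the
    lexicographically smallest matching multiset among ties.

    Raises :class:`SizeLimitError` when the linkage count exceeds
    ``max_linkages``.
    """
    sizes = component.sizes
    m = component.n_partites
    p = component.p
    if component.n_nodes == 0:
        matchings = pad_solution(component, [])
        return Solution(matchings=matchings, total_cost=solution_cost(component, Solution(matchings, 0.0), params))

    pad_cost = params.w_p * m  # cost of one all-placeholder matching
    nodes = component.all_local_nodes()
    node_pos = {nd: j for j, nd in enumerate(nodes)}

    # enumerate groups (= non-empty linkages); adjusted cost g' = g - pad_cost
    groups_containing: dict[tuple[int, int], list[tuple[float, Linkage, frozenset]]] = {
        nd: [] for nd in nodes
    }
    min_unit = {nd: np.inf for nd in nodes}
    for linkage in enumerate_linkages(component, max_linkages=max_linkages):
        picks = real_picks(component, linkage)
        if not picks:
            continue
        g_adj = matching_cost(component, linkage, params).total - pad_cost
        fs = frozenset(picks)
        for nd in picks:
            groups_containing[nd].append((g_adj, linkage, fs))
            unit = g_adj / len(picks)
            if unit < min_unit[nd]:
                min_unit[nd] = unit
    for nd in nodes:
        groups_containing[nd].sort(key=lambda t: (t[0], t[1]))

    best_cost = np.inf
    best_key: Optional[tuple[Linkage, ...]] = None
    covered = [False] * len(nodes)

    def dfs(cost_so_far: float, n_groups: int, chosen: list[Linkage], first_unc: int):
        nonlocal best_cost, best_key
        while first_unc < len(nodes) and covered[first_unc]:
            first_unc += 1
        if first_unc == len(nodes):
            key = tuple(sorted(chosen + [empty_linkage(component)] * (p - n_groups)))
            if cost_so_far < best_cost - _EPS or (
                cost_so_far <= best_cost + _EPS and (best_key is None or key < best_key)
            ):
                best_cost = min(best_cost, cost_so_far)
                best_key = key
            return
        if n_groups >= p:
            return
        target = nodes[first_unc]
        for g_adj, linkage, fs in groups_containing[target]:
            if any(covered[node_pos[nd]] for nd in fs if nd != target):
                continue
            for nd in fs:
                covered[node_pos[nd]] = True
            j = first_unc
            while j < len(nodes) and covered[j]:
                j += 1
            bound = cost_so_far + g_adj
            # admissible bound: bare cost plus each still-uncovered node's
            # cheapest per-node share of any group containing it
            remaining_after = sum(
                min_unit[nodes[jj]] for jj in range(j, len(nodes)) if not covered[jj]
            )
            if bound + remaining_after <= best_cost + _EPS:
                chosen.append(linkage)
                dfs(bound, n_groups + 1, chosen, j)
                chosen.pop()
            for nd in fs:
                covered[node_pos[nd]] = False

    dfs(0.0, 0, [], 0)
    assert best_key is not None
    matchings = list(best_key)
    total = p * pad_cost + best_cost
    sol = Solution(matchings=matchings, total_cost=total)
    sol.total_cost = solution_cost(component, sol, params)  # recompute defensively
    return sol


def solve_greedy(
    component: Component, params: CostParams, max_linkages: Optional[int] = 200_000
) -> Solution:
    """Commit the cheapest remaining matching until all real nodes are used.

    Ties break on the lexicographically smallest linkage. A candidate is
    skipped when committing it would leave fewer free matchings than the
    largest remaining partite requires (which would make the final solution
    infeasible).
    """
    sizes = component.sizes
    p = component.p
    if component.n_nodes == 0:
        matchings = pad_solution(component, [])
        return Solution(matchings, solution_cost(component, Solution(matchings, 0.0), params))

    cache = CostCache(component, params)
    candidates = []
    for linkage in enumerate_linkages(component, max_linkages=max_linkages):
        picks = real_picks(component, linkage)
        if picks:
            candidates.append((cache.total(linkage), linkage, picks))
    candidates.sort(key=lambda t: (t[0], t[1]))

    used: set[tuple[int, int]] = set()
    remaining = list(sizes)
    committed: list[Linkage] = []
    total_nodes = component.n_nodes
    while len(used) < total_nodes:
        for cost, linkage, picks in candidates:
            if any(nd in used for nd in picks):
                continue
            rem_after = [
                remaining[k] - (1 if linkage[k] < sizes[k] else 0)
                for k in range(len(sizes))
            ]
            if p - (len(committed) + 1) < max(rem_after):
                continue
            committed.append(linkage)
            used.update(picks)
            remaining = rem_after
            break
        else:  # pragma: no cover - cannot happen: singletons always remain valid
            raise RuntimeError("greedy search exhausted candidates")
    matchings = pad_solution(component, committed)
    return Solution(matchings, solution_cost(component, Solution(matchings, 0.0), params))


# ---------------------------------------------------------------------------
# VLSNS solver
# ---------------------------------------------------------------------------

Perms = list[list[int]]  # per partite: length-p list of node indices (n_k = placeholder)


def _perms_to_matchings(perms: Perms) -> list[Linkage]:
    p = len(perms[0])
    return [tuple(perms[k][j] for k in range(len(perms))) for j in range(p)]


def _random_perms(component: Component, rng: np.random.Generator) -> Perms:
    p = component.p
    perms: Perms = []
    for n in component.sizes:
        padded = list(range(n)) + [n] * (p - n)
        rng.shuffle(padded)
        perms.append(padded)
    return perms


def init_solutions(
    component: Component, method: str, cfg: VlsnsConfig
) -> list[Perms]:
    """Multi-start initial solutions as per-partite permutations.

    MSR: ``n_starts`` independent uniformly random permutations per partite.
    MSG: ``n_starts`` random bases, each expanded into ``grid_factor``
    variants with every partite's permutation cyclically rolled by
    ``floor(j * p / grid_factor)`` positions. All outputs are feasible by
    construction and deterministic given the seed.
    """
    rng = np.random.default_rng(cfg.seed)
    p = component.p
    starts: list[Perms] = []
    for _ in range(cfg.n_starts):
        base = _random_perms(component, rng)
        if method == "msr":
            starts.append(base)
        else:
            for j in range(cfg.grid_factor):
                shift = (j * p) // cfg.grid_factor
                rolled = [perm[shift:] + perm[:shift] for perm in base]
                starts.append(rolled)
    return starts


def _local_search(
    component: Component, cache: CostCache, perms: Perms, max_iterations: int
) -> tuple[Perms, float]:
    """Best-improvement partite re-assignment until a local optimum."""
    m = component.n_partites
    p = component.p
    rows = _perms_to_matchings(perms)
    row_cost = [cache.total(r) for r in rows]
    total = sum(row_cost)
    for _ in range(max_iterations):
        best_gain = _EPS
        best_k = -1
        best_perm: Optional[list[int]] = None
        best_total = total
        for k in range(m):
            # cell (i, j): cost of matching j if it receives entry i of partite k
            mat = np.empty((p, p))
            for i in range(p):
                entry = perms[k][i]
                for j in range(p):
                    if entry == rows[j][k]:
                        mat[i, j] = row_cost[j]
                    else:
                        cand = rows[j][:k] + (entry,) + rows[j][k + 1:]
                        mat[i, j] = cache.total(cand)
            lap = solve_lap(mat)
            gain = total - lap.total_cost
            if gain > best_gain:
                best_gain = gain
                best_k = k
                new_perm = [0] * p
                for i, j in lap.assignment.items():
                    new_perm[j] = perms[k][i]
                best_perm = new_perm
                best_total = lap.total_cost
        if best_k < 0:
            break
        perms = [list(perm) for perm in perms]
        perms[best_k] = best_perm  # type: ignore[assignment]
        rows = _perms_to_matchings(perms)
        row_cost = [cache.total(r) for r in rows]
        total = best_total
    return perms, total


def solve_vlsns(
    component: Component, params: CostParams, cfg: Optional[VlsnsConfig] = None
) -> Solution:
    """Multi-start very large-scale neighborhood search.

    Costs are computed on demand (no full linkage enumeration), so this
    solver scales to components the exact and greedy solvers cannot touch.
    Returns the lowest-cost local optimum across starts; ties pick the
    lexicographically smallest matching multiset.
    """
    if cfg is None:
        cfg = VlsnsConfig()
    if component.n_nodes == 0:
        matchings = pad_solution(component, [])
        return Solution(matchings, solution_cost(component, Solution(matchings, 0.0), params))
    cache = CostCache(component, params)
    best: Optional[Solution] = None
    for perms in init_solutions(component, cfg.init_method, cfg):
        perms, total = _local_search(component, cache, perms, cfg.max_iterations)
        sol = Solution(sorted(_perms_to_matchings(perms)), total)
        if (
            best is None
            or sol.total_cost < best.total_cost - _EPS
            or (sol.total_cost <= best.total_cost + _EPS and sol.canonical_key() < best.canonical_key())
        ):
            best = sol
    assert best is not None
    best.total_cost = solution_cost(component, best, params)
    return best


def solve_auto(
    component: Component,
    params: CostParams,
    vlsns_cfg: Optional[VlsnsConfig] = None,
    exact_limit: int = 20_000,
) -> tuple[Solution, str]:
    """Dispatch: exact when the linkage count is enumerable, else VLSNS."""
    if count_linkages(component) <= exact_limit:
        return solve_exact(component, params, max_linkages=exact_limit), "exact"
    return solve_vlsns(component, params, vlsns_cfg), "vlsns"


# ---------------------------------------------------------------------------
# local bipartite baseline
# ---------------------------------------------------------------------------

def _pair_weight(mz_a, rt_a, area_a, mz_b, rt_b, area_b, tol: ToleranceConfig) -> float:
    mz_t = tol.mz_tol_at(mz_a, mz_b)
    if abs(mz_a - mz_b) > mz_t or abs(rt_a - rt_b) > tol.rt_tol:
        return np.inf
    hi, lo = max(area_a, area_b), min(area_a, area_b)
    darea = 0.0 if hi <= 0 else 1.0 - lo / hi
    return (abs(mz_a - mz_b) / mz_t + abs(rt_a - rt_b) / tol.rt_tol + darea) / 3.0


def align_bipartite_baseline(
    runs: Sequence[Run], tol: ToleranceConfig
) -> list[dict[int, int]]:
    """Iterative run-to-reference bipartite matching (the comparison baseline).

    The run with the most features is the reference; remaining runs are
    matched in descending feature count to the growing consensus by a LAP
    over pairwise weights (non-neighbors infinite). Unmatched features start
    new consensus groups. Returns groups as {run index: feature index} maps.
    """
    if len(runs) < 2:
        raise ValueError("need at least two runs")
    ref = select_reference(runs)
    clusters: list[dict[int, int]] = [{ref: i} for i in range(len(runs[ref].features))]
    reps = [
        [f.mz, f.rt, f.area] for f in runs[ref].features
    ]  # running mean representative per cluster
    order = sorted(
        (i for i in range(len(runs)) if i != ref),
        key=lambda i: (-len(runs[i].features), runs[i].acquisition_index),
    )
    for r in order:
        feats = runs[r].features
        if not feats:
            continue
        mat = np.full((len(clusters), len(feats)), np.inf)
        for ci, rep in enumerate(reps):
            for fi, f in enumerate(feats):
                mat[ci, fi] = _pair_weight(rep[0], rep[1], rep[2], f.mz, f.rt, f.area, tol)
        lap = solve_lap(mat)
        matched_feats = set()
        for ci, fi in lap.assignment.items():
            clusters[ci][r] = fi
            matched_feats.add(fi)
            k = len(clusters[ci])
            f = feats[fi]
            reps[ci] = [
                reps[ci][0] + (f.mz - reps[ci][0]) / k,
                reps[ci][1] + (f.rt - reps[ci][1]) / k,
                reps[ci][2] + (f.area - reps[ci][2]) / k,
            ]
        for fi, f in enumerate(feats):
            if fi not in matched_feats:
                clusters.append({r: fi})
                reps.append([f.mz, f.rt, f.area])
    return clusters
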