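"""The unbalanced multidimensional assignment formalism and its cost model.

A *linkage* picks one node per partite of a component — either a real
feature or the partite's placeholder (index ``n_k``) meaning "no feature in
this run". A feasible *solution* consists of ``p = max(n_k) + 1`` matchings
(chosen linkages) such that every real node appears in exactly one matching;
the all-placeholder linkage may pad the solution with multiplicity.

The cost of a matching is

    C = C_distribution + w_c * N_c + w_p * N_p - B

where C_distribution is the weight of the minimum spanning forest over the
matching's real nodes (using only edges present in the component), N_c the
number of connected clusters among those nodes, N_p the placeholder count,
and B a bonus granted only to connected full matchings (N_p = 0, N_c = 1).
A solution's cost is the sum over its p matchings.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product
from typing import Iterator, Optional, Sequence

from .errors import InfeasibleSolutionError, SizeLimitError
from .relation_graph import Component

Linkage = tuple[int, ...]


@dataclass(frozen=True)
class CostParams:
    """Cost-model factors: cluster penalty, placeholder penalty, full-match bonus.

    The exact optimum is provably invariant to ``w_p`` (every feasible
    solution of a component contains the same total number of placeholders),
    so only ``w_c`` and ``bonus`` shape the matching behaviour.
    """

    w_c: float = 1.0
    w_p: float = 1.0
    bonus: float = 0.5

    def __post_init__(self):
        if self.w_c < 0 or self.w_p < 0 or self.bonus < 0:
            raise ValueError("cost factors must be >= 0")


@dataclass(frozen=True)
class CostBreakdown:
    distribution: float
    connectivity: float
    missing: float
    bonus: float
    total: float
    n_clusters: int
    n_placeholders: int


@dataclass
class Solution:
    """p matchings partitioning a component's real nodes, plus their total cost."""

    matchings: list[Linkage]
    total_cost: float

    def canonical_key(self) -> tuple[Linkage, ...]:
        return tuple(sorted(self.matchings))


def empty_linkage(component: Component) -> Linkage:
    return tuple(component.sizes)


def real_picks(component: Component, linkage: Linkage) -> list[tuple[int, int]]:
    """The (partite, local index) pairs of the linkage's non-placeholder picks."""
    sizes = component.sizes
    picks = []
    for k, i in enumerate(linkage):
        if not 0 <= i <= sizes[k]:
            raise ValueError(f"linkage index {i} out of range for partite {k} (n={sizes[k]})")
    for k, i in enumerate(linkage):
        if i < sizes[k]:
            picks.append((k, i))
    return picks


def _spanning_forest(component: Component, nodes: list[tuple[int, int]]) -> tuple[float, int]:
    """Kruskal minimum spanning forest over ``nodes``; returns (weight, #clusters)."""
    if not nodes:
        return 0.0, 0
    index = {n: j for j, n in enumerate(nodes)}
    cand = []
    for a in range(len(nodes)):
        for b in range(a + 1, len(nodes)):
            w = component.edge_weight(nodes[a], nodes[b])
            if w is not None:
                cand.append((w, a, b))
    cand.sort()
    parent = list(range(len(nodes)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    weight = 0.0
    used = 0
    for w, a, b in cand:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            weight += w
            used += 1
            if used == len(nodes) - 1:
                break
    return weight, len(nodes) - used


def matching_cost(component: Component, linkage: Linkage, params: CostParams) -> CostBreakdown:
    """Cost of a single matching (see module docstring)."""
    if len(linkage) != component.n_partites:
        raise ValueError("linkage length must equal the number of partites")
    picks = real_picks(component, linkage)
    m = component.n_partites
    n_p = m - len(picks)
    dist, n_c = _spanning_forest(component, picks)
    connectivity = params.w_c * n_c
    missing = params.w_p * n_p
    bonus = params.bonus if (n_p == 0 and n_c == 1) else 0.0
    total = dist + connectivity + missing - bonus
    return CostBreakdown(
        distribution=dist,
        connectivity=connectivity,
        missing=missing,
        bonus=bonus,
        total=total,
        n_clusters=n_c,
        n_placeholders=n_p,
    )


def check_feasibility(component: Component, solution: Solution) -> tuple[bool, list[str]]:
    """Check the four feasibility constraints; returns (verdict, violations).

    Constraints: (solution-size) exactly p matchings; (distinct-linkages)
    matchings containing real nodes are pairwise distinct; (shared-node) no
    real node appears in two matchings; (coverage) every real node appears.
    """
    violations: list[str] = []
    sizes = component.sizes
    p = component.p
    matchings = solution.matchings
    if len(matchings) != p:
        violations.append(f"solution-size: {len(matchings)} matchings, expected p={p}")
    nonempty = [m for m in matchings if any(i < sizes[k] for k, i in enumerate(m))]
    if len(set(nonempty)) != len(nonempty):
        dupes = sorted({m for m in nonempty if nonempty.count(m) > 1})
        violations.append(f"distinct-linkages: repeated matchings {dupes}")
    for k in range(component.n_partites):
        picked = [m[k] for m in matchings if k < len(m) and m[k] < sizes[k]]
        seen = set(picked)
        if len(picked) != len(seen):
            violations.append(f"shared-node: partite {k} node picked more than once")
        missing = set(range(sizes[k])) - seen
        if missing:
            violations.append(f"coverage: partite {k} nodes {sorted(missing)} unassigned")
    return (not violations), violations


def solution_cost(component: Component, solution: Solution, params: CostParams) -> float:
    """Total cost of a feasible solution (sum of its matching costs)."""
    if component.n_nodes == 0 and not solution.matchings:
        return 0.0
    ok, violations = check_feasibility(component, solution)
    if not ok:
        raise InfeasibleSolutionError(violations)
    return sum(matching_cost(component, m, params).total for m in solution.matchings)


def count_linkages(component: Component) -> int:
    return math.prod(n + 1 for n in component.sizes)


def enumerate_linkages(
    component: Component,
    max_linkages: Optional[int] = None,
    max_clusters: Optional[int] = None,
) -> Iterator[Linkage]:
    """Yield every linkage in lexicographic order.

    ``max_linkages`` guards against combinatorial blow-up (raises
    :class:`SizeLimitError`, pointing the caller at segmentation);
    ``max_clusters`` optionally filters linkages whose real picks split into
    more than that many connected clusters.
    """
    total = count_linkages(component)
    if max_linkages is not None and total > max_linkages:
        raise SizeLimitError(
            f"{total} linkages exceed the guard ({max_linkages}); "
            "segment the component or use the VLSNS solver"
        )
    for linkage in product(*(range(n + 1) for n in component.sizes)):
        if max_clusters is not None:
            picks = real_picks(component, linkage)
            if picks:
                _, n_c = _spanning_forest(component, picks)
                if n_c > max_clusters:
                    continue
        yield linkage


def pad_solution(component: Component, matchings: Sequence[Linkage]) -> list[Linkage]:
    """Pad with copies of the all-placeholder linkage up to p matchings."""
    padded = list(matchings)
    empty = empty_linkage(component)
    while len(padded) < component.p:
        padded.append(empty)
    return sorted(padded)


class CostCache:
    """Memoized matching costs for one (component, params) pair."""

    def __init__(self, component: Component, params: CostParams):
        self.component = component
        self.params = params
        self._cache: dict[Linkage, float] = {}

    def total(self, linkage: Linkage) -> float:
        c = self._cache.get(linkage)
        if c is None:
            c = matching_cost(self.component, linkage, self.params).total
            self._cache[linkage] = c
        return c

    def solution_total(self, matchings: Sequence[Linkage]) -> float:
        return sum(self.total(m) for m in matchings)
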