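"""The multipartite relation graph over warped runs.

After RT registration all runs are superimposed on the (m/z, RT) plane.
Every pair of features from *different* runs that falls within the user
tolerances becomes an edge (a potential correspondence). Connected
components of this graph are the independent matching problems; edges are
weighted by the normalized m/z, RT and intensity differences

    w(e) = (|dmz|/mz_tol + |dRT|/rt_tol + 1 - min(na)/max(na)) / 3

where ``na`` is the feature area normalized by the largest area of the same
run inside the same connected component.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import networkx as nx
import numpy as np

from .feature_io import Run

log = logging.getLogger(__name__)


class NodeRef(NamedTuple):
    """Reference to a feature: (global run index, feature index within run)."""

    run: int
    idx: int


@dataclass(frozen=True)
class ToleranceConfig:
    """Matching tolerances: m/z in Da (or ppm when ``mz_ppm`` set), RT in min."""

    mz_tol: float = 0.01
    rt_tol: float = 0.1
    mz_ppm: Optional[float] = None

    def __post_init__(self):
        if self.rt_tol <= 0:
            raise ValueError("rt_tol must be > 0")
        if self.mz_ppm is None and self.mz_tol <= 0:
            raise ValueError("mz_tol must be > 0")
        if self.mz_ppm is not None and self.mz_ppm <= 0:
            raise ValueError("mz_ppm must be > 0")

    def mz_tol_at(self, mz_a: float, mz_b: float) -> float:
        """Effective m/z tolerance in Da; ppm is applied at the smaller m/z."""
        if self.mz_ppm is not None:
            return self.mz_ppm * 1e-6 * min(mz_a, mz_b)
        return self.mz_tol


# local node key inside a Component: (partite index, local node index)
LocalNode = tuple[int, int]


@dataclass
class Component:
    """A connected multipartite subgraph: the smallest solvable matching unit.

    Partites are the runs present in the component, ordered by global run
    index; within a partite nodes keep their within-run order. ``edges`` maps
    canonically ordered local node pairs to weights (unweighted graphs use
    ``nan`` until :func:`weight_edges` runs).
    """

    run_indices: tuple[int, ...]
    nodes: tuple[tuple[NodeRef, ...], ...]
    mz: tuple[tuple[float, ...], ...]
    rt: tuple[tuple[float, ...], ...]
    area: tuple[tuple[float, ...], ...]
    edges: dict[tuple[LocalNode, LocalNode], float] = field(default_factory=dict)
    normed_area: dict[LocalNode, float] = field(default_factory=dict)

    @property
    def sizes(self) -> tuple[int, ...]:
        """Real-node count per partite (n_k)."""
        return tuple(len(p) for p in self.nodes)

    @property
    def n_partites(self) -> int:
        return len(self.nodes)

    @property
    def n_nodes(self) -> int:
        return sum(self.sizes)

    @property
    def p(self) -> int:
        """Number of matchings in any feasible solution: max(n_k) + 1."""
        return (max(self.sizes) if self.nodes else 0) + 1

    def all_local_nodes(self) -> list[LocalNode]:
        return [(k, i) for k, part in enumerate(self.nodes) for i in range(len(part))]

    def edge_weight(self, a: LocalNode, b: LocalNode) -> Optional[float]:
        key = (a, b) if a < b else (b, a)
        return self.edges.get(key)


def _within_tolerance(fa, fb, tol: ToleranceConfig) -> bool:
    return (
        abs(fa.mz - fb.mz) <= tol.mz_tol_at(fa.mz, fb.mz)
        and abs(fa.rt - fb.rt) <= tol.rt_tol
    )


def build_relation_graph(runs: Sequence[Run], tol: ToleranceConfig) -> nx.Graph:
    """Build the undirected relation graph over all features of all runs.

    Nodes are :class:`NodeRef`; an edge joins features of different runs whose
    m/z and RT differences are within tolerance (closed comparison). Uses an
    m/z-sorted sweep; see :func:`build_relation_graph_bruteforce` for the
    quadratic reference used as a test oracle.
    """
    if len(runs) < 2:
        raise ValueError("need at least two runs to build a relation graph")
    g = nx.Graph()
    flat: list[tuple[float, float, int, int]] = []  # (mz, rt, run, idx)
    for r, run in enumerate(runs):
        for i, f in enumerate(run.features):
            g.add_node(NodeRef(r, i))
            flat.append((f.mz, f.rt, r, i))
    flat.sort()
    mzs = np.array([t[0] for t in flat])
    # widest possible Da window for the sweep (ppm mode: at the largest m/z)
    if tol.mz_ppm is not None:
        max_win = tol.mz_ppm * 1e-6 * (mzs.max() if len(mzs) else 0.0)
    else:
        max_win = tol.mz_tol
    lo = 0
    for j in range(len(flat)):
        mz_j, rt_j, r_j, i_j = flat[j]
        while mzs[j] - mzs[lo] > max_win:
            lo += 1
        for k in range(lo, j):
            mz_k, rt_k, r_k, i_k = flat[k]
            if r_k == r_j:
                continue
            if abs(mz_j - mz_k) <= tol.mz_tol_at(mz_j, mz_k) and abs(rt_j - rt_k) <= tol.rt_tol:
                g.add_edge(NodeRef(r_k, i_k), NodeRef(r_j, i_j))
    return g


def build_relation_graph_bruteforce(runs: Sequence[Run], tol: ToleranceConfig) -> nx.Graph:
    """O(N^2) pairwise reference implementation (test oracle)."""
    g = nx.Graph()
    refs = [
        (NodeRef(r, i), f) for r, run in enumerate(runs) for i, f in enumerate(run.features)
    ]
    for ref, _ in refs:
        g.add_node(ref)
    for a in range(len(refs)):
        for b in range(a + 1, len(refs)):
            (na, fa), (nb, fb) = refs[a], refs[b]
            if na.run != nb.run and _within_tolerance(fa, fb, tol):
                g.add_edge(na, nb)
    return g


def split_components(graph: nx.Graph, runs: Sequence[Run]) -> list[Component]:
    """Split into connected components, ordered by (min m/z, min RT).

    Singleton nodes become one-node components. Edge weights are initialized
    to ``nan``; call :func:`compute_normed_areas` then :func:`weight_edges`.
    """
    comps: list[Component] = []
    for cc in nx.connected_components(graph):
        members = sorted(cc)  # NodeRef sort: by run then feature index
        run_ids = tuple(sorted({n.run for n in members}))
        part_of = {r: k for k, r in enumerate(run_ids)}
        per_part: list[list[NodeRef]] = [[] for _ in run_ids]
        for n in members:
            per_part[part_of[n.run]].append(n)
        local_of: dict[NodeRef, LocalNode] = {}
        for k, part in enumerate(per_part):
            for i, n in enumerate(part):
                local_of[n] = (k, i)
        edges: dict[tuple[LocalNode, LocalNode], float] = {}
        for u, v in graph.subgraph(cc).edges():
            a, b = local_of[u], local_of[v]
            key = (a, b) if a < b else (b, a)
            edges[key] = float("nan")
        comps.append(
            Component(
                run_indices=run_ids,
                nodes=tuple(tuple(p) for p in per_part),
                mz=tuple(tuple(runs[n.run].features[n.idx].mz for n in p) for p in per_part),
                rt=tuple(tuple(runs[n.run].features[n.idx].rt for n in p) for p in per_part),
                area=tuple(tuple(runs[n.run].features[n.idx].area for n in p) for p in per_part),
                edges=edges,
            )
        )
    comps.sort(key=lambda c: (min(min(p) for p in c.mz), min(min(p) for p in c.rt)))
    return comps


def compute_normed_areas(component: Component) -> dict[LocalNode, float]:
    """Normalize areas per component-partite: area / max area in the partite.

    Values lie in (0, 1]; a partite whose maximum area is zero degenerates to
    all ones (logged).
    """
    normed: dict[LocalNode, float] = {}
    for k, areas in enumerate(component.area):
        top = max(areas) if areas else 0.0
        if top <= 0:
            if areas:
                log.warning("partite %d has zero max area; normalized areas set to 1", k)
            for i in range(len(areas)):
                normed[(k, i)] = 1.0
        else:
            for i, a in enumerate(areas):
                normed[(k, i)] = a / top
    component.normed_area = normed
    return normed


def weight_edges(component: Component, tol: ToleranceConfig) -> Component:
    """Assign each edge its normalized-difference weight (requires normed areas)."""
    if not component.normed_area and component.n_nodes:
        compute_normed_areas(component)
    for (a, b) in list(component.edges):
        (ka, ia), (kb, ib) = a, b
        mza, mzb = component.mz[ka][ia], component.mz[kb][ib]
        dmz = abs(mza - mzb) / tol.mz_tol_at(mza, mzb)
        drt = abs(component.rt[ka][ia] - component.rt[kb][ib]) / tol.rt_tol
        na, nb = component.normed_area[a], component.normed_area[b]
        hi, lo_ = max(na, nb), min(na, nb)
        darea = 0.0 if hi <= 0 else 1.0 - lo_ / hi
        component.edges[(a, b)] = (dmz + drt + darea) / 3.0
    return component


def build_components(runs: Sequence[Run], tol: ToleranceConfig) -> list[Component]:
    """Convenience: graph -> components -> normalized areas -> weighted edges."""
    graph = build_relation_graph(runs, tol)
    comps = split_components(graph, runs)
    for c in comps:
        compute_normed_areas(c)
        weight_edges(c, tol)
    return comps
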