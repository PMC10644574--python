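"""Big-component acceleration: run-group segmentation and solution merging,
plus recursive folder-structured alignment.

Components whose node count exceeds a preset limit are split *by run*:
runs adjacent in acquisition order stay together and the cut balances the
node counts of the two halves; the halves are solved independently and
their matchings merged back agglomeratively, cheapest connecting edge
first, subject to run-disjointness.
"""
from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import IntegrityError
from .map_core import CostParams, Linkage, Solution, pad_solution, real_picks, solution_cost
from .relation_graph import Component

log = logging.getLogger(__name__)


def _restrict(component: Component, part_range: range) -> Component:
    """Sub-component over a contiguous slice of partites, keeping intra-slice
    edges and the full-component normalized areas (per-run maxima are
    unchanged by the slicing)."""
    ks = list(part_range)
    remap = {k: j for j, k in enumerate(ks)}
    edges = {}
    for (a, b), w in component.edges.items():
        if a[0] in remap and b[0] in remap:
            edges[((remap[a[0]], a[1]), (remap[b[0]], b[1]))] = w
    return Component(
        run_indices=tuple(component.run_indices[k] for k in ks),
        nodes=tuple(component.nodes[k] for k in ks),
        mz=tuple(component.mz[k] for k in ks),
        rt=tuple(component.rt[k] for k in ks),
        area=tuple(component.area[k] for k in ks),
        edges=edges,
        normed_area={(remap[k], i): v for (k, i), v in component.normed_area.items() if k in remap},
    )


@dataclass
class Segment:
    """A sub-component together with the partite slice it came from."""

    component: Component
    partites: range  # indices into the parent component's partites


def segment_component(component: Component, node_limit: int) -> list[Segment]:
    """Recursively bisect a component by run until below ``node_limit``.

    Each cut position (between acquisition-adjacent runs) is scored by the
    node-count imbalance of the halves; the most balanced cut wins (ties ->
    earliest cut). A single run exceeding the limit becomes its own leaf with
    a warning.
    """
    def rec(part_range: range) -> list[range]:
        counts = [len(component.nodes[k]) for k in part_range]
        if sum(counts) <= node_limit or len(part_range) == 1:
            if sum(counts) > node_limit:
                log.warning(
                    "single run with %d nodes exceeds node_limit=%d", sum(counts), node_limit
                )
            return [part_range]
        best_cut, best_diff = 1, np.inf
        for c in range(1, len(part_range)):
            diff = abs(sum(counts[:c]) - sum(counts[c:]))
            if diff < best_diff:
                best_cut, best_diff = c, diff
        left = range(part_range.start, part_range.start + best_cut)
        right = range(part_range.start + best_cut, part_range.stop)
        return rec(left) + rec(right)

    return [
        Segment(component=_restrict(component, r), partites=r)
        for r in rec(range(component.n_partites))
    ]


def merge_solutions(
    segments: Sequence[Segment],
    sub_solutions: Sequence[Solution],
    full_component: Component,
    params: CostParams,
) -> Solution:
    """Merge sub-solutions of disjoint run groups back into one solution.

    Matchings from different sub-solutions with at least one connecting edge
    in the full component are candidate pairs; their distance is the minimum
    connecting edge weight. Pairs are merged agglomeratively in ascending
    distance (ties lexicographic) while their run coverages are disjoint,
    recomputing distances after each merge, until closure. If more than ``p``
    clusters remain, remaining run-disjoint pairs are merged cheapest-first
    regardless of connectivity so the output satisfies the solution-size
    constraint.
    """
    seen_parts: set[int] = set()
    for seg in segments:
        overlap = seen_parts.intersection(seg.partites)
        if overlap:
            raise IntegrityError(f"segments overlap in partites {sorted(overlap)}")
        seen_parts.update(seg.partites)
    if seen_parts != set(range(full_component.n_partites)):
        raise IntegrityError("segments do not cover the full component")

    # clusters as sorted tuples of full-component (partite, idx) keys
    clusters: list[tuple[tuple[int, int], ...]] = []
    for seg, sol in zip(segments, sub_solutions):
        offset = seg.partites.start
        for m in sol.matchings:
            picks = [(k + offset, i) for k, i in real_picks(seg.component, m)]
            if picks:
                clusters.append(tuple(sorted(picks)))

    def runs_of(cl) -> set[int]:
        return {k for k, _ in cl}

    def distance(ca, cb) -> float:
        best = np.inf
        for a in ca:
            for b in cb:
                w = full_component.edge_weight(a, b)
                if w is not None and w < best:
                    best = w
        return best

    def merge_pass(require_edge: bool) -> bool:
        best = None  # (dist, key, ia, ib)
        for ia in range(len(clusters)):
            for ib in range(ia + 1, len(clusters)):
                if runs_of(clusters[ia]) & runs_of(clusters[ib]):
                    continue
                d = distance(clusters[ia], clusters[ib])
                if require_edge and not np.isfinite(d):
                    continue
                key = (d, clusters[ia], clusters[ib])
                if best is None or key < best[0]:
                    best = (key, ia, ib)
        if best is None:
            return False
        _, ia, ib = best
        merged = tuple(sorted(clusters[ia] + clusters[ib]))
        clusters[:] = [c for j, c in enumerate(clusters) if j not in (ia, ib)] + [merged]
        return True

    while merge_pass(require_edge=True):
        pass
    while len(clusters) > full_component.p and merge_pass(require_edge=False):
        pass

    sizes = full_component.sizes
    matchings: list[Linkage] = []
    for cl in clusters:
        picks = dict(cl)
        matchings.append(tuple(picks.get(k, sizes[k]) for k in range(full_component.n_partites)))
    matchings = pad_solution(full_component, matchings)
    sol = Solution(matchings, 0.0)
    sol.total_cost = solution_cost(full_component, sol, params)
    return sol


def solve_segmented(
    component: Component,
    params: CostParams,
    node_limit: int,
    solver,
) -> Solution:
    """segment -> solve each -> merge; ``solver(component) -> Solution``."""
    segments = segment_component(component, node_limit)
    if len(segments) == 1:
        return solver(component)
    subs = [solver(seg.component) for seg in segments]
    return merge_solutions(segments, subs, component, params)


# ---------------------------------------------------------------------------
# recursive folder alignment
# ---------------------------------------------------------------------------

TABLE_EXTS = (".csv", ".tsv", ".txt")


def _list_tables(folder: str) -> list[str]:
    return sorted(
        os.path.join(folder, f)
        for f in os.listdir(folder)
        if f.lower().endswith(TABLE_EXTS)
        and os.path.isfile(os.path.join(folder, f))
        and not f.startswith(("annotation", "config"))  # fixture metadata, not runs
    )


def _list_subfolders(folder: str) -> list[str]:
    return sorted(
        os.path.join(folder, d)
        for d in os.listdir(folder)
        if os.path.isdir(os.path.join(folder, d))
    )


def align_recursive(root_folder: str, config) -> "RecursiveResult":
    """Bottom-up alignment over a folder tree (replicates in subfolders).

    Each subfolder's tables are aligned; every consensus group is carried
    upward as one representative feature (mean m/z, RT and area of its
    members) and the parent level aligns the representatives. Provenance to
    leaf (run name, feature id) pairs is preserved throughout.
    """
    from .feature_io import Feature, Run, read_feature_table
    from .pipeline import align_runs

    def rec(folder: str, depth: int) -> Optional[tuple["Run", dict[str, list[tuple[str, str]]]]]:
        tables = _list_tables(folder)
        subfolders = _list_subfolders(folder)
        runs: list[Run] = []
        provenance: dict[tuple[str, str], list[tuple[str, str]]] = {}
        for i, path in enumerate(tables):
            run = read_feature_table(
                path,
                column_map=config.column_map,
                rt_unit=config.rt_unit,
                acquisition_index=i,
            )
            runs.append(run)
            for f in run.features:
                provenance[(run.name, f.feature_id)] = [(run.name, f.feature_id)]
        for sub in subfolders:
            child = rec(sub, depth + 1)
            if child is None:
                log.warning("skipping empty subfolder %s", sub)
                continue
            child_run, child_prov = child
            child_run.acquisition_index = len(runs)
            runs.append(child_run)
            for fid, leaves in child_prov.items():
                provenance[(child_run.name, fid)] = leaves
        if not runs:
            return None
        label = os.path.basename(os.path.abspath(folder))
        if len(runs) == 1:
            only = runs[0]
            merged = {
                f.feature_id: provenance[(only.name, f.feature_id)] for f in only.features
            }
            passthrough = Run(name=label, acquisition_index=0, features=list(only.features))
            return passthrough, merged
        result = align_runs(runs, config)
        reps: list[Feature] = []
        merged = {}
        for g, row in enumerate(result.rows):
            members = [
                (rn, fid) for rn, entry in row.entries.items() if entry is not None
                for fid in [entry[0]]
            ]
            leaves: list[tuple[str, str]] = []
            for rn, fid in members:
                leaves.extend(provenance[(rn, fid)])
            feats = [
                next(f for f in run.features if f.feature_id == entry[0])
                for run in result.runs
                for entry in [row.entries.get(run.name)]
                if entry is not None
            ]
            rep_id = f"g{g:05d}"
            reps.append(
                Feature(
                    mz=float(np.mean([f.mz for f in feats])),
                    rt=float(np.mean([f.rt for f in feats])),
                    area=float(np.mean([f.area for f in feats])),
                    feature_id=rep_id,
                )
            )
            merged[rep_id] = sorted(leaves)
        return Run(name=label, acquisition_index=0, features=reps), merged

    top = rec(root_folder, 0)
    if top is None:
        raise IntegrityError(f"no feature tables found under {root_folder}")
    run, provenance = top
    groups = [provenance[f.feature_id] for f in run.features]
    return RecursiveResult(
        representatives=run,
        groups=groups,
    )


@dataclass
class RecursiveResult:
    """Top-level representatives and their leaf-level member groups."""

    representatives: "object"  # Run of representative features
    groups: list[list[tuple[str, str]]]  # per group: (leaf run name, feature id)
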