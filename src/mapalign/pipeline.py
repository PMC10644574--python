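"""End-to-end orchestration: read -> dedup -> RT warp -> graph -> solve -> write.

The library entry points are :func:`align_runs` (in-memory) and
:func:`run_pipeline` (directory in, consensus CSV out); the CLI in
:mod:`mapalign.cli` is a thin wrapper over these.
"""
from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import yaml

from .errors import ConfigurationError, DataError
from .evaluation import AnnotationSet, MetricsReport, evaluate_matchings
from .feature_io import (
    ConsensusRow,
    Run,
    deduplicate_run,
    read_feature_table,
    write_consensus_table,
)
from .map_core import CostParams, Solution, real_picks
from .relation_graph import Component, ToleranceConfig, build_components
from .rt_alignment import RansacConfig, align_runs_rt
from .scaling import solve_segmented
from .solvers import VlsnsConfig, solve_auto, solve_exact, solve_greedy, solve_vlsns
from .synthetic import SynthConfig

log = logging.getLogger(__name__)


@dataclass
class JobConfig:
    """Everything one alignment job needs; loadable from YAML."""

    input_dir: Optional[str] = None
    output_dir: Optional[str] = None
    column_map: Optional[dict] = None
    rt_unit: str = "min"
    tolerances: ToleranceConfig = field(default_factory=ToleranceConfig)
    ransac: Optional[RansacConfig] = None
    rt_align: bool = True
    reference: Optional[str] = None  # None = auto (most features)
    cost: CostParams = field(default_factory=CostParams)
    solver_method: str = "auto"
    vlsns: VlsnsConfig = field(default_factory=VlsnsConfig)
    exact_limit: int = 20_000
    node_limit: int = 50
    recursive: bool = False
    seed: int = 42

    def __post_init__(self):
        if self.solver_method not in ("auto", "exact", "greedy", "vlsns"):
            raise ConfigurationError(f"unknown solver method {self.solver_method!r}")

    @classmethod
    def from_yaml(cls, path: str) -> "JobConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            io = raw.get("io", {})
            tol = raw.get("tolerances", {})
            ransac = raw.get("ransac")
            cost = raw.get("cost", {})
            solver = raw.get("solver", {})
            scaling = raw.get("scaling", {})
            vlsns = solver.get("vlsns", {})
            return cls(
                input_dir=io.get("input_dir"),
                output_dir=io.get("output_dir"),
                column_map=io.get("column_map"),
                rt_unit=io.get("rt_unit", "min"),
                tolerances=ToleranceConfig(
                    mz_tol=tol.get("mz_da", 0.01),
                    rt_tol=tol.get("rt_min", 0.1),
                    mz_ppm=tol.get("mz_ppm"),
                ),
                ransac=RansacConfig(**ransac) if ransac else None,
                rt_align=raw.get("rt_align", True),
                reference=raw.get("reference"),
                cost=CostParams(**cost) if cost else CostParams(),
                solver_method=solver.get("method", "auto"),
                vlsns=VlsnsConfig(**vlsns) if vlsns else VlsnsConfig(),
                exact_limit=solver.get("exact_limit", 20_000),
                node_limit=scaling.get("node_limit", 50),
                recursive=raw.get("recursive", False),
                seed=raw.get("seed", 42),
            )
        except TypeError as exc:
            raise ConfigurationError(f"bad config {path}: {exc}")


@dataclass
class AlignmentResult:
    rows: list[ConsensusRow]
    matchings: list[dict[str, str]]  # run name -> feature id, per consensus group
    runs: list[Run]  # deduplicated, warped runs (job order)
    report: dict


def _component_seed(base_seed: int, comp_idx: int) -> int:
    return int((base_seed * 1_000_003 + comp_idx) % (2**31 - 1))


def _solve_component(component: Component, cfg: JobConfig, comp_idx: int) -> tuple[Solution, str]:
    vl = replace(cfg.vlsns, seed=_component_seed(cfg.seed, comp_idx))

    def dispatch(comp: Component) -> tuple[Solution, str]:
        if cfg.solver_method == "exact":
            return solve_exact(comp, cfg.cost, max_linkages=None), "exact"
        if cfg.solver_method == "greedy":
            return solve_greedy(comp, cfg.cost, max_linkages=None), "greedy"
        if cfg.solver_method == "vlsns":
            return solve_vlsns(comp, cfg.cost, vl), "vlsns"
        return solve_auto(comp, cfg.cost, vl, exact_limit=cfg.exact_limit)

    if component.n_nodes > cfg.node_limit:
        used = ["segmented"]

        def sub_solver(c: Component) -> Solution:
            sol, name = dispatch(c)
            used.append(name)
            return sol

        sol = solve_segmented(component, cfg.cost, cfg.node_limit, sub_solver)
        return sol, "+".join(used)
    return dispatch(component)


def align_runs(runs: Sequence[Run], cfg: Optional[JobConfig] = None) -> AlignmentResult:
    """Align in-memory runs; fully deterministic given the config seed."""
    if cfg is None:
        cfg = JobConfig()
    if len(runs) < 2:
        raise DataError("need at least two runs to align")
    runs = sorted(runs, key=lambda r: r.acquisition_index)
    deduped = [deduplicate_run(r) for r in runs]
    warped, models, ref_idx = align_runs_rt(
        deduped,
        mz_tol=cfg.tolerances.mz_tol_at(500.0, 500.0),
        rt_tol=cfg.tolerances.rt_tol,
        cfg=cfg.ransac,
        reference=cfg.reference,
        enabled=cfg.rt_align,
    )
    components = build_components(warped, cfg.tolerances)
    rows: list[ConsensusRow] = []
    matchings: list[dict[str, str]] = []
    solver_used: list[str] = []
    total_cost = 0.0
    run_names = [r.name for r in warped]
    for idx, comp in enumerate(components):
        sol, used = _solve_component(comp, cfg, idx)
        solver_used.append(used)
        total_cost += sol.total_cost
        for m in sol.matchings:
            picks = real_picks(comp, m)
            if not picks:
                continue
            entries: dict[str, Optional[tuple[str, float]]] = {rn: None for rn in run_names}
            mzs, rts = [], []
            group: dict[str, str] = {}
            for k, i in picks:
                node = comp.nodes[k][i]
                feat = warped[node.run].features[node.idx]
                entries[run_names[node.run]] = (feat.feature_id, feat.area)
                group[run_names[node.run]] = feat.feature_id
                mzs.append(comp.mz[k][i])
                rts.append(comp.rt[k][i])
            rows.append(
                ConsensusRow(
                    consensus_mz=float(np.mean(mzs)),
                    consensus_rt=float(np.mean(rts)),
                    entries=entries,
                )
            )
            matchings.append(group)
    order = sorted(range(len(rows)), key=lambda i: (rows[i].consensus_mz, rows[i].consensus_rt))
    rows = [rows[i] for i in order]
    matchings = [matchings[i] for i in order]
    report = {
        "n_runs": len(runs),
        "n_features": [len(r.features) for r in runs],
        "n_features_dedup": [len(r.features) for r in deduped],
        "reference_run": run_names[ref_idx],
        "drift_models": [
            {"run": rn, "slope": m.slope, "intercept": m.intercept, "n_inliers": m.n_inliers}
            for rn, m in zip(run_names, models)
        ],
        "n_components": len(components),
        "component_sizes": [c.n_nodes for c in components],
        "solver_used": solver_used,
        "total_cost": total_cost,
        "n_consensus": len(rows),
    }
    return AlignmentResult(rows=rows, matchings=matchings, runs=warped, report=report)


def load_runs(cfg: JobConfig) -> list[Run]:
    """Read every feature table directly inside ``cfg.input_dir`` (flat mode)."""
    if not cfg.input_dir or not os.path.isdir(cfg.input_dir):
        raise ConfigurationError(f"input_dir {cfg.input_dir!r} is not a directory")
    paths = sorted(
        os.path.join(cfg.input_dir, f)
        for f in os.listdir(cfg.input_dir)
        if f.lower().endswith((".csv", ".tsv", ".txt"))
        and not f.startswith("annotation")
        and not f.startswith("config")
    )
    if len(paths) < 2:
        raise DataError(f"need >=2 feature tables in {cfg.input_dir}, found {len(paths)}")
    return [
        read_feature_table(
            p, column_map=cfg.column_map, rt_unit=cfg.rt_unit, acquisition_index=i
        )
        for i, p in enumerate(paths)
    ]


def run_pipeline(cfg: JobConfig) -> AlignmentResult:
    """Full job: read tables, align, and (if configured) write outputs."""
    if cfg.recursive:
        from .scaling import align_recursive

        rec = align_recursive(cfg.input_dir, cfg)
        matchings: list[dict[str, str]] = []
        for group in rec.groups:
            entry: dict[str, str] = {}
            for rn, fid in group:
                entry[rn] = fid
            matchings.append(entry)
        result = AlignmentResult(
            rows=[], matchings=matchings, runs=[],
            report={"mode": "recursive", "n_groups": len(matchings)},
        )
        return result
    runs = load_runs(cfg)
    result = align_runs(runs, cfg)
    if cfg.output_dir:
        os.makedirs(cfg.output_dir, exist_ok=True)
        write_consensus_table(
            result.rows, result.runs, os.path.join(cfg.output_dir, "consensus.csv")
        )
        import json

        with open(os.path.join(cfg.output_dir, "report.json"), "w") as fh:
            json.dump(result.report, fh, indent=2)
    return result


def run_evaluation(
    result: AlignmentResult, annotation: AnnotationSet, out_path: Optional[str] = None
) -> MetricsReport:
    """Score an alignment result against an annotation; optionally write JSON."""
    known = set(annotation.run_names)
    used = {rn for m in result.matchings for rn in m}
    if not used <= known:
        raise ConfigurationError(
            f"alignment contains runs absent from the annotation: {sorted(used - known)}"
        )
    report = evaluate_matchings(result.matchings, annotation)
    if out_path:
        report.to_json(out_path)
    return report


def simulate_to_dir(cfg: SynthConfig, out_dir: str, nested: bool = False) -> None:
    """Generate a synthetic benchmark and write it as a loadable fixture."""
    from .synthetic import generate_benchmark, write_fixture

    runs, annotation, _ = generate_benchmark(cfg)
    groups = None
    if nested:
        names = [r.name for r in runs]
        half = max(1, len(names) // 2)
        groups = [names[:half], names[half:]]
    write_fixture(runs, annotation, out_dir, cfg=cfg, nested_groups=groups)
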