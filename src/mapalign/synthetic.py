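"""Synthetic multi-run feature lists with exported ground truth.

Emulates the structure of real untargeted LC-MS benchmark data: a set of
true analytes seen across runs through per-run affine RT drift (optionally
with a smooth sinusoidal perturbation the linear correction cannot absorb),
Gaussian m/z and RT jitter, log-normal intensity variation, random feature
dropout, and uniform decoy (noise) features. The exact generated feature of
every analyte in every run is recorded as an :class:`AnnotationSet`, so the
whole pipeline can be scored without external downloads.
"""
from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DataError
from .evaluation import AnnotationSet
from .feature_io import Feature, Run

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; defaults emulate a mild 6-run benchmark.

    Units: m/z in Da, RT in minutes. ``area_log_cv`` is the sigma of the
    multiplicative log-normal intensity noise. ``decoy_density`` is decoys
    per analyte per run. ``hard_mode`` drops decoys within twice the stated
    matching tolerances of true features instead of uniformly.
    """

    n_runs: int = 6
    n_analytes: int = 100
    mz_range: tuple[float, float] = (100.0, 1000.0)
    rt_range: tuple[float, float] = (1.0, 14.0)
    drift_slope_range: tuple[float, float] = (0.97, 1.03)
    drift_intercept_range: tuple[float, float] = (-0.2, 0.2)
    drift_perturb_amp: float = 0.0
    drift_perturb_period: float = 5.0
    mz_sd: float = 0.002
    rt_sd: float = 0.02
    area_log_cv: float = 0.3
    dropout_prob: float = 0.05
    decoy_density: float = 0.5
    min_separation: Optional[tuple[float, float]] = None
    hard_mode: bool = False
    mz_tol: float = 0.01
    rt_tol: float = 0.1
    seed: int = 42

    def __post_init__(self):
        if not (0.0 <= self.dropout_prob <= 1.0):
            raise ValueError("dropout_prob must be in [0, 1]")
        if min(self.mz_sd, self.rt_sd, self.area_log_cv, self.decoy_density) < 0:
            raise ValueError("noise magnitudes must be >= 0")


@dataclass
class RunDrift:
    slope: float
    intercept: float
    perturb_amp: float
    perturb_phase: float
    perturb_period: float

    def apply(self, rt: np.ndarray) -> np.ndarray:
        out = self.slope * rt + self.intercept
        if self.perturb_amp:
            out = out + self.perturb_amp * np.sin(TWO_PI * rt / self.perturb_period + self.perturb_phase)
        return out


def generate_ground_truth(cfg: SynthConfig) -> pd.DataFrame:
    """True analyte table: analyte_id, mz, rt, base area (log-normal).

    With ``min_separation=(dmz, drt)`` a candidate is rejected when another
    analyte already sits within *both* windows; bounded retries, then error.
    """
    rng = np.random.default_rng(cfg.seed)
    mzs: list[float] = []
    rts: list[float] = []
    max_tries = 1000 * cfg.n_analytes
    tries = 0
    while len(mzs) < cfg.n_analytes:
        if tries >= max_tries:
            raise DataError(
                f"could not place {cfg.n_analytes} analytes with separation "
                f"{cfg.min_separation} after {max_tries} tries"
            )
        tries += 1
        mz = rng.uniform(*cfg.mz_range)
        rt = rng.uniform(*cfg.rt_range)
        if cfg.min_separation is not None:
            dmz, drt = cfg.min_separation
            if any(abs(mz - m) < dmz and abs(rt - r) < drt for m, r in zip(mzs, rts)):
                continue
        mzs.append(mz)
        rts.append(rt)
    areas = np.exp(rng.normal(np.log(1e6), 1.0, size=cfg.n_analytes))
    return pd.DataFrame(
        {
            "analyte_id": [f"A{i:04d}" for i in range(cfg.n_analytes)],
            "mz": mzs,
            "rt": rts,
            "area": areas,
        }
    )


def draw_run_drifts(cfg: SynthConfig, rng: np.random.Generator) -> list[RunDrift]:
    return [
        RunDrift(
            slope=float(rng.uniform(*cfg.drift_slope_range)),
            intercept=float(rng.uniform(*cfg.drift_intercept_range)),
            perturb_amp=cfg.drift_perturb_amp,
            perturb_phase=float(rng.uniform(0, TWO_PI)),
            perturb_period=cfg.drift_perturb_period,
        )
        for _ in range(cfg.n_runs)
    ]


def realize_runs(
    truth: pd.DataFrame, cfg: SynthConfig
) -> tuple[list[Run], AnnotationSet, list[RunDrift]]:
    """Materialize per-run feature lists and the exact ground-truth annotation."""
    rng = np.random.default_rng(cfg.seed + 1)
    drifts = draw_run_drifts(cfg, rng)
    run_names = [f"run{r:02d}" for r in range(cfg.n_runs)]
    runs: list[Run] = []
    analytes: dict[str, dict[str, Optional[str]]] = {
        a: {rn: None for rn in run_names} for a in truth["analyte_id"]
    }
    n_decoys = int(round(cfg.decoy_density * cfg.n_analytes))
    for r, rn in enumerate(run_names):
        drift = drifts[r]
        records: list[tuple[float, float, float, Optional[str]]] = []
        drifted = drift.apply(truth["rt"].to_numpy())
        for j, row in truth.reset_index(drop=True).iterrows():
            if rng.random() < cfg.dropout_prob:
                continue
            mz = row["mz"] + rng.normal(0.0, cfg.mz_sd)
            rt = max(0.0, drifted[j] + rng.normal(0.0, cfg.rt_sd))
            area = row["area"] * np.exp(rng.normal(0.0, cfg.area_log_cv))
            records.append((mz, rt, area, row["analyte_id"]))
        for d in range(n_decoys):
            if cfg.hard_mode and len(truth):
                j = int(rng.integers(len(truth)))
                mz = truth["mz"].iloc[j] + rng.uniform(-2 * cfg.mz_tol, 2 * cfg.mz_tol)
                rt = max(0.0, float(drifted[j]) + rng.uniform(-2 * cfg.rt_tol, 2 * cfg.rt_tol))
            else:
                mz = rng.uniform(*cfg.mz_range)
                rt = rng.uniform(*cfg.rt_range)
            area = float(np.exp(rng.normal(np.log(1e5), 1.0)))
            records.append((float(mz), float(rt), area, None))
        # present features in elution order, as real exports are
        records.sort(key=lambda t: (t[1], t[0]))
        features = []
        for i, (mz, rt, area, analyte) in enumerate(records):
            fid = f"{rn}_f{i:04d}"
            features.append(Feature(mz=float(mz), rt=float(rt), area=float(area), feature_id=fid))
            if analyte is not None:
                analytes[analyte][rn] = fid
        runs.append(Run(name=rn, acquisition_index=r, features=features))
    return runs, AnnotationSet(run_names=run_names, analytes=analytes), drifts


def generate_benchmark(cfg: SynthConfig) -> tuple[list[Run], AnnotationSet, list[RunDrift]]:
    """Ground truth + realized runs in one call."""
    truth = generate_ground_truth(cfg)
    return realize_runs(truth, cfg)


def write_fixture(
    runs: Sequence[Run],
    annotation: AnnotationSet,
    out_dir: str,
    cfg: Optional[SynthConfig] = None,
    nested_groups: Optional[Sequence[Sequence[str]]] = None,
) -> None:
    """Write one CSV per run, the annotation CSV and the config JSON.

    ``nested_groups`` (lists of run names) lays the run files out in
    subfolders, producing a tree consumable by recursive alignment.
    """
    os.makedirs(out_dir, exist_ok=True)
    folder_of: dict[str, str] = {}
    if nested_groups:
        for g, names in enumerate(nested_groups):
            sub = os.path.join(out_dir, f"sample{g}")
            os.makedirs(sub, exist_ok=True)
            for n in names:
                folder_of[n] = sub
    for run in runs:
        df = pd.DataFrame(
            {
                "mz": [f.mz for f in run.features],
                "rt": [f.rt for f in run.features],
                "area": [f.area for f in run.features],
                "feature_id": [f.feature_id for f in run.features],
            }
        )
        df.to_csv(os.path.join(folder_of.get(run.name, out_dir), f"{run.name}.csv"), index=False)
    annotation.to_csv(os.path.join(out_dir, "annotation.csv"))
    if cfg is not None:
        with open(os.path.join(out_dir, "config.json"), "w") as fh:
            json.dump(asdict(cfg), fh, indent=2, default=list)
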