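"""Coarse retention-time registration by robust linear regression (RANSAC).

Run-to-run RT drift is corrected *coarsely* before feature matching: every
run is warped onto a reference run by an affine model ``rt_ref = a*rt + b``
fitted with RANSAC on anchor pairs (confident one-to-one feature matches).
Residual per-feature drift is deliberately left to the assignment solver.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import AlignmentFailedError, DataError
from .feature_io import Run, warp_feature

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnchorPair:
    """A confident correspondence used as a RANSAC input point (minutes)."""

    rt_ref: float
    rt_target: float
    weight: float = 1.0


@dataclass(frozen=True)
class DriftModel:
    """Affine RT drift model ``rt_ref = slope * rt_target + intercept``."""

    slope: float = 1.0
    intercept: float = 0.0
    n_inliers: int = 0
    inlier_threshold: float = 0.0

    @classmethod
    def identity(cls) -> "DriftModel":
        return cls()

    def apply(self, rt: float) -> float:
        return self.slope * rt + self.intercept


@dataclass(frozen=True)
class RansacConfig:
    """RANSAC settings; ``min_inliers=None`` means max(10, 10% of anchors)."""

    n_iterations: int = 1000
    inlier_threshold: float = 0.05
    min_inliers: Optional[int] = None
    seed: int = 42

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.inlier_threshold <= 0:
            raise ValueError("inlier_threshold must be > 0")


def select_reference(runs: Sequence[Run]) -> int:
    """Index of the run with the most features; ties -> lowest acquisition index."""
    if not runs:
        raise DataError("cannot select a reference from an empty run list")
    order = sorted(
        range(len(runs)), key=lambda i: (-len(runs[i].features), runs[i].acquisition_index)
    )
    return order[0]


def collect_anchor_pairs(
    ref: Run, target: Run, mz_tol: float, rt_window: float
) -> list[AnchorPair]:
    """Anchor pairs for RANSAC: target features with a *unique* reference match.

    A target feature becomes an anchor iff exactly one reference feature lies
    within ``mz_tol`` (Da) and ``rt_window`` (min); ambiguous targets are
    skipped. Anchors are returned sorted by target RT.
    """
    if mz_tol <= 0 or rt_window <= 0:
        raise ValueError("tolerances must be > 0")
    ref_mz = np.array([f.mz for f in ref.features])
    ref_rt = np.array([f.rt for f in ref.features])
    order = np.argsort(ref_mz, kind="stable")
    ref_mz_sorted = ref_mz[order]
    anchors: list[AnchorPair] = []
    for f in target.features:
        lo = np.searchsorted(ref_mz_sorted, f.mz - mz_tol, side="left")
        hi = np.searchsorted(ref_mz_sorted, f.mz + mz_tol, side="right")
        cand = order[lo:hi]
        cand = cand[np.abs(ref_rt[cand] - f.rt) <= rt_window]
        if len(cand) == 1:
            anchors.append(AnchorPair(rt_ref=float(ref_rt[cand[0]]), rt_target=f.rt))
    anchors.sort(key=lambda a: a.rt_target)
    return anchors


def fit_ransac_line(anchors: Sequence[AnchorPair], cfg: RansacConfig) -> DriftModel:
    """Fit ``rt_ref = a*rt_target + b`` by RANSAC over 2-point samples.

    The model with the most inliers (|residual| <= threshold) wins; ties are
    broken by the smaller inlier residual sum of squares. The winning inlier
    set is then refit by ordinary least squares. Deterministic given the seed.

    Raises :class:`DataError` with fewer than two anchors and
    :class:`AlignmentFailedError` when the best inlier count is below
    ``min_inliers`` (callers fall back to the identity model).
    """
    n = len(anchors)
    if n < 2:
        raise DataError(f"RANSAC needs >=2 anchor pairs, got {n}")
    x = np.array([a.rt_target for a in anchors])
    y = np.array([a.rt_ref for a in anchors])
    min_inliers = cfg.min_inliers if cfg.min_inliers is not None else max(10, int(0.1 * n))
    min_inliers = min(min_inliers, n)
    rng = np.random.default_rng(cfg.seed)

    best_count = -1
    best_rss = np.inf
    best_mask: Optional[np.ndarray] = None
    for _ in range(cfg.n_iterations):
        i, j = rng.choice(n, size=2, replace=False)
        if x[i] == x[j]:
            continue
        a = (y[j] - y[i]) / (x[j] - x[i])
        b = y[i] - a * x[i]
        resid = y - (a * x + b)
        mask = np.abs(resid) <= cfg.inlier_threshold
        count = int(mask.sum())
        rss = float((resid[mask] ** 2).sum())
        if count > best_count or (count == best_count and rss < best_rss):
            best_count, best_rss, best_mask = count, rss, mask
    if best_mask is None or best_count < max(min_inliers, 2):
        raise AlignmentFailedError(
            f"best RANSAC model has {max(best_count, 0)} inliers < {min_inliers}"
        )
    slope, intercept = np.polyfit(x[best_mask], y[best_mask], deg=1)
    if slope <= 0:
        log.warning("fitted RT drift slope %.4f <= 0: physically implausible", slope)
    return DriftModel(
        slope=float(slope),
        intercept=float(intercept),
        n_inliers=best_count,
        inlier_threshold=cfg.inlier_threshold,
    )


def warp_run(run: Run, model: DriftModel) -> Run:
    """Apply a drift model to every feature's RT (m/z, area, ids unchanged)."""
    warped = [warp_feature(f, model.apply(f.rt)) for f in run.features]
    return Run(name=run.name, acquisition_index=run.acquisition_index, features=warped)


def align_runs_rt(
    runs: Sequence[Run],
    mz_tol: float,
    rt_tol: float,
    cfg: Optional[RansacConfig] = None,
    reference: Optional[str] = None,
    enabled: bool = True,
    anchor_rt_window: Optional[float] = None,
) -> tuple[list[Run], list[DriftModel], int]:
    """Warp all runs to a reference run; the reference gets the identity model.

    ``reference=None`` auto-selects the run with the most features. The anchor
    search window defaults to ``max(1 min, 10 * rt_tol)`` — it must cover the
    expected inter-run drift, which is typically much larger than the final
    matching tolerance. A run whose RANSAC fit fails keeps the identity model
    with a warning.
    """
    if anchor_rt_window is None:
        anchor_rt_window = max(1.0, 10.0 * rt_tol)
    if cfg is None:
        cfg = RansacConfig(inlier_threshold=rt_tol / 2)
    if reference is None:
        ref_idx = select_reference(runs)
    else:
        names = [r.name for r in runs]
        if reference not in names:
            raise DataError(f"reference run {reference!r} not among {names}")
        ref_idx = names.index(reference)
    models: list[DriftModel] = []
    warped: list[Run] = []
    for i, run in enumerate(runs):
        if not enabled or i == ref_idx:
            model = DriftModel.identity()
        else:
            anchors = collect_anchor_pairs(runs[ref_idx], run, mz_tol, rt_window=anchor_rt_window)
            try:
                model = fit_ransac_line(anchors, cfg)
            except (DataError, AlignmentFailedError) as exc:
                log.warning("run %s: RT alignment failed (%s); using identity", run.name, exc)
                model = DriftModel.identity()
        models.append(model)
        warped.append(warp_run(run, model))
    return warped, models, ref_idx
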