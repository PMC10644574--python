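"""Accuracy benchmarking of alignment results against annotated matchings.

For each annotated analyte, the predicted matching sharing the most
(run, feature) entries is its *corresponding matching*; each analyte x run
cell is then labelled exactly once:

* TP — predicted feature equals the annotated feature,
* FP — a feature predicted where none is annotated, or the wrong feature,
* TN — absent in both,
* FN — annotated feature missing from the prediction.

Reported metrics: precision, recall, F1, feature accuracy
F_ACC = (TP+TN)/total, and analyte accuracy A_ACC = fraction of analytes
whose every cell is TP or TN.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal
from typing import Mapping, Optional, Sequence

import pandas as pd

from .errors import IntegrityError
from .feature_io import Run
from .relation_graph import ToleranceConfig

log = logging.getLogger(__name__)

Matching = Mapping[str, str]  # run name -> feature id


@dataclass
class AnnotationSet:
    """Per-analyte reference matchings: run name -> feature id or None (absent)."""

    run_names: list[str]
    analytes: dict[str, dict[str, Optional[str]]] = field(default_factory=dict)

    def __post_init__(self):
        per_run_seen: dict[str, set[str]] = {r: set() for r in self.run_names}
        for analyte, entries in self.analytes.items():
            for run, fid in entries.items():
                if fid is None:
                    continue
                if run not in per_run_seen:
                    raise IntegrityError(f"analyte {analyte}: unknown run {run!r}")
                if fid in per_run_seen[run]:
                    raise IntegrityError(
                        f"feature {fid!r} in run {run} annotated to more than one analyte"
                    )
                per_run_seen[run].add(fid)

    @classmethod
    def from_csv(cls, path: str, run_names: Optional[Sequence[str]] = None) -> "AnnotationSet":
        """Load from a long CSV with columns analyte_id, run, feature_id
        (empty feature_id = absent)."""
        df = pd.read_csv(path, dtype={"analyte_id": str, "run": str})
        runs = sorted(df["run"].unique()) if run_names is None else list(run_names)
        analytes: dict[str, dict[str, Optional[str]]] = {}
        for _, rec in df.iterrows():
            a = str(rec["analyte_id"])
            fid = rec["feature_id"]
            analytes.setdefault(a, {r: None for r in runs})[str(rec["run"])] = (
                None if pd.isna(fid) or fid == "" else str(fid)
            )
        return cls(run_names=runs, analytes=analytes)

    def to_csv(self, path: str) -> None:
        records = [
            {"analyte_id": a, "run": r, "feature_id": fid if fid is not None else ""}
            for a, entries in self.analytes.items()
            for r, fid in entries.items()
        ]
        pd.DataFrame.from_records(records).to_csv(path, index=False)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    precision: float
    recall: float
    f1: float
    feature_accuracy: float
    analyte_accuracy: float
    counts: Optional[ConfusionCounts] = None

    def rounded(self) -> dict[str, float]:
        """Display rounding: half-even to 3 decimals."""
        return {
            name: float(Decimal(repr(value)).quantize(Decimal("0.001"), ROUND_HALF_EVEN))
            for name, value in (
                ("precision", self.precision),
                ("recall", self.recall),
                ("f1", self.f1),
                ("feature_accuracy", self.feature_accuracy),
                ("analyte_accuracy", self.analyte_accuracy),
            )
        }

    def to_json(self, path: str) -> None:
        payload = self.rounded()
        if self.counts is not None:
            payload.update(
                tp=self.counts.tp, fp=self.counts.fp, tn=self.counts.tn, fn=self.counts.fn
            )
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def correspond_predictions(
    predicted: Sequence[Matching], annotation: AnnotationSet
) -> dict[str, Optional[int]]:
    """Map each analyte to the index of its corresponding predicted matching.

    The matching sharing the most (run, feature) entries with the annotated
    matching wins; ties prefer the matching with fewer features, then the
    lexicographically smallest content. Zero overlap -> None.
    """
    correspondence: dict[str, Optional[int]] = {}
    for analyte, entries in annotation.analytes.items():
        ann = {(r, fid) for r, fid in entries.items() if fid is not None}
        best: Optional[tuple] = None
        best_idx: Optional[int] = None
        for idx, matching in enumerate(predicted):
            shared = sum(1 for r, fid in matching.items() if (r, fid) in ann)
            if shared == 0:
                continue
            key = (-shared, len(matching), tuple(sorted(matching.items())))
            if best is None or key < best:
                best, best_idx = key, idx
        correspondence[analyte] = best_idx
    return correspondence


def confusion_counts(
    predicted: Sequence[Matching],
    annotation: AnnotationSet,
    correspondence: Optional[dict[str, Optional[int]]] = None,
) -> tuple[ConfusionCounts, dict[str, bool]]:
    """Tally TP/FP/TN/FN over every analyte x run cell.

    Returns the counts and a per-analyte flag marking fully correct rows
    (every cell TP or TN), the basis of analyte accuracy.
    """
    if correspondence is None:
        correspondence = correspond_predictions(predicted, annotation)
    tp = fp = tn = fn = 0
    analyte_ok: dict[str, bool] = {}
    for analyte, entries in annotation.analytes.items():
        idx = correspondence.get(analyte)
        matching = predicted[idx] if idx is not None else {}
        ok = True
        for run in annotation.run_names:
            ann = entries.get(run)
            pred = matching.get(run)
            if ann is None and pred is None:
                tn += 1
            elif ann is not None and pred == ann:
                tp += 1
            elif pred is not None:
                fp += 1  # spurious or wrong feature
                ok = False
            else:
                fn += 1
                ok = False
        analyte_ok[analyte] = ok
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn), analyte_ok


def compute_metrics(
    counts: ConfusionCounts, analyte_ok: Optional[Mapping[str, bool]] = None
) -> MetricsReport:
    """P, R, F1, feature accuracy from counts; analyte accuracy from row flags.

    Zero denominators yield 0 with a warning (degenerate inputs).
    """
    if counts.total <= 0:
        raise ValueError("empty confusion table")

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            log.warning("%s undefined (zero denominator); reporting 0", name)
            return 0.0
        return num / den

    p = ratio(counts.tp, counts.tp + counts.fp, "precision")
    r = ratio(counts.tp, counts.tp + counts.fn, "recall")
    f1 = 0.0 if (p + r) == 0 else 2 * p * r / (p + r)
    if (p + r) == 0:
        log.warning("f1 undefined (precision + recall = 0); reporting 0")
    f_acc = (counts.tp + counts.tn) / counts.total
    if analyte_ok:
        a_acc = sum(analyte_ok.values()) / len(analyte_ok)
    else:
        a_acc = 0.0
    return MetricsReport(
        precision=p, recall=r, f1=f1, feature_accuracy=f_acc, analyte_accuracy=a_acc,
        counts=counts,
    )


def evaluate_matchings(predicted: Sequence[Matching], annotation: AnnotationSet) -> MetricsReport:
    """Convenience: correspondence -> confusion counts -> metrics."""
    counts, analyte_ok = confusion_counts(predicted, annotation)
    return compute_metrics(counts, analyte_ok)


def infer_annotation(
    candidate_runs: Sequence[Run],
    annotated: AnnotationSet,
    annotated_coords: Mapping[str, Mapping[str, tuple[float, float]]],
    tol: ToleranceConfig,
) -> AnnotationSet:
    """Transfer an annotation onto another feature set by nearest-neighbor.

    ``annotated_coords[analyte][run] = (mz, rt)`` gives the coordinates of
    each annotated feature. Candidates within the tolerance window are ranked
    by the tolerance-normalized squared distance
    ``(dmz/mz_tol)^2 + (drt/rt_tol)^2``; each candidate feature may be
    claimed by at most one analyte per run (closest wins, ties break on the
    lexicographically smallest analyte id then feature id).
    """
    runs_by_name = {r.name: r for r in candidate_runs}
    inferred: dict[str, dict[str, Optional[str]]] = {
        a: {r: None for r in annotated.run_names} for a in annotated.analytes
    }
    for run_name in annotated.run_names:
        run = runs_by_name.get(run_name)
        if run is None:
            continue
        pairs = []  # (distance, analyte, feature_id)
        for analyte, entries in annotated.analytes.items():
            coords = annotated_coords.get(analyte, {}).get(run_name)
            if coords is None or entries.get(run_name) is None:
                continue
            mz0, rt0 = coords
            for f in run.features:
                mz_t = tol.mz_tol_at(mz0, f.mz)
                if abs(f.mz - mz0) > mz_t or abs(f.rt - rt0) > tol.rt_tol:
                    continue
                d = (abs(f.mz - mz0) / mz_t) ** 2 + (abs(f.rt - rt0) / tol.rt_tol) ** 2
                pairs.append((d, analyte, f.feature_id))
        pairs.sort()
        claimed_analytes: set[str] = set()
        claimed_features: set[str] = set()
        for d, analyte, fid in pairs:
            if analyte in claimed_analytes or fid in claimed_features:
                continue
            inferred[analyte][run_name] = fid
            claimed_analytes.add(analyte)
            claimed_features.add(fid)
    return AnnotationSet(run_names=list(annotated.run_names), analytes=inferred)
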