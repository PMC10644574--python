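"""Reading, deduplicating and writing LC-MS feature tables.

A *feature* is one detected chromatographic peak (m/z in Da, retention time
in minutes, integrated area). One CSV/TSV file per LC-MS run is expected,
as exported by common feature-extraction software (MZmine, XCMS, OpenMS...),
hence the tolerant, synonym-aware column mapping.
"""
from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import pandas as pd

from .errors import ConfigurationError, DataError, IntegrityError

log = logging.getLogger(__name__)

#: case-insensitive header synonyms accepted when no explicit column map is given
COLUMN_SYNONYMS = {
    "mz": ("mz", "m/z", "mass", "mzmed", "mz_da"),
    "rt": ("rt", "retention time", "retention_time", "rtmed", "rtmin", "rt_min", "time"),
    "area": ("area", "intensity", "height", "into", "abundance"),
    "feature_id": ("feature_id", "id", "name", "feature"),
}


@dataclass(frozen=True)
class Feature:
    """One detected LC-MS peak.

    ``rt`` is always minutes inside the package; ``rt_original`` keeps the
    pre-warp retention time once a drift model has been applied.
    """

    mz: float
    rt: float
    area: float
    feature_id: str
    rt_original: Optional[float] = None


@dataclass
class Run:
    """One LC-MS run: a named, acquisition-ordered list of features."""

    name: str
    acquisition_index: int
    features: list[Feature] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.features)

    def __post_init__(self):
        ids = [f.feature_id for f in self.features]
        if len(set(ids)) != len(ids):
            raise IntegrityError(f"run {self.name}: duplicate feature ids")


@dataclass
class ConsensusRow:
    """One aligned consensus feature: mean coordinates plus one slot per run.

    ``entries`` maps run name to ``(feature_id, area)`` or ``None`` (absent).
    """

    consensus_mz: float
    consensus_rt: float
    entries: dict[str, Optional[tuple[str, float]]]


def _resolve_columns(
    columns: Sequence[str], column_map: Optional[Mapping[str, str]]
) -> dict[str, Optional[str]]:
    lower = {str(c).strip().lower(): c for c in columns}
    resolved: dict[str, Optional[str]] = {}
    for key in ("mz", "rt", "area"):
        if column_map and key in column_map:
            name = column_map[key]
            if name not in columns:
                raise ConfigurationError(
                    f"mapped column {name!r} for {key!r} not found in header {list(columns)}"
                )
            resolved[key] = name
            continue
        for syn in COLUMN_SYNONYMS[key]:
            if syn in lower:
                resolved[key] = lower[syn]
                break
        else:
            raise ConfigurationError(
                f"no column found for {key!r}; header is {list(columns)} "
                f"(accepted synonyms: {COLUMN_SYNONYMS[key]})"
            )
    resolved["feature_id"] = None
    if column_map and "feature_id" in column_map:
        name = column_map["feature_id"]
        if name not in columns:
            raise ConfigurationError(f"mapped id column {name!r} not found")
        resolved["feature_id"] = name
    else:
        for syn in COLUMN_SYNONYMS["feature_id"]:
            if syn in lower:
                resolved["feature_id"] = lower[syn]
                break
    return resolved


def read_feature_table(
    path: str,
    column_map: Optional[Mapping[str, str]] = None,
    delimiter: Optional[str] = None,
    rt_unit: str = "min",
    name: Optional[str] = None,
    acquisition_index: int = 0,
) -> Run:
    """Read one feature table (CSV or TSV) into a :class:`Run`.

    Parameters
    ----------
    column_map
        Optional explicit mapping ``{"mz": ..., "rt": ..., "area": ...}``;
        otherwise headers are matched case-insensitively against synonyms.
    delimiter
        ``None`` infers from the file extension (``.tsv`` -> tab, else comma).
    rt_unit
        ``"min"`` (default) or ``"seconds"`` (divided by 60 on read).

    Rows with non-finite or invariant-violating values (mz<=0, rt<0, area<0)
    are rejected; the rejected count is logged.
    """
    if rt_unit not in ("min", "seconds"):
        raise ConfigurationError(f"rt_unit must be 'min' or 'seconds', got {rt_unit!r}")
    if delimiter is None:
        delimiter = "\t" if path.lower().endswith((".tsv", ".txt")) else ","
    try:
        df = pd.read_csv(path, sep=delimiter)
    except pd.errors.EmptyDataError:
        raise DataError(f"empty feature table: {path}")
    if df.empty:
        raise DataError(f"feature table has no rows: {path}")
    cols = _resolve_columns(df.columns, column_map)
    run_name = name if name is not None else os.path.splitext(os.path.basename(path))[0]
    scale = 1.0 / 60.0 if rt_unit == "seconds" else 1.0

    features: list[Feature] = []
    n_rejected = 0
    id_col = cols["feature_id"]
    for i, row in enumerate(df.itertuples(index=False)):
        rec = dict(zip(df.columns, row))
        try:
            mz = float(rec[cols["mz"]])
            rt = float(rec[cols["rt"]]) * scale
            area = float(rec[cols["area"]])
        except (TypeError, ValueError):
            n_rejected += 1
            continue
        if not (math.isfinite(mz) and math.isfinite(rt) and math.isfinite(area)):
            n_rejected += 1
            continue
        if not (mz > 0 and rt >= 0 and area >= 0):
            n_rejected += 1
            continue
        fid = str(rec[id_col]) if id_col is not None else f"f{i:05d}"
        features.append(Feature(mz=mz, rt=rt, area=area, feature_id=fid))
    if n_rejected:
        log.warning("%s: rejected %d unparseable/non-finite rows", path, n_rejected)
    if not features:
        raise DataError(f"no valid feature rows in {path}")
    return Run(name=run_name, acquisition_index=acquisition_index, features=features)


def deduplicate_run(run: Run) -> Run:
    """Collapse exact duplicate (mz, rt, area) triples, keeping first occurrence."""
    seen: set[tuple[float, float, float]] = set()
    kept: list[Feature] = []
    for f in run.features:
        key = (f.mz, f.rt, f.area)
        if key in seen:
            continue
        seen.add(key)
        kept.append(f)
    if len(kept) != len(run.features):
        log.info("run %s: removed %d duplicate features", run.name, len(run.features) - len(kept))
    return Run(name=run.name, acquisition_index=run.acquisition_index, features=kept)


def write_consensus_table(rows: Sequence[ConsensusRow], runs: Sequence[Run], path: str) -> None:
    """Write consensus rows as a wide CSV: mz, rt, then per-run id/area columns.

    Rows are sorted by (consensus m/z, consensus RT); absent slots are empty
    cells. Raises :class:`IntegrityError` on a feature id not present in its run.
    """
    known = {run.name: {f.feature_id for f in run.features} for run in runs}
    records = []
    for row in sorted(rows, key=lambda r: (r.consensus_mz, r.consensus_rt)):
        if not any(v is not None for v in row.entries.values()):
            raise IntegrityError("consensus row with no non-absent slot")
        rec: dict[str, object] = {
            "consensus_mz": row.consensus_mz,
            "consensus_rt": row.consensus_rt,
        }
        for run in runs:
            entry = row.entries.get(run.name)
            if entry is None:
                rec[f"id_{run.name}"] = ""
                rec[f"area_{run.name}"] = ""
            else:
                fid, area = entry
                if fid not in known[run.name]:
                    raise IntegrityError(f"dangling feature id {fid!r} for run {run.name}")
                rec[f"id_{run.name}"] = fid
                rec[f"area_{run.name}"] = area
        records.append(rec)
    columns = ["consensus_mz", "consensus_rt"]
    for run in runs:
        columns += [f"id_{run.name}", f"area_{run.name}"]
    pd.DataFrame.from_records(records, columns=columns).to_csv(path, index=False)


def read_consensus_table(path: str) -> tuple[list[ConsensusRow], list[str]]:
    """Read back a consensus CSV written by :func:`write_consensus_table`."""
    df = pd.read_csv(path)
    run_names = [c[len("id_"):] for c in df.columns if c.startswith("id_")]
    rows: list[ConsensusRow] = []
    for _, rec in df.iterrows():
        entries: dict[str, Optional[tuple[str, float]]] = {}
        for rn in run_names:
            fid = rec[f"id_{rn}"]
            if pd.isna(fid) or fid == "":
                entries[rn] = None
            else:
                entries[rn] = (str(fid), float(rec[f"area_{rn}"]))
        rows.append(
            ConsensusRow(
                consensus_mz=float(rec["consensus_mz"]),
                consensus_rt=float(rec["consensus_rt"]),
                entries=entries,
            )
        )
    return rows, run_names


def warp_feature(feature: Feature, rt: float) -> Feature:
    """Return a copy of ``feature`` with a new (warped) retention time."""
    original = feature.rt_original if feature.rt_original is not None else feature.rt
    return replace(feature, rt=rt, rt_original=original)
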