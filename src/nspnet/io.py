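"""Delimited-text I/O for every table the pipeline reads or writes.

All formats are plain TSV with headers: time series (first row = region
ids, one row per frame), square FC matrices (region ids as header row and
index column), atlas maps, clinical records and region x gene expression
tables. Region ids are cross-checked between inputs on load.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import AtlasMap
from .fc import FCMatrix, RegionalTimeSeries
from .stats import SANS_DIMENSIONS, SAPS_DIMENSIONS, SubjectRecord

SEP = "\t"


def save_timeseries(ts: RegionalTimeSeries, path: str | Path) -> None:
    pd.DataFrame(ts.values, columns=list(ts.region_ids)).to_csv(
        path, sep=SEP, index=False
    )


def load_timeseries(
    path: str | Path, tr_seconds: float = 2.0, subject_id: str | None = None
) -> RegionalTimeSeries:
    df = pd.read_csv(path, sep=SEP)
    if df.isna().any().any():
        raise ValueError(f"{path}: missing values in time-series table")
    return RegionalTimeSeries(
        df.to_numpy(dtype=float),
        tr_seconds=tr_seconds,
        subject_id=subject_id or Path(path).stem,
        region_ids=tuple(df.columns),
    )


def save_fc(fc: FCMatrix, path: str | Path) -> None:
    ids = list(fc.region_ids)
    pd.DataFrame(fc.C, index=ids, columns=ids).to_csv(path, sep=SEP)


def load_fc(path: str | Path) -> FCMatrix:
    df = pd.read_csv(path, sep=SEP, index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: FC row/column region ids differ")
    return FCMatrix(df.to_numpy(dtype=float), region_ids=tuple(df.columns))


def save_atlas(atlas: AtlasMap, path: str | Path) -> None:
    atlas.to_frame().to_csv(path, sep=SEP, index=False)


def load_atlas(path: str | Path) -> AtlasMap:
    return AtlasMap.from_frame(pd.read_csv(path, sep=SEP))


def save_clinical(records: list[SubjectRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        row: dict = {
            "subject": r.subject_id, "group": r.group, "sex": r.sex,
            "age": r.age, "fd": r.fd,
        }
        for d in SANS_DIMENSIONS:
            row[f"sans_{d}"] = (r.sans or {}).get(d, "")
        for d in SAPS_DIMENSIONS:
            row[f"saps_{d}"] = (r.saps or {}).get(d, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=SEP, index=False)


def load_clinical(path: str | Path) -> list[SubjectRecord]:
    df = pd.read_csv(path, sep=SEP)
    required = {"subject", "group", "sex", "age", "fd"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    records = []
    for _, row in df.iterrows():
        sans = {
            d: float(row[f"sans_{d}"])
            for d in SANS_DIMENSIONS
            if f"sans_{d}" in df.columns and pd.notna(row[f"sans_{d}"])
        }
        saps = {
            d: float(row[f"saps_{d}"])
            for d in SAPS_DIMENSIONS
            if f"saps_{d}" in df.columns and pd.notna(row[f"saps_{d}"])
        }
        records.append(
            SubjectRecord(
                subject_id=str(row["subject"]), group=str(row["group"]),
                sex=int(row["sex"]), age=float(row["age"]), fd=float(row["fd"]),
                sans=sans or None, saps=saps or None,
            )
        )
    return records


def save_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep=SEP, index_label="region")


def load_expression(path: str | Path, atlas: AtlasMap | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep=SEP, index_col="region")
    if atlas is not None and list(df.index) != list(atlas.region_ids):
        raise ValueError(f"{path}: expression regions do not match atlas")
    return df


def check_regions(ts: RegionalTimeSeries, atlas: AtlasMap) -> None:
    if tuple(ts.region_ids) != tuple(atlas.region_ids):
        extra = set(ts.region_ids) - set(atlas.region_ids)
        missing = set(atlas.region_ids) - set(ts.region_ids)
        raise ValueError(
            f"region mismatch between series and atlas: "
            f"extra={sorted(extra)[:5]} missing={sorted(missing)[:5]}"
        )
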