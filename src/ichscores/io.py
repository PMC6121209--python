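"""Cohort CSV reading and writing.

The cohort interchange format is a flat CSV with one header row and the
columns::

    age,sex,gcs,mrs,temperature,sbp,dbp,location,ivh,sah,
    diam_a,diam_b,slice_extent_c,volume_cm3,dead_30d

Booleans are 0/1, location is ``supra``/``infra``, and optional fields are
left empty.  Parsing is delegated to pandas; this module only maps rows to
validated :class:`~ichscores.score_models.PatientRecord` objects and back.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence, Union

import pandas as pd
from pydantic import ValidationError

from .score_models import CohortScoringError, PatientRecord

COHORT_COLUMNS = [
    "age",
    "sex",
    "gcs",
    "mrs",
    "temperature",
    "sbp",
    "dbp",
    "location",
    "ivh",
    "sah",
    "diam_a",
    "diam_b",
    "slice_extent_c",
    "volume_cm3",
    "dead_30d",
]

_INT_FIELDS = {"age", "gcs", "mrs"}
_BOOL_FIELDS = {"ivh", "sah", "dead_30d"}
_FLOAT_FIELDS = {"temperature", "sbp", "dbp", "diam_a", "diam_b", "slice_extent_c", "volume_cm3"}
_LOCATION = {"supra": "supratentorial", "infra": "infratentorial"}
_LOCATION_INV = {v: k for k, v in _LOCATION.items()}


def _is_missing(v) -> bool:
    if v is None:
        return True
    if isinstance(v, float) and math.isnan(v):
        return True
    if isinstance(v, str) and v.strip() == "":
        return True
    return False


def _record_from_row(row: dict) -> PatientRecord:
    kwargs: dict = {}
    for name, v in row.items():
        if name not in COHORT_COLUMNS or _is_missing(v):
            continue
        if name in _INT_FIELDS:
            kwargs[name] = int(v)
        elif name in _BOOL_FIELDS:
            kwargs[name] = bool(int(v))
        elif name in _FLOAT_FIELDS:
            kwargs[name] = float(v)
        elif name == "location":
            kwargs[name] = _LOCATION.get(str(v), str(v))
        elif name == "sex":
            kwargs[name] = str(v)
    return PatientRecord(**kwargs)


def frame_to_records(df: pd.DataFrame) -> list[PatientRecord]:
    """Validate a cohort DataFrame row by row; failures are aggregated
    with their row indices."""
    records: list[PatientRecord] = []
    failures: list[tuple[int, str]] = []
    for i, row in enumerate(df.to_dict(orient="records")):
        try:
            records.append(_record_from_row(row))
        except (ValidationError, ValueError) as exc:
            failures.append((i, str(exc).replace("\n", " ")))
    if failures:
        raise CohortScoringError(failures)
    return records


def read_cohort_csv(path: Union[str, Path]) -> list[PatientRecord]:
    """Read and validate a cohort CSV into PatientRecord objects."""
    df = pd.read_csv(path)
    missing = [c for c in ("gcs", "mrs") if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV is missing required column(s): {missing}")
    return frame_to_records(df)


def records_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Serialize records to the cohort CSV schema."""
    rows = []
    for rec in records:
        row = {}
        for name in COHORT_COLUMNS:
            v = getattr(rec, name)
            if v is None:
                row[name] = None
            elif name in _BOOL_FIELDS:
                row[name] = int(v)
            elif name == "location":
                row[name] = _LOCATION_INV[v]
            else:
                row[name] = v
        rows.append(row)
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def write_cohort_csv(records: Sequence[PatientRecord], path: Union[str, Path]) -> None:
    records_to_frame(records).to_csv(path, index=False)
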