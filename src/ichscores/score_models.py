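"""Admission prognostic scores for primary intracerebral hemorrhage.

Implements the three component-based scores used to stratify 30-day
mortality risk at admission:

* **ICH score** (Hemphill): Glasgow Coma Scale, hematoma volume,
  intraventricular extension, infratentorial origin, and age.
* **New ICH score** (Cheung & Zou): NIHSS severity bin, body temperature,
  pulse pressure, intraventricular and subarachnoid extension.
* **Modified New ICH score**: the New ICH score with the NIHSS bin replaced
  by a Modified Rankin Scale (MRS) bin, so it can be computed from a rapid
  bedside disability assessment instead of the full NIHSS examination.

Hematoma volume is estimated from CT diameters with the ABC/2 ellipsoid
approximation.  Point allocations live in :class:`ScoreDefinition` objects
(data, not code) so alternative allocations can be loaded from JSON.
"""

from __future__ import annotations

import json
import logging
import math
from typing import Literal, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

logger = logging.getLogger(__name__)

__all__ = [
    "DomainError",
    "CohortScoringError",
    "PatientRecord",
    "Bin",
    "ScoreComponent",
    "ScoreDefinition",
    "default_ich_definition",
    "default_new_ich_definition",
    "default_modified_new_ich_definition",
    "abc2_volume",
    "pulse_pressure",
    "mrs_bin_points",
    "nihss_bin_points",
    "ich_score",
    "new_ich_score",
    "modified_new_ich_score",
    "hematoma_volume",
    "score_cohort",
]

# Thresholds the source report of the New ICH score does not restate;
# shipped as explicit assumptions, flagged in the definition JSON.
ASSUMED_TEMPERATURE_THRESHOLD_C = 37.5
ASSUMED_PULSE_PRESSURE_THRESHOLD_MMHG = 85.0


class DomainError(ValueError):
    """An argument lies outside its clinically valid domain."""


class CohortScoringError(ValueError):
    """One or more cohort rows could not be scored.

    Attributes
    ----------
    failures : list of (row_index, message)
    """

    def __init__(self, failures: list[tuple[int, str]]):
        self.failures = failures
        lines = "; ".join(f"row {i}: {msg}" for i, msg in failures)
        super().__init__(f"{len(failures)} record(s) failed to score: {lines}")


class PatientRecord(BaseModel):
    """One admission record.

    All clinical fields are optional at construction so partially observed
    cohorts can be loaded; each scoring function checks the presence of the
    components it needs and raises a descriptive error naming any missing
    field.  Invariants (GCS 3-15, MRS 0-5 at admission, sbp > dbp >= 0,
    non-negative diameters) are enforced whenever a value is present.
    """

    model_config = ConfigDict(frozen=True)

    age: Optional[int] = Field(default=None, ge=0)
    sex: Optional[Literal["male", "female"]] = None
    gcs: Optional[int] = None
    mrs: Optional[int] = None
    temperature: Optional[float] = None  # °C
    sbp: Optional[float] = None  # mmHg
    dbp: Optional[float] = None  # mmHg
    location: Optional[Literal["supratentorial", "infratentorial"]] = None
    ivh: Optional[bool] = None
    sah: Optional[bool] = None
    diam_a: Optional[float] = Field(default=None, ge=0)  # cm
    diam_b: Optional[float] = Field(default=None, ge=0)  # cm
    slice_extent_c: Optional[float] = Field(default=None, ge=0)  # cm
    volume_cm3: Optional[float] = Field(default=None, ge=0)
    dead_30d: Optional[bool] = None

    @model_validator(mode="after")
    def _check_invariants(self) -> "PatientRecord":
        if self.gcs is not None and not 3 <= self.gcs <= 15:
            raise ValueError(f"gcs must lie in 3..15, got {self.gcs}")
        if self.mrs is not None and not 0 <= self.mrs <= 5:
            raise ValueError(
                f"mrs must lie in 0..5 at admission (6 denotes death), got {self.mrs}"
            )
        if self.dbp is not None and self.dbp < 0:
            raise ValueError(f"dbp must be >= 0, got {self.dbp}")
        if self.sbp is not None and self.dbp is not None and self.sbp <= self.dbp:
            raise ValueError(
                f"sbp must exceed dbp, got sbp={self.sbp}, dbp={self.dbp}"
            )
        return self

    def require(self, *fields: str) -> None:
        """Raise :class:`DomainError` naming the first missing field."""
        for name in fields:
            if getattr(self, name) is None:
                raise DomainError(f"missing required field for scoring: {name!r}")


class Bin(BaseModel):
    """One half-open-or-closed interval mapped to a point value.

    ``lo``/``hi`` of ``None`` mean unbounded.  Integer fields use inclusive
    integer bounds throughout so no floating-point edges appear in the
    shipped definitions.
    """

    lo: Optional[float] = None
    hi: Optional[float] = None
    points: int = Field(ge=0)
    lo_inclusive: bool = True
    hi_inclusive: bool = True

    def contains(self, x: float) -> bool:
        if self.lo is not None:
            if self.lo_inclusive:
                if x < self.lo:
                    return False
            elif x <= self.lo:
                return False
        if self.hi is not None:
            if self.hi_inclusive:
                if x > self.hi:
                    return False
            elif x >= self.hi:
                return False
        return True


class ScoreComponent(BaseModel):
    """Point allocation for one record field."""

    field: str
    bins: list[Bin]
    assumed: bool = False  # True when the threshold is an assumption, not sourced

    @model_validator(mode="after")
    def _check_bins(self) -> "ScoreComponent":
        if not self.bins:
            raise ValueError(f"component {self.field!r} has no bins")
        for a, b in zip(self.bins, self.bins[1:]):
            if a.hi is None or b.lo is None:
                raise ValueError(
                    f"component {self.field!r}: interior bins must be bounded"
                )
            if a.hi > b.lo or (a.hi == b.lo and a.hi_inclusive and b.lo_inclusive):
                raise ValueError(
                    f"component {self.field!r}: bins overlap at {a.hi}"
                )
        return self

    @property
    def max_points(self) -> int:
        return max(b.points for b in self.bins)

    def points_for(self, value: float) -> int:
        for b in self.bins:
            if b.contains(value):
                return b.points
        raise DomainError(
            f"value {value!r} of {self.field!r} falls outside every bin"
        )


class ScoreDefinition(BaseModel):
    """A named, serializable point-allocation table."""

    name: str
    components: list[ScoreComponent]

    @property
    def max_score(self) -> int:
        return sum(c.max_points for c in self.components)

    def evaluate(self, values: dict[str, float]) -> int:
        """Sum component points for a dict of numeric component values."""
        total = 0
        for comp in self.components:
            if comp.field not in values:
                raise DomainError(
                    f"missing required field for scoring: {comp.field!r}"
                )
            total += comp.points_for(values[comp.field])
        return total

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.model_dump(), **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "ScoreDefinition":
        return cls.model_validate(json.loads(text))


def _flag_bins() -> list[Bin]:
    return [Bin(lo=0, hi=0, points=0), Bin(lo=1, hi=1, points=1)]


def default_ich_definition() -> ScoreDefinition:
    """Hemphill allocation: GCS 3-4 → 2 / 5-12 → 1 / 13-15 → 0; volume
    >= 30 cm³ → 1; IVH → 1; infratentorial → 1; age >= 80 → 1 (max 6)."""
    return ScoreDefinition(
        name="ICH score",
        components=[
            ScoreComponent(
                field="gcs",
                bins=[
                    Bin(lo=3, hi=4, points=2),
                    Bin(lo=5, hi=12, points=1),
                    Bin(lo=13, hi=15, points=0),
                ],
            ),
            ScoreComponent(
                field="volume_cm3",
                bins=[
                    Bin(lo=0, hi=30, points=0, hi_inclusive=False),
                    Bin(lo=30, hi=None, points=1),
                ],
            ),
            ScoreComponent(field="ivh", bins=_flag_bins()),
            ScoreComponent(field="infratentorial", bins=_flag_bins()),
            ScoreComponent(
                field="age",
                bins=[
                    Bin(lo=0, hi=80, points=0, hi_inclusive=False),
                    Bin(lo=80, hi=None, points=1),
                ],
            ),
        ],
    )


def _mrs_component() -> ScoreComponent:
    # MRS 0-2 stands in for NIHSS 0-10, MRS 3-4 for NIHSS 11-20, MRS 5 for
    # NIHSS 21-40.
    return ScoreComponent(
        field="mrs",
        bins=[
            Bin(lo=0, hi=2, points=0),
            Bin(lo=3, hi=4, points=1),
            Bin(lo=5, hi=5, points=2),
        ],
    )


def _nihss_component() -> ScoreComponent:
    return ScoreComponent(
        field="nihss",
        bins=[
            Bin(lo=0, hi=10, points=0),
            Bin(lo=11, hi=20, points=1),
            Bin(lo=21, hi=40, points=2),
        ],
    )


def _vital_components(
    temperature_threshold: float, pulse_pressure_threshold: float
) -> list[ScoreComponent]:
    return [
        ScoreComponent(
            field="temperature",
            assumed=True,
            bins=[
                Bin(lo=None, hi=temperature_threshold, points=0, hi_inclusive=False),
                Bin(lo=temperature_threshold, hi=None, points=1),
            ],
        ),
        ScoreComponent(
            field="pulse_pressure",
            assumed=True,
            bins=[
                Bin(lo=0, hi=pulse_pressure_threshold, points=0, hi_inclusive=False),
                Bin(lo=pulse_pressure_threshold, hi=None, points=1),
            ],
        ),
        ScoreComponent(field="ivh", bins=_flag_bins()),
        ScoreComponent(field="sah", bins=_flag_bins()),
    ]


def default_new_ich_definition(
    temperature_threshold: float = ASSUMED_TEMPERATURE_THRESHOLD_C,
    pulse_pressure_threshold: float = ASSUMED_PULSE_PRESSURE_THRESHOLD_MMHG,
) -> ScoreDefinition:
    """New ICH score: NIHSS bin (0-2 points) plus one point each for
    temperature and pulse pressure above threshold, IVH, and SAH (max 6).

    The vital-sign thresholds are assumptions (``assumed: true`` in the
    serialized form) and every report states the values used.
    """
    return ScoreDefinition(
        name="New ICH score",
        components=[_nihss_component()]
        + _vital_components(temperature_threshold, pulse_pressure_threshold),
    )


def default_modified_new_ich_definition(
    temperature_threshold: float = ASSUMED_TEMPERATURE_THRESHOLD_C,
    pulse_pressure_threshold: float = ASSUMED_PULSE_PRESSURE_THRESHOLD_MMHG,
) -> ScoreDefinition:
    """Modified New ICH score: as the New ICH score with the NIHSS bin
    replaced by the MRS bin (MRS 0-2 → 0, 3-4 → 1, 5 → 2)."""
    return ScoreDefinition(
        name="Modified New ICH score",
        components=[_mrs_component()]
        + _vital_components(temperature_threshold, pulse_pressure_threshold),
    )


def abc2_volume(diam_a: float, diam_b: float, slice_extent_c: float) -> float:
    """Ellipsoid (ABC/2) hematoma volume in cm³.

    ``diam_a`` is the largest hematoma diameter on the reference CT slice,
    ``diam_b`` the diameter perpendicular to it on the same slice, and
    ``slice_extent_c`` the number of slices containing blood multiplied by
    the slice spacing, all in cm.
    """
    for name, v in (
        ("diam_a", diam_a),
        ("diam_b", diam_b),
        ("slice_extent_c", slice_extent_c),
    ):
        if v < 0 or not math.isfinite(v):
            raise DomainError(f"{name} must be finite and >= 0, got {v}")
    return diam_a * diam_b * slice_extent_c / 2.0


def pulse_pressure(sbp: float, dbp: float) -> float:
    """Systolic minus diastolic blood pressure, mmHg."""
    if dbp < 0:
        raise DomainError(f"dbp must be >= 0, got {dbp}")
    if sbp < dbp:
        raise DomainError(f"sbp ({sbp}) must be >= dbp ({dbp})")
    return sbp - dbp


def mrs_bin_points(mrs: int) -> int:
    """MRS severity bin: 0-2 → 0, 3-4 → 1, 5 → 2.

    MRS 6 denotes death and is invalid at admission scoring.
    """
    if not isinstance(mrs, (int,)) or isinstance(mrs, bool):
        raise DomainError(f"mrs must be an integer, got {mrs!r}")
    if not 0 <= mrs <= 5:
        raise DomainError(f"mrs must lie in 0..5, got {mrs}")
    return _mrs_component().points_for(mrs)


def nihss_bin_points(nihss: int) -> int:
    """NIHSS severity bin: 0-10 → 0, 11-20 → 1, 21-40 → 2."""
    if not isinstance(nihss, (int,)) or isinstance(nihss, bool):
        raise DomainError(f"nihss must be an integer, got {nihss!r}")
    if not 0 <= nihss <= 40:
        raise DomainError(f"nihss must lie in 0..40, got {nihss}")
    return _nihss_component().points_for(nihss)


def hematoma_volume(rec: PatientRecord) -> float:
    """Resolve the hematoma volume of a record in cm³.

    A directly measured ``volume_cm3`` takes precedence; otherwise the
    ABC/2 estimate is computed from the three diameters.  If both are
    present the measured volume wins and a warning is logged.
    """
    has_diams = (
        rec.diam_a is not None
        and rec.diam_b is not None
        and rec.slice_extent_c is not None
    )
    if rec.volume_cm3 is not None:
        if has_diams:
            logger.warning(
                "both volume_cm3 and diameters given; using volume_cm3=%s",
                rec.volume_cm3,
            )
        return rec.volume_cm3
    if has_diams:
        return abc2_volume(rec.diam_a, rec.diam_b, rec.slice_extent_c)
    raise DomainError(
        "missing required field for scoring: 'volume_cm3' or all of "
        "('diam_a', 'diam_b', 'slice_extent_c')"
    )


def ich_score(rec: PatientRecord, defn: Optional[ScoreDefinition] = None) -> int:
    """ICH score (0-6 under the default definition)."""
    defn = defn or default_ich_definition()
    rec.require("gcs", "ivh", "location", "age")
    values = {
        "gcs": rec.gcs,
        "volume_cm3": hematoma_volume(rec),
        "ivh": int(rec.ivh),
        "infratentorial": int(rec.location == "infratentorial"),
        "age": rec.age,
    }
    return defn.evaluate(values)


def modified_new_ich_score(
    rec: PatientRecord, defn: Optional[ScoreDefinition] = None
) -> int:
    """Modified New ICH score (0-6 under the default definition)."""
    defn = defn or default_modified_new_ich_definition()
    rec.require("mrs", "temperature", "sbp", "dbp", "ivh", "sah")
    values = {
        "mrs": rec.mrs,
        "temperature": rec.temperature,
        "pulse_pressure": pulse_pressure(rec.sbp, rec.dbp),
        "ivh": int(rec.ivh),
        "sah": int(rec.sah),
    }
    return defn.evaluate(values)


def new_ich_score(
    rec: PatientRecord, nihss: int, defn: Optional[ScoreDefinition] = None
) -> int:
    """New ICH score (0-6), taking the NIHSS separately since admission
    records in this cohort schema do not carry it."""
    defn = defn or default_new_ich_definition()
    if not 0 <= nihss <= 40:
        raise DomainError(f"nihss must lie in 0..40, got {nihss}")
    rec.require("temperature", "sbp", "dbp", "ivh", "sah")
    values = {
        "nihss": nihss,
        "temperature": rec.temperature,
        "pulse_pressure": pulse_pressure(rec.sbp, rec.dbp),
        "ivh": int(rec.ivh),
        "sah": int(rec.sah),
    }
    return defn.evaluate(values)


def score_cohort(
    records: Sequence[PatientRecord],
    ich_defn: Optional[ScoreDefinition] = None,
    modified_defn: Optional[ScoreDefinition] = None,
) -> pd.DataFrame:
    """Score every record; one row per patient.

    Returns a DataFrame with ``ich_score`` and ``modified_new_ich_score``
    columns (plus ``dead_30d`` where present).  Per-record failures are
    aggregated into a single :class:`CohortScoringError` carrying row
    indices, so a malformed cohort reports every bad row at once.
    """
    rows: list[dict] = []
    failures: list[tuple[int, str]] = []
    for i, rec in enumerate(records):
        try:
            rows.append(
                {
                    "ich_score": ich_score(rec, ich_defn),
                    "modified_new_ich_score": modified_new_ich_score(
                        rec, modified_defn
                    ),
                    "dead_30d": rec.dead_30d,
                }
            )
        except (DomainError, ValueError) as exc:
            failures.append((i, str(exc)))
    if failures:
        raise CohortScoringError(failures)
    return pd.DataFrame(
        rows, columns=["ich_score", "modified_new_ich_score", "dead_30d"]
    )
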