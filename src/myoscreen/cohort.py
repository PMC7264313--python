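"""Subject-level data model, CSV I/O and raw-measurement reduction.

A cohort is a collection of :class:`SubjectRecord`, one per participant,
holding anthropometrics (sex, age, height, forearm circumference), the raw
exercise performances (handgrip maximal voluntary contraction force in
decanewtons, maximal cycling power in watts, optionally peak oxygen uptake)
and a diagnostic group label.  The on-disk format is a plain UTF-8 CSV with
a fixed header (see :data:`CSV_COLUMNS`); heights may be recorded in
centimeters with a dialect flag.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Group",
    "Sex",
    "SubjectRecord",
    "RowDiagnostic",
    "CohortReadResult",
    "CSV_COLUMNS",
    "METABOLIC_GROUPS",
    "read_cohort",
    "write_cohort",
    "to_dataframe",
    "select_mvc",
]


class Group(str, Enum):
    """Diagnostic group label."""

    CONTROL = "control"
    NON_METABOLIC_MYALGIA = "non_metabolic_myalgia"
    MAD_ABSENT = "mad_absent"
    MCARDLE = "mcardle"
    RESPIRATORY_CHAIN = "respiratory_chain"


#: The three inborn-error groups pooled as "metabolic myopathy" downstream.
METABOLIC_GROUPS = (Group.MAD_ABSENT, Group.MCARDLE, Group.RESPIRATORY_CHAIN)


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


#: Exact CSV header contract, in order.
CSV_COLUMNS = [
    "subject_id",
    "group",
    "sex",
    "age_yr",
    "height_m",
    "bmi",
    "forearm_circumference_cm",
    "mvc_trial1_dan",
    "mvc_trial2_dan",
    "mvc_trial3_dan",
    "mvc_dan",
    "mp_watt",
    "peak_vo2_ml_min_kg",
]


class CohortError(ValueError):
    """Raised for file-level format problems (e.g. a missing column)."""


@dataclass(frozen=True)
class SubjectRecord:
    """One participant: anthropometrics, raw performances and group label.

    Units: age in years, height in meters, forearm circumference in cm,
    MVC in DaN (1 DaN = 10 N), maximal power in watts, peak V'O2 in
    mL·min⁻¹·kg⁻¹.  ``mvc`` must equal ``max(mvc_trials)`` when the
    individual trials are recorded.
    """

    subject_id: str
    group: Group
    sex: Sex
    age: float
    height: float
    forearm_circumference: float
    mvc: float
    mp: float
    bmi: float | None = None
    mvc_trials: tuple[float, ...] | None = None
    peak_vo2: float | None = None

    def __post_init__(self) -> None:
        if not self.age > 0:
            raise ValueError(f"age must be positive, got {self.age}")
        if not 1.0 <= self.height <= 2.3:
            raise ValueError(
                f"height {self.height} m outside plausible range [1.0, 2.3] "
                "(was it recorded in cm?)"
            )
        if not self.forearm_circumference > 0:
            raise ValueError(
                f"forearm_circumference must be positive, got {self.forearm_circumference}"
            )
        if not self.mvc > 0:
            raise ValueError(f"mvc must be positive, got {self.mvc}")
        if not self.mp > 0:
            raise ValueError(f"mp must be positive, got {self.mp}")
        if self.mvc_trials is not None:
            if not 1 <= len(self.mvc_trials) <= 3:
                raise ValueError("mvc_trials must hold 1-3 values")
            if any(t <= 0 for t in self.mvc_trials):
                raise ValueError("all mvc trials must be positive")
            if not math.isclose(self.mvc, max(self.mvc_trials), rel_tol=1e-9):
                raise ValueError(
                    f"mvc ({self.mvc}) must equal the maximum trial "
                    f"({max(self.mvc_trials)})"
                )


@dataclass(frozen=True)
class RowDiagnostic:
    """Why a CSV data row was rejected (``row`` is the 0-based data-row index)."""

    row: int
    message: str


@dataclass
class CohortReadResult:
    records: list[SubjectRecord] = field(default_factory=list)
    rejected: list[RowDiagnostic] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def select_mvc(trials: Sequence[float]) -> tuple[float, float]:
    """Reduce 1-3 grip trials to (MVC, within-subject CV).

    MVC is the maximum of the trials; the coefficient of variation is the
    sample standard deviation (n−1 denominator) divided by the mean, 0.0 for
    a single trial.
    """
    trials = tuple(trials)
    if not trials:
        raise ValueError("select_mvc requires at least one trial")
    if any(t <= 0 for t in trials):
        raise ValueError("all trials must be positive forces")
    mvc = max(trials)
    if len(trials) == 1:
        return mvc, 0.0
    cv = statistics.stdev(trials) / statistics.mean(trials)
    return mvc, cv


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and value.strip() == "":
        return None
    return float(value)


def _row_to_record(row: pd.Series, *, height_in_cm: bool) -> SubjectRecord:
    height = float(row["height_m"])
    if height_in_cm:
        height /= 100.0
    trials = [
        _opt_float(row[c])
        for c in ("mvc_trial1_dan", "mvc_trial2_dan", "mvc_trial3_dan")
    ]
    trials = tuple(t for t in trials if t is not None) or None
    return SubjectRecord(
        subject_id=str(row["subject_id"]),
        group=Group(str(row["group"])),
        sex=Sex(str(row["sex"])),
        age=float(row["age_yr"]),
        height=height,
        forearm_circumference=float(row["forearm_circumference_cm"]),
        mvc=float(row["mvc_dan"]),
        mp=float(row["mp_watt"]),
        bmi=_opt_float(row["bmi"]),
        mvc_trials=trials,
        peak_vo2=_opt_float(row["peak_vo2_ml_min_kg"]),
    )


def read_cohort(path: str | Path, *, height_in_cm: bool = False) -> CohortReadResult:
    """Read a cohort CSV, validating each row.

    Rows violating a record invariant (or with non-numeric cells) are not
    fatal: they are collected in ``result.rejected`` with a row-indexed
    diagnostic.  A missing mandatory column is fatal (:class:`CohortError`).
    With ``height_in_cm`` the height column is interpreted as centimeters
    and converted to meters.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise CohortError(f"missing mandatory column(s): {', '.join(missing)}")
    result = CohortReadResult()
    for i, (_, row) in enumerate(frame.iterrows()):
        try:
            result.records.append(_row_to_record(row, height_in_cm=height_in_cm))
        except (ValueError, KeyError) as exc:
            result.rejected.append(RowDiagnostic(row=i, message=str(exc)))
    return result


def to_dataframe(records: Iterable[SubjectRecord]) -> pd.DataFrame:
    """Records → DataFrame in the CSV column contract (None → empty cell)."""
    rows = []
    for r in records:
        trials = list(r.mvc_trials) if r.mvc_trials else []
        trials += [None] * (3 - len(trials))
        rows.append(
            {
                "subject_id": r.subject_id,
                "group": r.group.value,
                "sex": r.sex.value,
                "age_yr": r.age,
                "height_m": r.height,
                "bmi": r.bmi,
                "forearm_circumference_cm": r.forearm_circumference,
                "mvc_trial1_dan": trials[0],
                "mvc_trial2_dan": trials[1],
                "mvc_trial3_dan": trials[2],
                "mvc_dan": r.mvc,
                "mp_watt": r.mp,
                "peak_vo2_ml_min_kg": r.peak_vo2,
            }
        )
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def write_cohort(records: Iterable[SubjectRecord], path: str | Path) -> None:
    """Write records as cohort CSV (inverse of :func:`read_cohort`).

    Floats are written with ``repr`` precision so a read→write→read
    round-trip is bit-exact on every field.
    """
    to_dataframe(records).to_csv(path, index=False)
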