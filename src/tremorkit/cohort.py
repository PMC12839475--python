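"""Descriptive cohort summaries.

Summarises a clinical cohort table (one row per patient: age, sex, weight,
disease duration, standing tremor frequency, medication) into per-column
count, mean, sample standard deviation (n-1 denominator), minimum and
maximum.  A bundled reference table holds the published characteristics of a
seven-patient primary-orthostatic-tremor cohort and serves as a worked
example and regression anchor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence
import warnings

import numpy as np
import pandas as pd

from .exceptions import DataError, FormatError

__all__ = [
    "PatientRecord",
    "ColumnSummary",
    "CohortSummary",
    "read_cohort",
    "reference_cohort",
    "summarize_cohort",
    "format_summary",
]

#: Frequency band defining primary orthostatic tremor.
POT_BAND_HZ = (13.0, 18.0)

#: Numeric cohort columns and the decimal places used when formatting to the
#: conventional printed precision.
NUMERIC_COLUMNS = {
    "age_years": 1,
    "weight_kg": 1,
    "duration_years": 1,
    "tremor_frequency_hz": 2,
}

COHORT_COLUMNS = [
    "patient",
    "age_years",
    "sex",
    "weight_kg",
    "duration_years",
    "tremor_frequency_hz",
    "medication",
]


@dataclass(frozen=True)
class PatientRecord:
    """One cohort row; the tremor frequency, when known, must lie in the
    13-18 Hz band that defines primary orthostatic tremor."""

    patient: str
    age_years: float
    sex: str
    weight_kg: float
    duration_years: float
    tremor_frequency_hz: Optional[float] = None
    medication: str = ""

    def __post_init__(self) -> None:
        if self.age_years <= 0:
            raise DataError("age_years must be positive")
        if self.sex not in ("M", "F"):
            raise DataError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if self.weight_kg <= 0:
            raise DataError("weight_kg must be positive")
        if self.duration_years < 0:
            raise DataError("duration_years must be non-negative")
        f = self.tremor_frequency_hz
        if f is not None and not (POT_BAND_HZ[0] <= f <= POT_BAND_HZ[1]):
            raise DataError(
                f"tremor_frequency_hz {f} outside the POT band {POT_BAND_HZ}"
            )


@dataclass(frozen=True)
class ColumnSummary:
    n: int
    mean: float
    sd: Optional[float]  # None when n == 1
    min: float
    max: float


@dataclass(frozen=True)
class CohortSummary:
    columns: dict[str, ColumnSummary]

    def to_dict(self) -> dict:
        return {
            name: {"n": c.n, "mean": c.mean, "sd": c.sd, "min": c.min, "max": c.max}
            for name, c in self.columns.items()
        }


def read_cohort(path: str | Path) -> list[PatientRecord]:
    """Read a tab-separated cohort table into patient records."""
    df = pd.read_csv(path, sep="\t")
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"cohort table missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        freq = row["tremor_frequency_hz"]
        records.append(
            PatientRecord(
                patient=str(row["patient"]),
                age_years=float(row["age_years"]),
                sex=str(row["sex"]),
                weight_kg=float(row["weight_kg"]),
                duration_years=float(row["duration_years"]),
                tremor_frequency_hz=None if pd.isna(freq) else float(freq),
                medication="" if pd.isna(row["medication"]) else str(row["medication"]),
            )
        )
    return records


def reference_cohort() -> list[PatientRecord]:
    """The bundled seven-patient POT reference cohort."""
    with resources.as_file(
        resources.files("tremorkit.data") / "reference_cohort.tsv"
    ) as p:
        return read_cohort(p)


def summarize_cohort(records: Sequence[PatientRecord]) -> CohortSummary:
    """Per-column n, mean, sample SD (n-1), min and max.

    Missing values are excluded pairwise per column.  A column with a single
    observation reports its value with SD absent; an empty column is skipped
    with a warning.
    """
    if not records:
        raise DataError("empty cohort")
    columns: dict[str, ColumnSummary] = {}
    for name in NUMERIC_COLUMNS:
        values = np.array(
            [
                getattr(r, name)
                for r in records
                if getattr(r, name) is not None
                and not math.isnan(getattr(r, name))
            ],
            dtype=float,
        )
        values.sort()  # fixed summation order => exact permutation invariance
        n = values.size
        if n == 0:
            warnings.warn(f"column {name!r} has no observations; skipped", stacklevel=2)
            continue
        columns[name] = ColumnSummary(
            n=n,
            mean=float(values.mean()),
            sd=float(values.std(ddof=1)) if n > 1 else None,
            min=float(values.min()),
            max=float(values.max()),
        )
    return CohortSummary(columns=columns)


def format_summary(summary: CohortSummary) -> dict[str, dict[str, object]]:
    """Round a summary to the conventional printed precision
    (1 decimal for age/weight/duration, 2 for frequency)."""
    out: dict[str, dict[str, object]] = {}
    for name, col in summary.columns.items():
        nd = NUMERIC_COLUMNS.get(name, 2)
        out[name] = {
            "n": col.n,
            "mean": round(col.mean, nd),
            "sd": None if col.sd is None else round(col.sd, nd),
            "min": round(col.min, nd),
            "max": round(col.max, nd),
        }
    return out
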