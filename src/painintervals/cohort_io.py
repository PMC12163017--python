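"""Interval-valued pain cohort data model and CSV I/O.

Patients report pain intensity on a bounded numerical pain scale (NPS,
0-10 by default) either as a single value or as an uncertainty interval
``[lower, upper]``.  A point estimate is encoded as a degenerate interval
with ``lower == upper``, so the traditional assessment is the zero-width
special case of the same data model.

A cohort pairs one pre-intervention and one post-intervention interval
per patient.  On disk a cohort is a plain CSV table with the columns

    patient_id, pre_lower, pre_upper, post_lower, post_upper

comma-separated, decimal point, UTF-8, header required.  Reversed bounds
are rejected rather than silently swapped: in a clinical instrument a
reversed interval is a data-entry fault that must surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "PainInterval",
    "PatientRecord",
    "Cohort",
    "CohortFormatError",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "REQUIRED_COLUMNS",
]

REQUIRED_COLUMNS = ("patient_id", "pre_lower", "pre_upper", "post_lower", "post_upper")


class CohortFormatError(ValueError):
    """The on-disk table does not conform to the cohort CSV dialect."""


class CohortValidationError(ValueError):
    """One or more records violate the interval or cohort invariants."""


@dataclass(frozen=True)
class PainInterval:
    """One patient's stated pain-intensity uncertainty interval.

    ``lower == upper`` denotes a traditional point estimate.  Bounds are
    validated against the scale by the owning :class:`Cohort`.
    """

    lower: float
    upper: float

    @property
    def width(self) -> float:
        return self.upper - self.lower

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lower + self.upper)

    @property
    def is_point(self) -> bool:
        return self.lower == self.upper

    def violations(self, scale_min: float, scale_max: float) -> list[str]:
        """Human-readable invariant violations, empty when valid."""
        problems = []
        if not (np.isfinite(self.lower) and np.isfinite(self.upper)):
            problems.append(f"non-finite bounds [{self.lower}, {self.upper}]")
            return problems
        if self.lower > self.upper:
            problems.append(f"lower bound {self.lower} exceeds upper bound {self.upper}")
        if self.lower < scale_min or self.upper > scale_max:
            problems.append(
                f"bounds [{self.lower}, {self.upper}] outside scale "
                f"[{scale_min}, {scale_max}]"
            )
        return problems


@dataclass(frozen=True)
class PatientRecord:
    """Paired pre/post intervals for one patient; the unit of resampling."""

    patient_id: str
    pre: PainInterval
    post: PainInterval


@dataclass(frozen=True)
class Cohort:
    """An ordered, validated collection of patient records on one scale.

    Validation is total: construction either succeeds with every record
    checked or raises :class:`CohortValidationError` listing every
    offending patient_id — no partially valid cohort is ever returned.
    """

    records: tuple[PatientRecord, ...]
    scale_min: float = 0.0
    scale_max: float = 10.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        if self.scale_min >= self.scale_max:
            raise CohortValidationError(
                f"scale_min ({self.scale_min}) must be < scale_max ({self.scale_max})"
            )
        if len(self.records) == 0:
            raise CohortValidationError("a cohort requires at least one patient record")
        problems: list[str] = []
        seen: set[str] = set()
        for rec in self.records:
            if rec.patient_id in seen:
                problems.append(f"{rec.patient_id}: duplicate patient_id")
            seen.add(rec.patient_id)
            for phase, interval in (("pre", rec.pre), ("post", rec.post)):
                for msg in interval.violations(self.scale_min, self.scale_max):
                    problems.append(f"{rec.patient_id}: {phase} interval {msg}")
        if problems:
            raise CohortValidationError("; ".join(problems))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    @property
    def patient_ids(self) -> tuple[str, ...]:
        return tuple(r.patient_id for r in self.records)

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(pre_lower, pre_upper, post_lower, post_upper) as float arrays."""
        pre_lo = np.array([r.pre.lower for r in self.records], dtype=float)
        pre_hi = np.array([r.pre.upper for r in self.records], dtype=float)
        post_lo = np.array([r.post.lower for r in self.records], dtype=float)
        post_hi = np.array([r.post.upper for r in self.records], dtype=float)
        return pre_lo, pre_hi, post_lo, post_hi

    @property
    def pre_midpoints(self) -> np.ndarray:
        return np.array([r.pre.midpoint for r in self.records], dtype=float)

    @property
    def post_midpoints(self) -> np.ndarray:
        return np.array([r.post.midpoint for r in self.records], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": [r.patient_id for r in self.records],
                "pre_lower": [r.pre.lower for r in self.records],
                "pre_upper": [r.pre.upper for r in self.records],
                "post_lower": [r.post.lower for r in self.records],
                "post_upper": [r.post.upper for r in self.records],
            }
        )

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, scale_min: float = 0.0, scale_max: float = 10.0
    ) -> "Cohort":
        missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise CohortFormatError(f"missing required column(s): {', '.join(missing)}")
        records = []
        for row in frame.itertuples(index=False):
            try:
                pre = PainInterval(float(row.pre_lower), float(row.pre_upper))
                post = PainInterval(float(row.post_lower), float(row.post_upper))
            except (TypeError, ValueError) as exc:
                raise CohortFormatError(
                    f"{row.patient_id}: non-numeric interval bound ({exc})"
                ) from exc
            records.append(PatientRecord(str(row.patient_id), pre, post))
        return cls(tuple(records), scale_min=scale_min, scale_max=scale_max)


def read_cohort(
    path: str | Path, scale_min: float = 0.0, scale_max: float = 10.0
) -> Cohort:
    """Read and validate a cohort CSV; row order is preserved."""
    # round_trip parsing so write_cohort -> read_cohort is bit-exact
    frame = pd.read_csv(path, float_precision="round_trip")
    return Cohort.from_frame(frame, scale_min=scale_min, scale_max=scale_max)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort as CSV with full float precision (round-trip exact)."""
    frame = cohort.to_frame()
    # repr-precision floats so read_cohort(write_cohort(c)) == c exactly
    frame.to_csv(path, index=False, float_format=None)
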