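"""Domain types and I/O for longitudinal quantitative sputum cytometry records.

A cohort is a collection of :class:`PatientSeries`, each a time-ordered list
of :class:`SputumSample` examinations.  Samples carry the standard
quantitative cytometry read-out (total cell count, viability, squamous
contamination, five-part differential) plus the semi-quantitative free
eosinophil granule (FEG) observation and the corticosteroid doses at the
time of sampling.  FEGs — extracellular granule clumps left by eosinophil
cytolysis — are enumerated per 400x field of view and graded on the ordinal
scale none < few < moderate < many; they provide evidence of eosinophilic
activity even when the cytospin is too degenerated for an intact cell
differential.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import enum
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd

__all__ = [
    "FegGrade",
    "ClinicalState",
    "SputumSample",
    "PatientSeries",
    "Cohort",
    "ThresholdSpec",
    "ABNORMAL_1_2",
    "CLINICAL_2_3",
    "DEFAULT_THRESHOLDS",
    "ValidationError",
    "grade_feg",
    "read_cohort",
    "write_cohort",
    "split_by_multiplicity",
    "summarize_cohort",
    "COHORT_COLUMNS",
    "PERCENT_SUM_TOL",
]

#: rounding tolerance on the five-part differential summing to 100
PERCENT_SUM_TOL = 0.5


class ValidationError(ValueError):
    """A record or configuration value violates a domain invariant."""


class FegGrade(enum.IntEnum):
    """Ordinal grade of free eosinophil granule clumps per 400x field."""

    NONE = 0
    FEW = 1
    MODERATE = 2
    MANY = 3

    def __str__(self) -> str:  # CSV token
        return self.name.lower()

    @classmethod
    def from_string(cls, token: str) -> "FegGrade":
        try:
            return cls[token.strip().upper()]
        except KeyError:
            raise ValidationError(f"unknown FEG grade {token!r}") from None


class ClinicalState(enum.Enum):
    STABLE = "stable"
    EXACERBATION = "exacerbation"
    UNKNOWN = "unknown"


#: clump-count bins for each grade: (inclusive upper bound, grade).  The
#: published wording overlaps at 2 clumps ("1-2 as few, 2-3 as moderate");
#: the boundary count 2 is resolved to the milder grade, and ">3 as many"
#: is preserved literally, giving none=0, few=1-2, moderate=3, many>=4.
DEFAULT_GRADE_BINS: tuple[tuple[int, FegGrade], ...] = (
    (0, FegGrade.NONE),
    (2, FegGrade.FEW),
    (3, FegGrade.MODERATE),
)


def grade_feg(
    clumps_per_fov: int,
    bins: Sequence[tuple[int, FegGrade]] = DEFAULT_GRADE_BINS,
) -> FegGrade:
    """Map a clump count per 400x field of view to its ordinal FEG grade.

    Parameters
    ----------
    clumps_per_fov
        Non-negative integer count of degranulated eosinophil clumps.
    bins
        Ordered ``(inclusive_upper_bound, grade)`` pairs; counts above the
        last bound receive :attr:`FegGrade.MANY`.

    Returns
    -------
    FegGrade
    """
    if isinstance(clumps_per_fov, bool) or not isinstance(
        clumps_per_fov, (int,)
    ):
        # numpy integers pass through via __index__
        try:
            clumps_per_fov = int(clumps_per_fov.__index__())
        except AttributeError:
            raise ValidationError(
                f"clump count must be an integer, got {clumps_per_fov!r}"
            ) from None
    if clumps_per_fov < 0:
        raise ValidationError("clump count must be non-negative")
    for upper, grade in bins:
        if clumps_per_fov <= upper:
            return grade
    return FegGrade.MANY


def _check_pct(name: str, value: Optional[float]) -> None:
    if value is None:
        return
    if not (0.0 <= value <= 100.0) or math.isnan(value):
        raise ValidationError(f"{name}={value!r} outside [0, 100]")


_DIFFERENTIAL_FIELDS = (
    "neutrophil_pct",
    "eosinophil_pct",
    "macrophage_pct",
    "lymphocyte_pct",
    "bronchial_epithelial_pct",
)


@dataclass(frozen=True)
class SputumSample:
    """One sputum examination for one patient.

    Differential percentages are present only when an intact cell
    differential could be made (``differential_viable``).  FEG evidence may
    be given as a raw clump count, a pre-assigned grade, or both (both must
    agree).  Doses of ``None`` mean *unknown*, not zero; downstream dose
    comparisons involving unknown doses are indeterminate.
    """

    patient_id: str
    exam_date: _dt.date
    differential_viable: bool
    total_cell_count: Optional[float] = None  # 10^6 cells/g
    viability_pct: Optional[float] = None
    squamous_pct: Optional[float] = None
    neutrophil_pct: Optional[float] = None
    eosinophil_pct: Optional[float] = None
    macrophage_pct: Optional[float] = None
    lymphocyte_pct: Optional[float] = None
    bronchial_epithelial_pct: Optional[float] = None
    feg_clumps_per_fov: Optional[int] = None
    feg_grade: Optional[FegGrade] = None
    ics_dose: Optional[float] = None  # ug/day fluticasone-equivalent
    ocs_dose: Optional[float] = None  # mg/day
    clinical_state: ClinicalState = ClinicalState.UNKNOWN
    percent_sum_tol: dataclasses.InitVar[float] = PERCENT_SUM_TOL

    def __post_init__(self, percent_sum_tol: float) -> None:
        if not self.patient_id:
            raise ValidationError("patient_id must be non-empty")
        if self.total_cell_count is not None and self.total_cell_count < 0:
            raise ValidationError("total_cell_count must be non-negative")
        for nm in ("viability_pct", "squamous_pct") + _DIFFERENTIAL_FIELDS:
            _check_pct(nm, getattr(self, nm))
        diffs = [getattr(self, nm) for nm in _DIFFERENTIAL_FIELDS]
        if self.differential_viable:
            if any(v is None for v in diffs):
                raise ValidationError(
                    "differential_viable sample lacks a differential field"
                )
            total = sum(diffs)
            if abs(total - 100.0) > percent_sum_tol:
                raise ValidationError(
                    f"differential percentages sum to {total:.2f}, "
                    f"not 100 +/- {percent_sum_tol}"
                )
        elif any(v is not None for v in diffs):
            raise ValidationError(
                "differential percentages present but differential_viable "
                "is false"
            )
        if self.feg_clumps_per_fov is not None:
            derived = grade_feg(self.feg_clumps_per_fov)
            if self.feg_grade is None:
                object.__setattr__(self, "feg_grade", derived)
            elif self.feg_grade != derived:
                raise ValidationError(
                    f"feg_grade {self.feg_grade} inconsistent with "
                    f"{self.feg_clumps_per_fov} clumps/fov ({derived})"
                )
        for nm in ("ics_dose", "ocs_dose"):
            v = getattr(self, nm)
            if v is not None and v < 0:
                raise ValidationError(f"{nm} must be non-negative")

    @property
    def feg_observed(self) -> bool:
        """Whether any FEG enumeration was recorded for this sample."""
        return self.feg_grade is not None


@dataclass(frozen=True)
class PatientSeries:
    """Time-ordered examinations for one patient; the unit of longitudinal
    analysis."""

    patient_id: str
    samples: tuple[SputumSample, ...]

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValidationError("PatientSeries requires >= 1 sample")
        if any(s.patient_id != self.patient_id for s in self.samples):
            raise ValidationError("sample patient_id mismatch in series")
        dates = [s.exam_date for s in self.samples]
        if any(b < a for a, b in zip(dates, dates[1:])):
            raise ValidationError("samples not ordered by exam_date")
        if any(b == a for a, b in zip(dates, dates[1:])):
            warnings.warn(
                f"patient {self.patient_id}: same-day examinations kept in "
                "input order",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[SputumSample]:
        return iter(self.samples)


class Cohort:
    """An ordered collection of :class:`PatientSeries`."""

    def __init__(self, series: Iterable[PatientSeries]):
        self.series: list[PatientSeries] = list(series)
        ids = [s.patient_id for s in self.series]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate patient_id across series")

    def __len__(self) -> int:
        return len(self.series)

    def __iter__(self) -> Iterator[PatientSeries]:
        return iter(self.series)

    @property
    def n_patients(self) -> int:
        return len(self.series)

    @property
    def n_samples(self) -> int:
        return sum(len(s) for s in self.series)

    def samples(self) -> Iterator[SputumSample]:
        for ser in self.series:
            yield from ser


@dataclass(frozen=True)
class ThresholdSpec:
    """An eosinophilia threshold: an intact-differential cutoff plus the
    set of FEG grades accepted as equivalent evidence.

    The two published criteria are 1.2% (upper limit of normal; any FEG
    grade qualifies) and 2.3% (clinically relevant endotype; only
    moderate/many qualify — few granules are not regarded as clinically
    relevant).
    """

    name: str
    intact_cutoff: float
    qualifying_feg_grades: frozenset[FegGrade]
    comparison: str = ">="  # configurable for sensitivity checks

    def __post_init__(self) -> None:
        if self.intact_cutoff <= 0:
            raise ValidationError("intact_cutoff must be > 0")
        if FegGrade.NONE in self.qualifying_feg_grades:
            raise ValidationError("qualifying grades may not include 'none'")
        if self.comparison not in (">=", ">"):
            raise ValidationError("comparison must be '>=' or '>'")

    def intact_positive(self, eosinophil_pct: float) -> bool:
        if self.comparison == ">=":
            return eosinophil_pct >= self.intact_cutoff
        return eosinophil_pct > self.intact_cutoff


ABNORMAL_1_2 = ThresholdSpec(
    name="1.2",
    intact_cutoff=1.2,
    qualifying_feg_grades=frozenset(
        {FegGrade.FEW, FegGrade.MODERATE, FegGrade.MANY}
    ),
)
CLINICAL_2_3 = ThresholdSpec(
    name="2.3",
    intact_cutoff=2.3,
    qualifying_feg_grades=frozenset({FegGrade.MODERATE, FegGrade.MANY}),
)
DEFAULT_THRESHOLDS = (ABNORMAL_1_2, CLINICAL_2_3)


# ---------------------------------------------------------------------------
# CSV ingestion / serialization

COHORT_COLUMNS = [
    "patient_id",
    "exam_date",
    "total_cell_count_e6_per_g",
    "viability_pct",
    "squamous_pct",
    "differential_viable",
    "neutrophil_pct",
    "eosinophil_pct",
    "macrophage_pct",
    "lymphocyte_pct",
    "bronchial_epithelial_pct",
    "feg_clumps_per_fov",
    "feg_grade",
    "ics_dose_mcg",
    "ocs_dose_mg",
    "clinical_state",
]

_MANDATORY_COLUMNS = {"patient_id", "exam_date", "differential_viable"}


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str):
        value = value.strip()
        if value == "":
            return None
    return float(value)


def _opt_int(value) -> Optional[int]:
    f = _opt_float(value)
    if f is None:
        return None
    if f != int(f):
        raise ValidationError(f"expected integer, got {value!r}")
    return int(f)


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    token = str(value).strip().lower()
    if token in ("true", "1", "yes"):
        return True
    if token in ("false", "0", "no"):
        return False
    raise ValidationError(f"unparseable boolean {value!r}")


def _row_to_sample(row: dict, percent_sum_tol: float) -> SputumSample:
    raw_date = row.get("exam_date")
    if isinstance(raw_date, _dt.datetime):
        date = raw_date.date()
    elif isinstance(raw_date, _dt.date):
        date = raw_date
    else:
        try:
            date = _dt.date.fromisoformat(str(raw_date).strip())
        except ValueError:
            raise ValidationError(
                f"unparseable ISO-8601 date {raw_date!r}"
            ) from None
    grade_token = row.get("feg_grade")
    if grade_token is None or (
        isinstance(grade_token, float) and math.isnan(grade_token)
    ):
        grade = None
    else:
        token = str(grade_token).strip()
        grade = FegGrade.from_string(token) if token else None
    state_token = row.get("clinical_state")
    if state_token is None or (
        isinstance(state_token, float) and math.isnan(state_token)
    ):
        state = ClinicalState.UNKNOWN
    else:
        token = str(state_token).strip().lower()
        state = ClinicalState(token) if token else ClinicalState.UNKNOWN
    return SputumSample(
        patient_id=str(row["patient_id"]).strip(),
        exam_date=date,
        differential_viable=_parse_bool(row["differential_viable"]),
        total_cell_count=_opt_float(row.get("total_cell_count_e6_per_g")),
        viability_pct=_opt_float(row.get("viability_pct")),
        squamous_pct=_opt_float(row.get("squamous_pct")),
        neutrophil_pct=_opt_float(row.get("neutrophil_pct")),
        eosinophil_pct=_opt_float(row.get("eosinophil_pct")),
        macrophage_pct=_opt_float(row.get("macrophage_pct")),
        lymphocyte_pct=_opt_float(row.get("lymphocyte_pct")),
        bronchial_epithelial_pct=_opt_float(
            row.get("bronchial_epithelial_pct")
        ),
        feg_clumps_per_fov=_opt_int(row.get("feg_clumps_per_fov")),
        feg_grade=grade,
        ics_dose=_opt_float(row.get("ics_dose_mcg")),
        ocs_dose=_opt_float(row.get("ocs_dose_mg")),
        clinical_state=state,
        percent_sum_tol=percent_sum_tol,
    )


def read_cohort(
    path: str | Path,
    percent_sum_tol: float = PERCENT_SUM_TOL,
) -> tuple[Cohort, pd.DataFrame]:
    """Read a cohort CSV, returning ``(cohort, rejects)``.

    Rows violating a domain invariant are collected into the rejects frame
    (original columns plus ``reject_reason``), never silently dropped.
    Rows are grouped by ``patient_id`` and sorted by ``exam_date`` (stable
    on ties, which are flagged with a warning).

    Raises
    ------
    ValidationError
        If a mandatory column is missing from the header.
    """
    df = pd.read_csv(path, dtype={"patient_id": str, "feg_grade": str})
    missing = _MANDATORY_COLUMNS - set(df.columns)
    if missing:
        raise ValidationError(f"missing mandatory column(s): {sorted(missing)}")
    samples: dict[str, list[SputumSample]] = {}
    order: list[str] = []
    reject_rows: list[dict] = []
    for row in df.to_dict("records"):
        try:
            sample = _row_to_sample(row, percent_sum_tol)
        except (ValidationError, KeyError, ValueError) as exc:
            rec = dict(row)
            rec["reject_reason"] = str(exc)
            reject_rows.append(rec)
            continue
        if sample.patient_id not in samples:
            samples[sample.patient_id] = []
            order.append(sample.patient_id)
        samples[sample.patient_id].append(sample)
    series = []
    for pid in order:
        ordered = sorted(samples[pid], key=lambda s: s.exam_date)
        series.append(PatientSeries(patient_id=pid, samples=tuple(ordered)))
    rejects = pd.DataFrame(
        reject_rows, columns=list(df.columns) + ["reject_reason"]
    )
    return Cohort(series), rejects


def _sample_to_row(s: SputumSample) -> dict:
    return {
        "patient_id": s.patient_id,
        "exam_date": s.exam_date.isoformat(),
        "total_cell_count_e6_per_g": s.total_cell_count,
        "viability_pct": s.viability_pct,
        "squamous_pct": s.squamous_pct,
        "differential_viable": s.differential_viable,
        "neutrophil_pct": s.neutrophil_pct,
        "eosinophil_pct": s.eosinophil_pct,
        "macrophage_pct": s.macrophage_pct,
        "lymphocyte_pct": s.lymphocyte_pct,
        "bronchial_epithelial_pct": s.bronchial_epithelial_pct,
        "feg_clumps_per_fov": s.feg_clumps_per_fov,
        "feg_grade": str(s.feg_grade) if s.feg_grade is not None else None,
        "ics_dose_mcg": s.ics_dose,
        "ocs_dose_mg": s.ocs_dose,
        "clinical_state": s.clinical_state.value,
    }


def cohort_to_frame(cohort: Cohort) -> pd.DataFrame:
    """Flatten a cohort to one row per examination (the CSV schema)."""
    return pd.DataFrame(
        [_sample_to_row(s) for s in cohort.samples()], columns=COHORT_COLUMNS
    )


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Serialize a cohort to the canonical CSV schema."""
    cohort_to_frame(cohort).to_csv(path, index=False)


def split_by_multiplicity(cohort: Cohort) -> tuple[Cohort, Cohort]:
    """Partition into (single-sample patients, multi-sample patients).

    The parts are disjoint and exhaustive: a patient contributes to exactly
    one part according to whether their series holds one examination or two
    or more.
    """
    single = [s for s in cohort if len(s) == 1]
    multi = [s for s in cohort if len(s) >= 2]
    return Cohort(single), Cohort(multi)


def summarize_cohort(cohort: Cohort) -> pd.DataFrame:
    """Descriptive summary of a cohort, one row per characteristic.

    Dose fields are summarized as mean (SD); cytometry fields as median
    (minimum-maximum); binary exposure fields as count (%).  Unknown doses
    are excluded from dose means but counted in the exposure denominators
    as not-on-drug is unknowable — they are dropped from those tallies too.
    """
    if cohort.n_samples == 0:
        raise ValidationError("cannot summarize an empty cohort")
    rows = []
    all_samples = list(cohort.samples())
    n = len(all_samples)

    def _series(getter) -> pd.Series:
        return pd.Series(
            [getter(s) for s in all_samples], dtype="float64"
        ).dropna()

    for label, getter in [
        ("ics_dose_mcg", lambda s: s.ics_dose),
        ("ocs_dose_mg", lambda s: s.ocs_dose),
    ]:
        vals = _series(getter)
        rows.append(
            {
                "characteristic": label,
                "statistic": "mean (SD)",
                "value": vals.mean() if len(vals) else math.nan,
                "spread": vals.std(ddof=1) if len(vals) > 1 else math.nan,
                "n": len(vals),
            }
        )
    for label, getter in [
        ("on_ics", lambda s: None if s.ics_dose is None else s.ics_dose > 0),
        ("on_ocs", lambda s: None if s.ocs_dose is None else s.ocs_dose > 0),
        (
            "differential_viable",
            lambda s: s.differential_viable,
        ),
    ]:
        flags = [getter(s) for s in all_samples]
        known = [f for f in flags if f is not None]
        count = sum(known)
        rows.append(
            {
                "characteristic": label,
                "statistic": "count (%)",
                "value": count,
                "spread": 100.0 * count / len(known) if known else math.nan,
                "n": len(known),
            }
        )
    for label, getter in [
        ("viability_pct", lambda s: s.viability_pct),
        ("total_cell_count_e6_per_g", lambda s: s.total_cell_count),
        ("neutrophil_pct", lambda s: s.neutrophil_pct),
        ("eosinophil_pct", lambda s: s.eosinophil_pct),
        ("macrophage_pct", lambda s: s.macrophage_pct),
        ("lymphocyte_pct", lambda s: s.lymphocyte_pct),
        ("bronchial_epithelial_pct", lambda s: s.bronchial_epithelial_pct),
    ]:
        vals = _series(getter)
        rows.append(
            {
                "characteristic": label,
                "statistic": "median (min-max)",
                "value": vals.median() if len(vals) else math.nan,
                "spread": (
                    (vals.min(), vals.max()) if len(vals) else (math.nan,) * 2
                ),
                "n": len(vals),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["n_samples"] = n
    out.attrs["n_patients"] = cohort.n_patients
    return out
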