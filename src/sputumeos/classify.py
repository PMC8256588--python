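"""Per-sample eosinophilia calls at a threshold specification.

A sample is called eosinophilic when the intact eosinophil differential
meets the cutoff, or when free eosinophil granules of a qualifying grade
are present, or both.  FEG evidence also applies to samples too
degenerated for an intact differential, which would otherwise be
mis-classified as non-eosinophilic.  A sample with neither an intact
differential nor any FEG enumeration is *indeterminate*: it is called
non-eosinophilic with ``basis="none"`` and flagged for audit.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import pandas as pd

from .cohort import (
    Cohort,
    FegGrade,
    SputumSample,
    ThresholdSpec,
    ValidationError,
)

__all__ = [
    "CallBasis",
    "EosinophiliaCall",
    "CohortTallies",
    "classify_sample",
    "classify_intact_only",
    "classify_cohort",
    "calls_to_frame",
]


class CallBasis(enum.Enum):
    INTACT_COUNT = "intact_count"
    FEG_ONLY = "feg_only"
    INTACT_AND_FEG = "intact_and_feg"
    NONE = "none"


@dataclass(frozen=True)
class EosinophiliaCall:
    """Classification of one sample under one threshold."""

    sample: SputumSample
    threshold_name: str
    eosinophilic: bool
    basis: CallBasis
    intact_available: bool
    indeterminate: bool

    def __post_init__(self) -> None:
        if (self.basis is CallBasis.NONE) != (not self.eosinophilic):
            raise ValidationError("basis 'none' iff not eosinophilic")


def _feg_qualifies(sample: SputumSample, spec: ThresholdSpec) -> bool:
    return (
        sample.feg_grade is not None
        and sample.feg_grade in spec.qualifying_feg_grades
    )


def classify_sample(
    sample: SputumSample, spec: ThresholdSpec
) -> EosinophiliaCall:
    """Call a sample eosinophilic/not under the FEG-augmented rule.

    eosinophilic = (intact differential available AND eosinophil % meets
    the cutoff) OR (FEG grade in the qualifying set).  The basis records
    which disjunct(s) fired.
    """
    if not spec.qualifying_feg_grades:
        raise ValidationError("qualifying FEG grade set must be non-empty")
    intact_hit = sample.differential_viable and spec.intact_positive(
        sample.eosinophil_pct
    )
    feg_hit = _feg_qualifies(sample, spec)
    if intact_hit and feg_hit:
        basis = CallBasis.INTACT_AND_FEG
    elif intact_hit:
        basis = CallBasis.INTACT_COUNT
    elif feg_hit:
        basis = CallBasis.FEG_ONLY
    else:
        basis = CallBasis.NONE
    indeterminate = (
        not sample.differential_viable and not sample.feg_observed
    )
    return EosinophiliaCall(
        sample=sample,
        threshold_name=spec.name,
        eosinophilic=intact_hit or feg_hit,
        basis=basis,
        intact_available=sample.differential_viable,
        indeterminate=indeterminate,
    )


def classify_intact_only(
    sample: SputumSample, spec: ThresholdSpec
) -> EosinophiliaCall:
    """Call a sample using the intact differential alone (FEG disjunct
    disabled); the basis for the single-time-point intact-count tier."""
    intact_hit = sample.differential_viable and spec.intact_positive(
        sample.eosinophil_pct
    )
    return EosinophiliaCall(
        sample=sample,
        threshold_name=spec.name,
        eosinophilic=intact_hit,
        basis=CallBasis.INTACT_COUNT if intact_hit else CallBasis.NONE,
        intact_available=sample.differential_viable,
        indeterminate=not sample.differential_viable,
    )


@dataclass(frozen=True)
class CohortTallies:
    """Per-category sample counts feeding the prevalence composition.

    ``n_feg_no_diff_few`` / ``n_feg_no_diff_modmany`` count samples with no
    intact differential by observed FEG grade regardless of the threshold's
    qualifying set, so both the nested composition (all qualifying grades)
    and the published tally convention (few at the 1.2% tier, moderate/many
    at the 2.3% tier) can be formed from the same object.
    """

    threshold_name: str
    n_total: int
    n_intact_pos: int
    n_feg_with_diff: int  # intact differential present, below cutoff, FEG qualifying
    n_feg_no_diff_few: int
    n_feg_no_diff_modmany: int
    n_indeterminate: int

    @property
    def n_feg_no_diff_qualifying(self) -> int:
        """Non-viable FEG-positive count under this threshold's own
        qualifying grade set (the logically nested rule)."""
        if FegGrade.FEW in self._qualifying:
            return self.n_feg_no_diff_few + self.n_feg_no_diff_modmany
        return self.n_feg_no_diff_modmany

    # set post-construction by classify_cohort
    _qualifying: frozenset = frozenset()


def classify_cohort(
    cohort: Cohort,
    spec: ThresholdSpec,
    mode: str = "with_feg",
) -> tuple[list[EosinophiliaCall], CohortTallies]:
    """Classify every sample and tally the composition categories.

    Parameters
    ----------
    cohort
        Validated cohort.
    spec
        Threshold specification.
    mode
        ``"with_feg"`` (default) applies the FEG-augmented rule;
        ``"intact_only"`` disables the FEG disjunct (category tallies for
        FEG columns are then zero by construction).
    """
    if mode not in ("with_feg", "intact_only"):
        raise ValidationError(f"unknown classification mode {mode!r}")
    classify = classify_sample if mode == "with_feg" else classify_intact_only
    calls = [classify(s, spec) for s in cohort.samples()]
    n_intact_pos = 0
    n_feg_with_diff = 0
    n_nd_few = 0
    n_nd_modmany = 0
    n_indeterminate = 0
    for call in calls:
        s = call.sample
        if call.indeterminate:
            n_indeterminate += 1
        if s.differential_viable:
            if spec.intact_positive(s.eosinophil_pct):
                n_intact_pos += 1
            elif mode == "with_feg" and _feg_qualifies(s, spec):
                n_feg_with_diff += 1
        elif mode == "with_feg" and s.feg_grade is not None:
            if s.feg_grade is FegGrade.FEW:
                n_nd_few += 1
            elif s.feg_grade in (FegGrade.MODERATE, FegGrade.MANY):
                n_nd_modmany += 1
    tallies = CohortTallies(
        threshold_name=spec.name,
        n_total=len(calls),
        n_intact_pos=n_intact_pos,
        n_feg_with_diff=n_feg_with_diff,
        n_feg_no_diff_few=n_nd_few,
        n_feg_no_diff_modmany=n_nd_modmany,
        n_indeterminate=n_indeterminate,
        _qualifying=spec.qualifying_feg_grades,
    )
    return calls, tallies


def calls_to_frame(calls: list[EosinophiliaCall]) -> pd.DataFrame:
    """Serialize calls as a flat table (one row per sample x threshold)."""
    return pd.DataFrame(
        {
            "patient_id": [c.sample.patient_id for c in calls],
            "exam_date": [c.sample.exam_date.isoformat() for c in calls],
            "threshold_name": [c.threshold_name for c in calls],
            "eosinophilic": [c.eosinophilic for c in calls],
            "basis": [c.basis.value for c in calls],
            "indeterminate": [c.indeterminate for c in calls],
        }
    )
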