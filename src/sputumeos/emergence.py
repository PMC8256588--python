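"""Detection of re-emergence (unmasking) of sputum eosinophilia.

An emergence event is a consecutive within-patient pair of examinations in
which the first is non-eosinophilic and the second eosinophilic under the
FEG-augmented rule.  Airway eosinophilia can be transiently masked — by
corticosteroid dosing, or by a concomitant neutrophilia that dilutes the
differential — so a patient examined repeatedly may show eosinophilia
"re-emerging" after such a mask resolves.  Each event is attributed to a
suspected etiology: treated neutrophilic bronchitis (elevated neutrophil %
on the initial sample), a decrease in corticosteroid dose between the two
samples, both, or — when neither condition holds — a flare of eosinophilic
inflammation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import pandas as pd

from .classify import EosinophiliaCall, classify_sample
from .cohort import Cohort, PatientSeries, SputumSample, ThresholdSpec
from .cohort import ValidationError

__all__ = [
    "DEFAULT_NEUTROPHIL_CUTOFF",
    "Etiology",
    "EmergenceEvent",
    "EmergenceSummary",
    "detect_events",
    "attribute_etiology",
    "summarize_emergence",
    "events_to_frame",
]

#: Conventional upper limit of normal for the sputum neutrophil
#: differential (%); "elevated" initial neutrophilia means above this.
DEFAULT_NEUTROPHIL_CUTOFF = 64.4


class Etiology(enum.Enum):
    NEUTROPHILIA_AND_STEROID_DECREASE = "neutrophilia_and_steroid_decrease"
    NEUTROPHILIA_TREATED = "neutrophilia_treated"
    STEROID_DECREASE = "steroid_decrease"
    FLARE = "flare"


@dataclass(frozen=True)
class EmergenceEvent:
    """One non-eosinophilic -> eosinophilic transition between consecutive
    examinations of the same patient."""

    patient_id: str
    initial: SputumSample
    subsequent: SputumSample
    threshold_name: str
    etiology: Etiology
    neutrophilia_at_initial: bool
    steroid_decreased: bool

    def __post_init__(self) -> None:
        if self.subsequent.exam_date < self.initial.exam_date:
            raise ValidationError("subsequent sample precedes initial")
        expected = _etiology_from_flags(
            self.neutrophilia_at_initial, self.steroid_decreased
        )
        if expected is not self.etiology:
            raise ValidationError("etiology inconsistent with flags")


def _etiology_from_flags(neutrophilia: bool, steroid_dec: bool) -> Etiology:
    if neutrophilia and steroid_dec:
        return Etiology.NEUTROPHILIA_AND_STEROID_DECREASE
    if neutrophilia:
        return Etiology.NEUTROPHILIA_TREATED
    if steroid_dec:
        return Etiology.STEROID_DECREASE
    return Etiology.FLARE


def attribute_etiology(
    initial: SputumSample,
    subsequent: SputumSample,
    neutrophil_cutoff: float = DEFAULT_NEUTROPHIL_CUTOFF,
) -> tuple[Etiology, bool, bool]:
    """Attribute a suspected etiology to an emergence pair.

    Returns ``(etiology, neutrophilia_at_initial, steroid_decreased)``.
    Neutrophilia at the initial sample means its neutrophil % exceeds
    ``neutrophil_cutoff`` (indeterminate-false when no intact differential
    was available).  A steroid decrease means the oral or the inhaled
    (fluticasone-equivalent) dose at the subsequent examination is lower
    than at the initial one; comparisons involving an unknown dose are
    indeterminate-false rather than guessed.  The four categories are
    mutually exclusive.
    """
    neutrophilia = (
        initial.neutrophil_pct is not None
        and initial.neutrophil_pct > neutrophil_cutoff
    )

    def _lower(a, b) -> bool:
        return a is not None and b is not None and b < a

    steroid_dec = _lower(initial.ocs_dose, subsequent.ocs_dose) or _lower(
        initial.ics_dose, subsequent.ics_dose
    )
    return (
        _etiology_from_flags(neutrophilia, steroid_dec),
        neutrophilia,
        steroid_dec,
    )


def detect_events(
    series: PatientSeries,
    spec: ThresholdSpec,
    neutrophil_cutoff: float = DEFAULT_NEUTROPHIL_CUTOFF,
    indeterminate_policy: str = "skip",
) -> list[EmergenceEvent]:
    """Scan consecutive examination pairs of one patient for emergence.

    A pair ``(i, i+1)`` yields an event when the call at ``i`` is
    non-eosinophilic and the call at ``i+1`` eosinophilic under the
    FEG-augmented rule for ``spec``.  A patient may contribute several
    events (e.g. between the first and second samples and again between
    the fourth and fifth).

    ``indeterminate_policy`` controls pairs touching an indeterminate call
    (no intact differential and no FEG enumeration): ``"skip"`` (default)
    drops the pair from scanning entirely; ``"negative_initial"`` lets an
    indeterminate initial count as non-eosinophilic, while an
    indeterminate subsequent can never count as eosinophilic.

    A series with fewer than two samples yields an empty list.
    """
    if indeterminate_policy not in ("skip", "negative_initial"):
        raise ValidationError(
            f"unknown indeterminate policy {indeterminate_policy!r}"
        )
    calls = [classify_sample(s, spec) for s in series]
    events: list[EmergenceEvent] = []
    for first, second in zip(calls, calls[1:]):
        if second.indeterminate:
            continue
        if first.indeterminate and indeterminate_policy == "skip":
            continue
        if (not first.eosinophilic) and second.eosinophilic:
            etiology, neut, dec = attribute_etiology(
                first.sample, second.sample, neutrophil_cutoff
            )
            events.append(
                EmergenceEvent(
                    patient_id=series.patient_id,
                    initial=first.sample,
                    subsequent=second.sample,
                    threshold_name=spec.name,
                    etiology=etiology,
                    neutrophilia_at_initial=neut,
                    steroid_decreased=dec,
                )
            )
    return events


@dataclass(frozen=True)
class EmergenceSummary:
    """Cohort-level emergence statistics over multi-sample patients."""

    threshold_name: str
    neutrophil_cutoff: float
    n_multi_patients: int
    n_patients_with_event: int
    n_events: int
    etiology_counts: dict

    @property
    def fraction_patients(self) -> float:
        return self.n_patients_with_event / self.n_multi_patients

    @property
    def events_per_patient(self) -> float:
        return self.n_events / self.n_multi_patients

    @property
    def etiology_fractions(self) -> dict:
        """Mutually exclusive event-level fractions (sum to 1 when any
        events exist)."""
        if self.n_events == 0:
            return {k: 0.0 for k in self.etiology_counts}
        return {
            k: v / self.n_events for k, v in self.etiology_counts.items()
        }

    def to_dict(self) -> dict:
        return {
            "threshold_name": self.threshold_name,
            "neutrophil_cutoff": self.neutrophil_cutoff,
            "n_multi_patients": self.n_multi_patients,
            "n_patients_with_event": self.n_patients_with_event,
            "n_events": self.n_events,
            "fraction_patients": self.fraction_patients,
            "events_per_patient": self.events_per_patient,
            "etiology_counts": dict(self.etiology_counts),
            "etiology_fractions": self.etiology_fractions,
        }


def summarize_emergence(
    cohort_multi: Cohort,
    spec: ThresholdSpec,
    neutrophil_cutoff: float = DEFAULT_NEUTROPHIL_CUTOFF,
    indeterminate_policy: str = "skip",
) -> tuple[EmergenceSummary, list[EmergenceEvent]]:
    """Aggregate emergence over the multi-sample part of a cohort.

    ``fraction_patients`` is the share of multi-sample patients with at
    least one event; ``events_per_patient`` is total events divided by
    multi-sample patients.  The etiology breakdown partitions events into
    mutually exclusive categories.
    """
    if cohort_multi.n_patients == 0:
        raise ValidationError("no multi-sample patients: emergence not "
                              "estimable")
    all_events: list[EmergenceEvent] = []
    n_with_event = 0
    for series in cohort_multi:
        events = detect_events(
            series, spec, neutrophil_cutoff, indeterminate_policy
        )
        if events:
            n_with_event += 1
        all_events.extend(events)
    counts = {e.value: 0 for e in Etiology}
    for ev in all_events:
        counts[ev.etiology.value] += 1
    summary = EmergenceSummary(
        threshold_name=spec.name,
        neutrophil_cutoff=neutrophil_cutoff,
        n_multi_patients=cohort_multi.n_patients,
        n_patients_with_event=n_with_event,
        n_events=len(all_events),
        etiology_counts=counts,
    )
    return summary, all_events


def events_to_frame(events: list[EmergenceEvent]) -> pd.DataFrame:
    """Serialize events as a flat table."""
    return pd.DataFrame(
        {
            "patient_id": [e.patient_id for e in events],
            "initial_date": [e.initial.exam_date.isoformat() for e in events],
            "subsequent_date": [
                e.subsequent.exam_date.isoformat() for e in events
            ],
            "threshold_name": [e.threshold_name for e in events],
            "etiology": [e.etiology.value for e in events],
            "neutrophilia_at_initial": [
                e.neutrophilia_at_initial for e in events
            ],
            "steroid_decreased": [e.steroid_decreased for e in events],
        }
    )
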