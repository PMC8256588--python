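"""Shared construction helpers for the test suite."""

from __future__ import annotations

import datetime as dt
from typing import Optional, Sequence

from sputumeos import Cohort, PatientSeries, SputumSample


def make_sample(
    eos: Optional[float] = 0.0,
    viable: bool = True,
    clumps: Optional[int] = None,
    pid: str = "P1",
    day: int = 0,
    neut: Optional[float] = 50.0,
    ics: Optional[float] = None,
    ocs: Optional[float] = None,
) -> SputumSample:
    """A valid sample with the differential balanced to sum to 100."""
    if viable:
        rest = 100.0 - eos - neut
        macro, lymph, epith = rest - 1.0, 0.6, 0.4
    else:
        eos = neut = macro = lymph = epith = None
    return SputumSample(
        patient_id=pid,
        exam_date=dt.date(2010, 1, 1) + dt.timedelta(days=day),
        differential_viable=viable,
        neutrophil_pct=neut,
        eosinophil_pct=eos,
        macrophage_pct=macro,
        lymphocyte_pct=lymph,
        bronchial_epithelial_pct=epith,
        feg_clumps_per_fov=clumps,
        ics_dose=ics,
        ocs_dose=ocs,
    )


def series_from_eos(
    eos_values: Sequence[Optional[float]], pid: str = "P1", **kwargs
) -> PatientSeries:
    """A series whose call pattern is driven by intact eos % alone;
    ``None`` means a degenerated sample with no FEG enumeration
    (indeterminate)."""
    samples = tuple(
        make_sample(
            eos=v if v is not None else None,
            viable=v is not None,
            pid=pid,
            day=30 * i,
            **kwargs,
        )
        for i, v in enumerate(eos_values)
    )
    return PatientSeries(patient_id=pid, samples=samples)


def cohort_from_eos(per_patient: Sequence[Sequence[Optional[float]]]) -> Cohort:
    return Cohort(
        series_from_eos(vals, pid=f"P{i}")
        for i, vals in enumerate(per_patient)
    )
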