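"""Model/Results interface wiring the full staged analysis.

:class:`SputumEosinophilia` is constructed from a cohort (object, flat
DataFrame, or CSV path) and fitting it runs the whole published-style
pipeline: descriptive summary, per-threshold FEG-augmented classification
tallies, emergence detection over multi-sample patients with etiology
attribution, staged prevalence composition with extrapolation, the
two-state Markov sensitivity model, and the Euler tier composition.  The
returned :class:`SputumEosinophiliaResults` carries every intermediate
object and renders a text ``summary()``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import classify as _classify
from . import emergence as _emergence
from . import markov as _markov
from . import prevalence as _prevalence
from .cohort import (
    Cohort,
    DEFAULT_THRESHOLDS,
    ThresholdSpec,
    ValidationError,
    read_cohort,
    split_by_multiplicity,
    summarize_cohort,
)

__all__ = ["SputumEosinophilia", "SputumEosinophiliaResults"]


@dataclass
class ThresholdResult:
    """Everything estimated at one threshold."""

    spec: ThresholdSpec
    tallies: _classify.CohortTallies
    calls: list
    estimate: _prevalence.PrevalenceEstimate
    emergence: Optional[_emergence.EmergenceSummary]
    events: list
    transition_model: Optional[_markov.TransitionModel]
    euler: dict

    @property
    def estimable_longitudinal(self) -> bool:
        return self.emergence is not None


class SputumEosinophilia:
    """Staged eosinophilia prevalence model for a sputum cytometry cohort.

    Parameters
    ----------
    cohort
        A validated :class:`~sputumeos.cohort.Cohort`.
    thresholds
        Threshold specifications to analyse (default: 1.2% with any FEG
        grade, 2.3% with moderate/many).
    neutrophil_cutoff
        Sputum neutrophil % above which the initial sample of an emergence
        pair counts as neutrophilic (etiology attribution).
    tally_mode
        ``"nested"`` (logically nested classification rule) or
        ``"paper_tally"`` (reproduces the published tier arithmetic, which
        splits non-viable FEG samples between tiers by grade).
    indeterminate_policy
        How emergence scanning treats indeterminate calls; see
        :func:`sputumeos.emergence.detect_events`.
    """

    def __init__(
        self,
        cohort: Cohort,
        thresholds: Sequence[ThresholdSpec] = DEFAULT_THRESHOLDS,
        neutrophil_cutoff: float = _emergence.DEFAULT_NEUTROPHIL_CUTOFF,
        tally_mode: str = "nested",
        indeterminate_policy: str = "skip",
    ):
        if not thresholds:
            raise ValidationError("at least one threshold required")
        if cohort.n_samples == 0:
            raise ValidationError("empty cohort")
        self.cohort = cohort
        self.thresholds = tuple(thresholds)
        self.neutrophil_cutoff = neutrophil_cutoff
        self.tally_mode = tally_mode
        self.indeterminate_policy = indeterminate_policy

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "SputumEosinophilia":
        cohort, rejects = read_cohort(path)
        if len(rejects):
            raise ValidationError(
                f"{len(rejects)} rejected rows in {path}; validate first"
            )
        return cls(cohort, **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "SputumEosinophilia":
        import io

        buf = io.StringIO()
        df.to_csv(buf, index=False)
        buf.seek(0)
        cohort, rejects = read_cohort(buf)
        if len(rejects):
            raise ValidationError(f"{len(rejects)} rows failed validation")
        return cls(cohort, **kwargs)

    def fit(self) -> "SputumEosinophiliaResults":
        """Run the full staged analysis and return the results object."""
        single, multi = split_by_multiplicity(self.cohort)
        descriptives = summarize_cohort(self.cohort)
        per_threshold: dict[str, ThresholdResult] = {}
        for spec in self.thresholds:
            calls, tallies = _classify.classify_cohort(
                self.cohort, spec, mode="with_feg"
            )
            emergence_summary = None
            events: list = []
            tm = None
            if multi.n_patients > 0:
                emergence_summary, events = _emergence.summarize_emergence(
                    multi,
                    spec,
                    self.neutrophil_cutoff,
                    self.indeterminate_policy,
                )
                sequences = []
                for series in multi:
                    seq = [
                        c.eosinophilic
                        for c in (
                            _classify.classify_sample(s, spec) for s in series
                        )
                        if not c.indeterminate
                    ]
                    if len(seq) >= 2:
                        sequences.append(seq)
                if sequences:
                    tm = _markov.estimate_transitions(
                        sequences, threshold_name=spec.name
                    )
            estimate = _prevalence.estimate_from_tallies(
                tallies,
                emergence_fraction=(
                    emergence_summary.fraction_patients
                    if emergence_summary is not None
                    else None
                ),
                tally_mode=self.tally_mode,
            )
            per_threshold[spec.name] = ThresholdResult(
                spec=spec,
                tallies=tallies,
                calls=calls,
                estimate=estimate,
                emergence=emergence_summary,
                events=events,
                transition_model=tm,
                euler=_prevalence.euler_composition(estimate),
            )
        return SputumEosinophiliaResults(
            model=self,
            descriptives=descriptives,
            n_single_patients=single.n_patients,
            n_multi_patients=multi.n_patients,
            n_multi_samples=multi.n_samples,
            per_threshold=per_threshold,
        )


class SputumEosinophiliaResults:
    """Fitted staged-prevalence results; one entry per threshold."""

    def __init__(
        self,
        model: SputumEosinophilia,
        descriptives: pd.DataFrame,
        n_single_patients: int,
        n_multi_patients: int,
        n_multi_samples: int,
        per_threshold: dict,
    ):
        self.model = model
        self.descriptives = descriptives
        self.n_single_patients = n_single_patients
        self.n_multi_patients = n_multi_patients
        self.n_multi_samples = n_multi_samples
        self.per_threshold = per_threshold

    def __getitem__(self, threshold_name: str) -> ThresholdResult:
        return self.per_threshold[threshold_name]

    def to_dict(self) -> dict:
        out = {
            "n_patients": self.model.cohort.n_patients,
            "n_samples": self.model.cohort.n_samples,
            "n_single_patients": self.n_single_patients,
            "n_multi_patients": self.n_multi_patients,
            "n_multi_samples": self.n_multi_samples,
            "neutrophil_cutoff": self.model.neutrophil_cutoff,
            "tally_mode": self.model.tally_mode,
            "thresholds": {},
        }
        for name, res in self.per_threshold.items():
            out["thresholds"][name] = {
                "prevalence": res.estimate.to_dict(),
                "emergence": (
                    res.emergence.to_dict() if res.emergence else None
                ),
                "transition_model": (
                    res.transition_model.to_dict()
                    if res.transition_model
                    else None
                ),
                "euler": res.euler,
                "longitudinal_estimable": res.estimable_longitudinal,
            }
        return out

    def save_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def summary(self) -> str:
        """Human-readable report of the staged estimates."""
        m = self.model
        lines = [
            "Airway luminal eosinophilia: staged prevalence estimates",
            "=" * 60,
            f"Samples: {m.cohort.n_samples}   Patients: "
            f"{m.cohort.n_patients}   (multi-sample: "
            f"{self.n_multi_patients} patients / {self.n_multi_samples} "
            "samples)",
            f"Tally mode: {m.tally_mode}   Neutrophil cutoff: "
            f"{m.neutrophil_cutoff}%",
            "",
        ]
        for name, res in self.per_threshold.items():
            e = res.estimate
            lines.append(f"Threshold {name}% "
                         f"(FEG grades: "
                         f"{sorted(str(g) for g in res.spec.qualifying_feg_grades)})")
            lines.append("-" * 60)
            lines.append(
                f"  intact-only prevalence      {100 * e.prev_intact:6.1f}%"
                f"   ({e.n_intact_pos}/{e.n_total})"
            )
            lines.append(
                f"  FEG-augmented prevalence    {100 * e.prev_feg_aug:6.1f}%"
                f"   (+{e.n_feg_with_diff} with diff, "
                f"+{e.n_feg_no_diff} no diff)"
            )
            if res.emergence is not None:
                s = res.emergence
                lines.append(
                    f"  emergence fraction          "
                    f"{100 * s.fraction_patients:6.1f}%   "
                    f"({s.n_patients_with_event}/{s.n_multi_patients} "
                    f"patients, {s.events_per_patient:.3f} events/patient)"
                )
                lines.append(
                    f"  extrapolated additional     "
                    f"{100 * e.additional_extrapolated:6.1f}%"
                )
                lines.append(
                    f"  total estimated prevalence  "
                    f"{100 * e.prev_total:6.1f}%"
                )
                lines.append(
                    f"  underestimation (intact)    "
                    f"{100 * e.underestimation:6.1f}%"
                )
                tm = res.transition_model
                if tm is not None and tm.fully_defined:
                    st = tm.stationary
                    lines.append(
                        f"  Markov chain   p_NE={tm.p_ne:.3f}  "
                        f"p_EN={tm.p_en:.3f}  "
                        + (
                            f"stationary pi_E={st[1]:.3f}"
                            if st
                            else "stationary undefined"
                        )
                    )
            else:
                lines.append(
                    "  extrapolation / Markov stages: not estimable "
                    "(no multi-sample patients)"
                )
            lines.append("")
        return "\n".join(lines)
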