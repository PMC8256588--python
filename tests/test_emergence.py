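"""Emergence (unmasking) detection, etiology attribution, summaries."""

import numpy as np
import pytest

from sputumeos import (
    ABNORMAL_1_2,
    CLINICAL_2_3,
    Cohort,
    Etiology,
    ValidationError,
    attribute_etiology,
    detect_events,
    summarize_emergence,
)
from sputumeos.classify import classify_sample

from helpers import cohort_from_eos, make_sample, series_from_eos

NEG, POS = 0.2, 5.0  # intact eos % well clear of both cutoffs


def brute_force_event_count(series, spec, indeterminate_policy="skip"):
    """Independent oracle: enumerate every consecutive index pair and
    apply the event definition directly."""
    calls = [classify_sample(s, spec) for s in series.samples]
    count = 0
    for i in range(len(calls) - 1):
        a, b = calls[i], calls[i + 1]
        if b.indeterminate:
            continue
        if a.indeterminate and indeterminate_policy == "skip":
            continue
        if not a.eosinophilic and b.eosinophilic:
            count += 1
    return count


class TestDetectEvents:
    def test_single_transition(self):
        events = detect_events(series_from_eos([NEG, POS]), ABNORMAL_1_2)
        assert len(events) == 1
        assert events[0].initial.exam_date < events[0].subsequent.exam_date

    def test_multiple_episodes_within_one_patient(self):
        series = series_from_eos([NEG, POS, NEG, NEG, POS])
        events = detect_events(series, ABNORMAL_1_2)
        assert len(events) == 2
        # episodes between samples 1->2 and 4->5
        assert [e.initial.exam_date for e in events] == [
            series.samples[0].exam_date,
            series.samples[3].exam_date,
        ]

    def test_persistent_eosinophilia_yields_no_events(self):
        assert detect_events(series_from_eos([POS, POS, POS]),
                             ABNORMAL_1_2) == []

    def test_single_sample_series_yields_empty_list(self):
        assert detect_events(series_from_eos([NEG]), ABNORMAL_1_2) == []

    def test_indeterminate_pairs_skipped_by_default(self):
        # degenerated, FEG-less middle sample: neither side of an event
        series = series_from_eos([NEG, None, POS])
        assert detect_events(series, ABNORMAL_1_2) == []

    def test_indeterminate_initial_counts_under_negative_policy(self):
        series = series_from_eos([NEG, None, POS])
        events = detect_events(
            series, ABNORMAL_1_2, indeterminate_policy="negative_initial"
        )
        assert len(events) == 1

    def test_indeterminate_never_counts_as_eosinophilic_side(self):
        series = series_from_eos([NEG, None])
        for policy in ("skip", "negative_initial"):
            assert detect_events(
                series, ABNORMAL_1_2, indeterminate_policy=policy
            ) == []

    def test_unknown_policy_rejected(self):
        with pytest.raises(ValidationError):
            detect_events(
                series_from_eos([NEG, POS]),
                ABNORMAL_1_2,
                indeterminate_policy="drop",
            )

    def test_streaming_scan_matches_brute_force_oracle(self):
        """Spot-check on structured patterns; the large randomized
        comparison lives in the acceptance suite."""
        patterns = [
            [NEG, POS], [POS, NEG, POS], [NEG, None, POS, NEG, POS],
            [None, None], [NEG] * 5, [POS, NEG] * 3,
        ]
        for pat in patterns:
            series = series_from_eos(pat)
            for spec in (ABNORMAL_1_2, CLINICAL_2_3):
                assert len(detect_events(series, spec)) == (
                    brute_force_event_count(series, spec)
                )


class TestAttributeEtiology:
    def _pair(self, neut=50.0, ics0=None, ics1=None, ocs0=None, ocs1=None):
        a = make_sample(eos=NEG, neut=neut, ics=ics0, ocs=ocs0, day=0)
        b = make_sample(eos=POS, ics=ics1, ocs=ocs1, day=30)
        return a, b

    def test_elevated_initial_neutrophils_alone(self):
        etiology, neut, dec = attribute_etiology(*self._pair(neut=90.0))
        assert etiology is Etiology.NEUTROPHILIA_TREATED
        assert neut and not dec

    def test_ics_step_down_alone(self):
        etiology, neut, dec = attribute_etiology(
            *self._pair(ics0=1000.0, ics1=500.0)
        )
        assert etiology is Etiology.STEROID_DECREASE
        assert dec and not neut

    def test_ocs_step_down_alone(self):
        etiology, *_ = attribute_etiology(*self._pair(ocs0=10.0, ocs1=5.0))
        assert etiology is Etiology.STEROID_DECREASE

    def test_both_conditions(self):
        etiology, *_ = attribute_etiology(
            *self._pair(neut=80.0, ocs0=10.0, ocs1=0.0)
        )
        assert etiology is Etiology.NEUTROPHILIA_AND_STEROID_DECREASE

    def test_neither_condition_is_a_flare(self):
        etiology, *_ = attribute_etiology(*self._pair())
        assert etiology is Etiology.FLARE

    def test_unknown_dose_comparison_is_indeterminate_false(self):
        # initial dose unknown: a lower-looking subsequent dose must not fire
        etiology, _, dec = attribute_etiology(*self._pair(ics1=100.0))
        assert not dec
        assert etiology is Etiology.FLARE

    def test_cutoff_is_strictly_greater_than(self):
        etiology, neut, _ = attribute_etiology(
            *self._pair(neut=64.4), neutrophil_cutoff=64.4
        )
        assert not neut

    def test_dose_increase_does_not_fire(self):
        _, _, dec = attribute_etiology(*self._pair(ics0=500.0, ics1=1000.0))
        assert not dec


class TestSummarizeEmergence:
    def test_fractions_and_rates(self):
        cohort = cohort_from_eos(
            [
                [POS, POS],            # 0 events
                [NEG, POS],            # 1 event
                [NEG, POS, NEG, POS],  # 2 events
            ]
        )
        summary, events = summarize_emergence(cohort, ABNORMAL_1_2)
        assert summary.n_multi_patients == 3
        assert summary.n_patients_with_event == 2
        assert summary.fraction_patients == pytest.approx(2 / 3)
        assert summary.events_per_patient == pytest.approx(1.0)
        assert len(events) == 3

    def test_etiology_categories_partition_events(self):
        from sputumeos import generate_cohort, paper_cohort_config
        from sputumeos.cohort import split_by_multiplicity

        cohort, _ = generate_cohort(
            paper_cohort_config(seed=13, n_patients=400)
        )
        _, multi = split_by_multiplicity(cohort)
        summary, events = summarize_emergence(multi, ABNORMAL_1_2)
        assert sum(summary.etiology_counts.values()) == summary.n_events
        assert summary.n_events == len(events)
        fracs = summary.etiology_fractions
        assert sum(fracs.values()) == pytest.approx(1.0)
        assert 0 <= summary.fraction_patients <= 1

    def test_events_bounded_by_series_length(self):
        cohort = cohort_from_eos([[NEG, POS] * 4])
        summary, _ = summarize_emergence(cohort, ABNORMAL_1_2)
        assert summary.events_per_patient <= 7  # max pairs in 8 samples

    def test_empty_multi_cohort_is_an_error(self):
        with pytest.raises(ValidationError):
            summarize_emergence(Cohort([]), ABNORMAL_1_2)

    def test_summary_records_cutoff_used(self):
        cohort = cohort_from_eos([[NEG, POS]])
        summary, _ = summarize_emergence(
            cohort, ABNORMAL_1_2, neutrophil_cutoff=70.0
        )
        assert summary.neutrophil_cutoff == 70.0


def test_emergence_fraction_matches_closed_form_on_fixed_length_series():
    """With series of length 2 and calls equal to the latent state, the
    patient-level emergence probability is pi_N * p_NE; Monte Carlo at
    n = 4000 should sit within 3 binomial standard errors."""
    from sputumeos import (
        closed_form_expectations,
        generate_cohort,
        noiseless_config,
    )
    from sputumeos.cohort import split_by_multiplicity

    cfg = noiseless_config(seed=29, n_patients=4000, p_ne=0.3, p_en=0.2)
    # force all series to length 2: geometric p -> 1
    cfg = type(cfg).from_dict(
        {**cfg.to_dict(), "series_length_geom_p": 0.999999}
    )
    cohort, _ = generate_cohort(cfg)
    _, multi = split_by_multiplicity(cohort)
    summary, _ = summarize_emergence(multi, ABNORMAL_1_2)
    pi_n = 1 - cfg.stationary_latent
    expected = pi_n * cfg.p_ne  # single pair per patient
    se = np.sqrt(expected * (1 - expected) / summary.n_multi_patients)
    assert abs(summary.fraction_patients - expected) < 3 * se
    closed = closed_form_expectations(cfg)["thresholds"]["1.2"]
    assert closed["patient_emergence_fraction"] == pytest.approx(
        expected, rel=1e-4
    )
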