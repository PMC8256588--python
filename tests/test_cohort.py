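"""Domain types, FEG grading, CSV ingestion and cohort partitioning."""

import datetime as dt
import math

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sputumeos import (
    Cohort,
    FegGrade,
    PatientSeries,
    SputumSample,
    ThresholdSpec,
    ValidationError,
    grade_feg,
    read_cohort,
    split_by_multiplicity,
    summarize_cohort,
    write_cohort,
)
from sputumeos.cohort import cohort_to_frame

from helpers import cohort_from_eos, make_sample


class TestGradeFeg:
    @pytest.mark.parametrize(
        "clumps, expected",
        [
            (0, FegGrade.NONE),
            (1, FegGrade.FEW),
            (2, FegGrade.FEW),  # overlapping boundary resolved to milder
            (3, FegGrade.MODERATE),
            (4, FegGrade.MANY),
            (5, FegGrade.MANY),
            (100, FegGrade.MANY),
        ],
    )
    def test_grade_mapping(self, clumps, expected):
        assert grade_feg(clumps) is expected

    @pytest.mark.parametrize("bad", [-1, 1.5, "two", None])
    def test_invalid_counts_rejected(self, bad):
        with pytest.raises(ValidationError):
            grade_feg(bad)

    @given(st.integers(min_value=0, max_value=50))
    def test_monotone_in_clump_count(self, c):
        assert grade_feg(c + 1) >= grade_feg(c)


class TestSputumSample:
    def test_differential_must_sum_to_100(self):
        with pytest.raises(ValidationError, match="sum"):
            SputumSample(
                patient_id="P1",
                exam_date=dt.date(2010, 1, 1),
                differential_viable=True,
                neutrophil_pct=80.0,
                eosinophil_pct=10.0,
                macrophage_pct=1.0,
                lymphocyte_pct=0.5,
                bronchial_epithelial_pct=0.5,
            )  # sums to 92

    def test_sum_tolerance_is_configurable(self):
        s = SputumSample(
            patient_id="P1",
            exam_date=dt.date(2010, 1, 1),
            differential_viable=True,
            neutrophil_pct=50.0,
            eosinophil_pct=1.0,
            macrophage_pct=46.0,
            lymphocyte_pct=1.0,
            bronchial_epithelial_pct=1.7,
            percent_sum_tol=0.5,
        )  # sums to 99.7, inside the 0.5 tolerance
        assert s.eosinophil_pct == 1.0

    def test_differential_without_viability_flag_rejected(self):
        with pytest.raises(ValidationError, match="differential_viable"):
            SputumSample(
                patient_id="P1",
                exam_date=dt.date(2010, 1, 1),
                differential_viable=False,
                eosinophil_pct=3.0,
            )

    def test_feg_grade_derived_from_clumps(self):
        assert make_sample(clumps=3).feg_grade is FegGrade.MODERATE

    def test_inconsistent_grade_and_clumps_rejected(self):
        with pytest.raises(ValidationError, match="inconsistent"):
            SputumSample(
                patient_id="P1",
                exam_date=dt.date(2010, 1, 1),
                differential_viable=False,
                feg_clumps_per_fov=5,
                feg_grade=FegGrade.FEW,
            )

    def test_negative_dose_rejected(self):
        with pytest.raises(ValidationError):
            make_sample(ics=-100.0)


class TestPatientSeries:
    def test_dates_must_be_non_decreasing(self):
        a = make_sample(day=10)
        b = make_sample(day=0)
        with pytest.raises(ValidationError, match="ordered"):
            PatientSeries(patient_id="P1", samples=(a, b))

    def test_same_day_ties_warn_but_pass(self):
        a = make_sample(day=0)
        b = make_sample(day=0)
        with pytest.warns(UserWarning, match="same-day"):
            series = PatientSeries(patient_id="P1", samples=(a, b))
        assert len(series) == 2

    def test_mixed_patient_ids_rejected(self):
        with pytest.raises(ValidationError):
            PatientSeries(
                patient_id="P1",
                samples=(make_sample(pid="P2"),),
            )


class TestThresholdSpec:
    def test_none_grade_never_qualifies(self):
        with pytest.raises(ValidationError):
            ThresholdSpec(
                name="x",
                intact_cutoff=1.2,
                qualifying_feg_grades=frozenset({FegGrade.NONE}),
            )

    def test_comparison_operator_configurable(self):
        strict = ThresholdSpec(
            name="strict",
            intact_cutoff=1.2,
            qualifying_feg_grades=frozenset({FegGrade.FEW}),
            comparison=">",
        )
        assert not strict.intact_positive(1.2)
        assert strict.intact_positive(1.3)


class TestReadCohort:
    HEADER = (
        "patient_id,exam_date,total_cell_count_e6_per_g,viability_pct,"
        "squamous_pct,differential_viable,neutrophil_pct,eosinophil_pct,"
        "macrophage_pct,lymphocyte_pct,bronchial_epithelial_pct,"
        "feg_clumps_per_fov,feg_grade,ics_dose_mcg,ocs_dose_mg,"
        "clinical_state\n"
    )

    def _write(self, tmp_path, rows):
        path = tmp_path / "cohort.csv"
        path.write_text(self.HEADER + "".join(rows))
        return path

    def test_rows_grouped_by_patient_and_sorted(self, tmp_path):
        rows = [
            "A,2011-05-02,6.0,80,5,true,60,1.0,38,0.6,0.4,0,,500,0,stable\n",
            "B,2010-01-01,6.0,80,5,true,60,1.0,38,0.6,0.4,0,,500,0,stable\n",
            "A,2010-03-01,6.0,80,5,true,60,1.0,38,0.6,0.4,0,,500,0,stable\n",
        ]
        cohort, rejects = read_cohort(self._write(tmp_path, rows))
        assert len(rejects) == 0
        assert cohort.n_patients == 2
        sizes = {s.patient_id: len(s) for s in cohort}
        assert sizes == {"A": 2, "B": 1}
        a = next(s for s in cohort if s.patient_id == "A")
        assert a.samples[0].exam_date < a.samples[1].exam_date

    def test_invariant_violations_become_rejects_not_drops(self, tmp_path):
        rows = [
            "A,2010-01-01,6.0,80,5,true,60,1.0,38,0.6,0.4,0,,500,0,stable\n",
            # eosinophil % present but differential flagged non-viable
            "B,2010-01-01,6.0,80,5,false,,4.0,,,,2,,500,0,stable\n",
            # unparseable date
            "C,01/02/2010,6.0,80,5,true,60,1.0,38,0.6,0.4,0,,500,0,stable\n",
        ]
        cohort, rejects = read_cohort(self._write(tmp_path, rows))
        assert cohort.n_samples == 1
        assert len(rejects) == 2
        assert "reject_reason" in rejects.columns
        assert rejects["reject_reason"].str.len().min() > 0

    def test_empty_file_with_header_gives_empty_cohort(self, tmp_path):
        cohort, rejects = read_cohort(self._write(tmp_path, []))
        assert cohort.n_patients == 0 and len(rejects) == 0

    def test_missing_mandatory_column_is_schema_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("patient_id,eosinophil_pct\nA,1.0\n")
        with pytest.raises(ValidationError, match="mandatory"):
            read_cohort(path)

    def test_pre_assigned_grade_accepted_without_clumps(self, tmp_path):
        rows = [
            "A,2010-01-01,6.0,80,5,false,,,,,,,moderate,500,0,stable\n",
        ]
        cohort, rejects = read_cohort(self._write(tmp_path, rows))
        assert len(rejects) == 0
        sample = next(cohort.samples())
        assert sample.feg_grade is FegGrade.MODERATE
        assert sample.feg_clumps_per_fov is None


def test_write_read_round_trip_is_identity(tmp_path):
    from sputumeos import generate_cohort, paper_cohort_config

    cohort, _ = generate_cohort(paper_cohort_config(seed=11, n_patients=60))
    path = tmp_path / "cohort.csv"
    write_cohort(cohort, path)
    back, rejects = read_cohort(path)
    assert len(rejects) == 0
    pd.testing.assert_frame_equal(
        cohort_to_frame(cohort), cohort_to_frame(back)
    )


class TestSplitByMultiplicity:
    def test_partition_sizes(self):
        cohort = cohort_from_eos([[0.5], [3.0], [0.5, 3.0, 0.5]])
        single, multi = split_by_multiplicity(cohort)
        assert (single.n_patients, single.n_samples) == (2, 2)
        assert (multi.n_patients, multi.n_samples) == (1, 3)

    def test_all_singletons_leave_multi_empty(self):
        single, multi = split_by_multiplicity(cohort_from_eos([[1.0], [2.0]]))
        assert multi.n_patients == 0 and single.n_patients == 2

    def test_parts_disjoint_and_exhaustive(self):
        from sputumeos import generate_cohort, paper_cohort_config

        cohort, _ = generate_cohort(
            paper_cohort_config(seed=5, n_patients=200)
        )
        single, multi = split_by_multiplicity(cohort)
        ids_s = {s.patient_id for s in single}
        ids_m = {s.patient_id for s in multi}
        assert not (ids_s & ids_m)
        assert ids_s | ids_m == {s.patient_id for s in cohort}
        assert single.n_samples + multi.n_samples == cohort.n_samples


class TestSummarizeCohort:
    def test_single_value_median_and_range(self):
        table = summarize_cohort(cohort_from_eos([[0.8]]))
        row = table[table.characteristic == "eosinophil_pct"].iloc[0]
        assert row.value == 0.8
        assert row.spread == (0.8, 0.8)

    def test_binary_count_percentage(self):
        cohort = Cohort(
            [
                PatientSeries(
                    f"P{i}", (make_sample(pid=f"P{i}", ocs=d),)
                )
                for i, d in enumerate([10.0, 0.0, 0.0])
            ]
        )
        table = summarize_cohort(cohort)
        row = table[table.characteristic == "on_ocs"].iloc[0]
        assert row.value == 1
        assert row.spread == pytest.approx(33.3, abs=0.05)

    def test_empty_cohort_is_an_error(self):
        with pytest.raises(ValidationError):
            summarize_cohort(Cohort([]))

    def test_generator_targets_reproduced(self):
        """Summary medians track the generating distribution's empirical
        quantiles on a seeded cohort."""
        from sputumeos import generate_cohort, paper_cohort_config

        cohort, _ = generate_cohort(
            paper_cohort_config(seed=7, n_patients=1500)
        )
        table = summarize_cohort(cohort)
        eos = table[table.characteristic == "eosinophil_pct"].iloc[0]
        values = sorted(
            s.eosinophil_pct
            for s in cohort.samples()
            if s.eosinophil_pct is not None
        )
        import statistics

        assert eos.value == pytest.approx(statistics.median(values))
        assert eos.spread == (values[0], values[-1])
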