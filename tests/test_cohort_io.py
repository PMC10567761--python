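"""Reading, validation, plausibility filtering, segmentation and joining."""

import textwrap

import numpy as np
import pandas as pd
import pytest

from labri import (
    LOINC_CREATININE,
    LOINC_UREA,
    filter_plausible,
    join_analytes,
    read_results,
    segment_by_gender_age,
    split_by_analyte,
    write_results,
)
from labri.cohort_io import SegmentKey


def _csv(text: str, tmp_path, name="in.csv"):
    path = tmp_path / name
    path.write_text(textwrap.dedent(text).strip() + "\n", encoding="utf-8")
    return path


class TestReadResults:
    def test_well_formed_rows_pass_through(self, tmp_path):
        path = _csv(
            """
            person_id,gender,age,analyte,value,date
            P1,male,30,2160-0,0.9,2020-01-01
            P2,female,41,2160-0,0.8,2020-02-02
            P3,M,55,3094-0,14.5,2020-03-03
            """,
            tmp_path,
        )
        table, report = read_results(path)
        assert len(table) == 3
        assert report.n_dropped == 0
        assert set(table["gender"]) == {"male", "female"}
        assert table["age"].tolist() == [30, 41, 55]

    @pytest.mark.parametrize(
        "bad_row, reason",
        [
            ("P9,male,30,2160-0,,2020-01-01", "invalid_value"),
            ("P9,male,30,2160-0,abc,2020-01-01", "invalid_value"),
            ("P9,unknown,30,2160-0,0.9,2020-01-01", "unknown_gender"),
            ("P9,male,-3,2160-0,0.9,2020-01-01", "invalid_age"),
            ("P9,male,30,2160-0,0.9,not-a-date", "invalid_date"),
        ],
    )
    def test_invalid_rows_dropped_and_counted(self, tmp_path, bad_row, reason):
        path = _csv(
            f"""
            person_id,gender,age,analyte,value,date
            P1,male,30,2160-0,0.9,2020-01-01
            {bad_row}
            """,
            tmp_path,
        )
        table, report = read_results(path)
        assert len(table) == 1
        assert report.dropped == {reason: 1}

    def test_missing_column_is_fatal(self, tmp_path):
        path = _csv("person_id,gender\nP1,male", tmp_path)
        with pytest.raises(ValueError, match="missing required columns"):
            read_results(path)

    def test_column_map_renames(self, tmp_path):
        path = _csv(
            """
            pid,sex,years,loinc,result,when
            P1,female,33,3094-0,12.0,2021-06-07
            """,
            tmp_path,
        )
        table, _ = read_results(
            path,
            column_map={
                "person_id": "pid", "gender": "sex", "age": "years",
                "analyte": "loinc", "value": "result", "date": "when",
            },
        )
        assert table.loc[0, "person_id"] == "P1"
        assert table.loc[0, "value"] == 12.0

    def test_generator_csv_round_trips(self, tmp_path, small_cohort):
        table, _ = small_cohort
        path = tmp_path / "rt.csv"
        write_results(table, path)
        back, report = read_results(path)
        assert report.n_dropped == 0
        assert len(back) == len(table)
        # values survive to 6 significant digits
        expected = np.asarray(
            [float(f"{v:.6g}") for v in table["value"].to_numpy()]
        )
        np.testing.assert_allclose(back["value"].to_numpy(), expected, rtol=1e-12)


class TestFilterPlausible:
    def _table(self, values, analyte=LOINC_CREATININE):
        n = len(values)
        return pd.DataFrame(
            {
                "person_id": [f"P{i}" for i in range(n)],
                "gender": "male", "age": 40, "analyte": analyte,
                "value": values, "date": "2020-01-01",
            }
        )

    def test_exceeding_threshold_removed(self):
        out, removed = filter_plausible(self._table([0.9, 26.0, 1.1]))
        assert out["value"].tolist() == [0.9, 1.1]
        assert removed == 1

    def test_empty_table(self):
        out, removed = filter_plausible(self._table([]))
        assert out.empty and removed == 0

    def test_boundary_is_inclusive(self):
        out, removed = filter_plausible(self._table([25.0, 25.0]))
        assert removed == 0 and len(out) == 2

    def test_nonpositive_values_always_removed(self):
        out, removed = filter_plausible(self._table([0.0, -1.0, 0.9]))
        assert removed == 2
        assert out["value"].tolist() == [0.9]

    def test_unknown_analyte_retained_or_dropped(self):
        t = self._table([5.0], analyte="9999-9")
        kept, r1 = filter_plausible(t)
        assert r1 == 0 and len(kept) == 1
        dropped, r2 = filter_plausible(t, on_missing="drop")
        assert r2 == 1 and dropped.empty

    def test_idempotent(self, small_cohort):
        table, _ = small_cohort
        once, n1 = filter_plausible(table)
        twice, n2 = filter_plausible(once)
        assert n2 == 0
        pd.testing.assert_frame_equal(once, twice)


class TestSegmentation:
    def test_counts_per_segment(self):
        t = pd.DataFrame(
            {
                "person_id": [f"P{i}" for i in range(10)],
                "gender": ["male"] * 6 + ["female"] * 4,
                "age": [30] * 6 + [31] * 4,
                "analyte": LOINC_CREATININE,
                "value": 1.0,
                "date": "2020-01-01",
            }
        )
        seg = segment_by_gender_age(t, min_n=1)
        assert seg.segments[SegmentKey("male", 30)].size == 6
        assert seg.segments[SegmentKey("female", 31)].size == 4

    def test_small_segments_flagged_unreliable(self):
        t = pd.DataFrame(
            {
                "person_id": "P", "gender": "male", "age": 50,
                "analyte": LOINC_CREATININE,
                "value": np.ones(80), "date": "2020-01-01",
            }
        )
        seg = segment_by_gender_age(t, min_n=120)
        assert seg.unreliable == [SegmentKey("male", 50)]
        assert list(seg.reliable_items()) == []

    def test_partition_is_exact(self, small_cohort):
        table, _ = small_cohort
        sub = split_by_analyte(table)[LOINC_UREA]
        seg = segment_by_gender_age(sub)
        assert seg.n_total == len(sub)

    def test_mixed_analytes_rejected(self, small_cohort):
        table, _ = small_cohort
        with pytest.raises(ValueError, match="single-analyte"):
            segment_by_gender_age(table)


class TestJoinAnalytes:
    def _tables(self):
        a = pd.DataFrame(
            {
                "person_id": ["P1", "P2"], "gender": "male", "age": 30,
                "analyte": LOINC_CREATININE, "value": [0.9, 1.0],
                "date": "2020-01-01",
            }
        )
        b = pd.DataFrame(
            {
                "person_id": ["P1"], "gender": "male", "age": 30,
                "analyte": LOINC_UREA, "value": [14.0], "date": "2020-01-01",
            }
        )
        return a, b

    def test_matched_visit_produces_joint_record(self):
        a, b = self._tables()
        joint, report = join_analytes(a, b)
        assert len(joint) == 1
        assert joint.loc[0, LOINC_CREATININE] == 0.9
        assert joint.loc[0, LOINC_UREA] == 14.0
        assert report[f"unmatched_{LOINC_CREATININE}"] == 1

    def test_symmetric_up_to_column_order(self):
        a, b = self._tables()
        j1, _ = join_analytes(a, b)
        j2, _ = join_analytes(b, a)
        pd.testing.assert_frame_equal(j1, j2[j1.columns])

    def test_duplicates_keep_first(self):
        a, b = self._tables()
        a2 = pd.concat([a, a.iloc[[0]].assign(value=99.0)], ignore_index=True)
        joint, report = join_analytes(a2, b)
        assert joint.loc[0, LOINC_CREATININE] == 0.9
        assert report[f"duplicates_{LOINC_CREATININE}"] == 1

    def test_same_analyte_rejected(self):
        a, _ = self._tables()
        with pytest.raises(ValueError, match="distinct analytes"):
            join_analytes(a, a.copy())

    def test_every_visit_yields_one_joint_record(self, small_cohort):
        table, truth = small_cohort
        per = split_by_analyte(table)
        joint, _ = join_analytes(per[LOINC_CREATININE], per[LOINC_UREA])
        n_visits = len(table) // 2  # both analytes measured at every visit
        assert len(joint) == n_visits
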