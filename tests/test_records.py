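"""Record parsing, cleaning, normalization, windowing and splitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spo2former import (
    PatientRecord,
    drop_missing,
    minmax_normalize,
    read_record,
    read_records,
    split_holdout,
    window_record,
    write_record,
)
from spo2former.records import EmptyRecordError, RecordParseError, Segment, SplitError


def make_record(spo2, labels, pid="t"):
    return PatientRecord(patient_id=pid, spo2=np.array(spo2, dtype=float), labels=np.array(labels))


class TestCSV:
    def test_direct_parse(self, tmp_path):
        (tmp_path / "a.csv").write_text("t_s,spo2,label\n0,96,0\n1,95,0\n2,92,1\n")
        rec = read_record(tmp_path / "a.csv")
        assert rec.patient_id == "a"
        assert len(rec) == 3
        assert rec.labels.tolist() == [0, 0, 1]
        assert rec.spo2.tolist() == [96.0, 95.0, 92.0]

    def test_empty_cell_becomes_missing(self, tmp_path):
        (tmp_path / "a.csv").write_text("t_s,spo2,label\n0,96,0\n1,,0\n2,92,1\n")
        rec = read_record(tmp_path / "a.csv")
        assert np.isnan(rec.spo2[1]) and not np.isnan(rec.spo2[[0, 2]]).any()

    @pytest.mark.parametrize(
        "body,fragment",
        [
            ("t_s,spo2,label\n0,96,0\n1,95,2\n", "label"),
            ("t_s,spo2,label\n0,abc,0\n", "spo2"),
            ("t_s,spo2,label\n0,96,0\n0,95,0\n", "t_s"),
            ("t_s,spo2,label\n0,150,0\n", "spo2"),
        ],
        ids=["bad-label", "non-numeric", "non-increasing-t", "out-of-range"],
    )
    def test_malformed_rows_name_the_problem(self, tmp_path, body, fragment):
        p = tmp_path / "bad.csv"
        p.write_text(body)
        with pytest.raises(RecordParseError, match=fragment):
            read_record(p)

    def test_roundtrip_cohort_and_manifest(self, tmp_path, tiny_cohort):
        for rec in tiny_cohort:
            write_record(rec, tmp_path)
        back = read_records(tmp_path)
        assert [r.patient_id for r in back] == [r.patient_id for r in tiny_cohort]
        manifest = tmp_path / "manifest.txt"
        manifest.write_text("\n".join(f"{r.patient_id}.csv" for r in tiny_cohort[:2]))
        assert len(read_records(manifest)) == 2


class TestDropMissing:
    def test_removes_aligned_pairs(self):
        rec = make_record([96, np.nan, 92], [0, 0, 1])
        out, removed = drop_missing(rec)
        assert removed == 1
        assert out.spo2.tolist() == [96, 92]
        assert out.labels.tolist() == [0, 1]

    def test_identity_when_clean(self):
        rec = make_record([96, 95], [0, 1])
        out, removed = drop_missing(rec)
        assert removed == 0 and out is rec

    def test_all_missing_errors(self):
        with pytest.raises(EmptyRecordError):
            drop_missing(make_record([np.nan, np.nan], [0, 0]))

    def test_order_preserved_and_lengths_match(self, short_record):
        out, removed = drop_missing(short_record)
        assert len(out.spo2) == len(out.labels) == len(short_record) - removed
        keep = ~np.isnan(short_record.spo2)
        assert np.array_equal(out.spo2, short_record.spo2[keep])
        assert np.array_equal(out.labels, short_record.labels[keep])


class TestMinMaxNormalize:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([90, 95, 100], [0.0, 0.5, 1.0]),
            ([97, 97, 97], [0.0, 0.0, 0.0]),
            ([88, 91, 94, 96], [0.0, 0.375, 0.75, 1.0]),
        ],
    )
    def test_worked_examples(self, values, expected):
        assert np.allclose(minmax_normalize(values), expected)

    @given(
        st.lists(
            st.floats(min_value=0, max_value=100, allow_nan=False).map(lambda x: round(x, 3)),
            min_size=2,
            max_size=50,
        )
    )
    @settings(deadline=None, max_examples=100)
    def test_range_and_rank_order(self, values):
        out = minmax_normalize(values)
        assert out.min() >= 0.0 and out.max() <= 1.0
        v = np.asarray(values)
        if v.max() > v.min():
            assert out.min() == 0.0 and out.max() == 1.0
            assert np.array_equal(np.argsort(out, kind="stable"), np.argsort(v, kind="stable"))

    @given(
        st.lists(
            st.floats(min_value=-50, max_value=50, allow_nan=False).map(lambda x: round(x, 3)),
            min_size=2,
            max_size=30,
        ),
        st.floats(min_value=0.1, max_value=10),
        st.floats(min_value=-20, max_value=20),
    )
    @settings(deadline=None, max_examples=100)
    def test_affine_invariance(self, values, a, b):
        v = np.asarray(values)
        assert np.allclose(minmax_normalize(a * v + b), minmax_normalize(v), atol=1e-9)


class TestWindowing:
    def test_exact_tiling(self, clean_short_record):
        rec = clean_short_record
        segs = window_record(rec, 120, 120)
        assert len(segs) == len(rec) // 120
        # concatenated raw windows reconstruct the record prefix
        raw = window_record(rec, 120, 120, normalize=False)
        prefix = np.concatenate([s.values for s in raw])
        assert np.array_equal(prefix, rec.spo2[: len(prefix)])

    def test_overlap_counting_formula(self, clean_short_record):
        t = len(clean_short_record)
        segs = window_record(clean_short_record, 120, 60)
        assert len(segs) == (t - 120) // 60 + 1
        assert [s.start_s for s in segs[:3]] == [0, 60, 120]

    def test_too_short_record_warns_and_returns_empty(self):
        rec = make_record(list(np.linspace(90, 100, 100)), [0] * 100)
        with pytest.warns(UserWarning):
            assert window_record(rec, 120) == []

    def test_each_window_normalized_independently(self, clean_short_record):
        for seg in window_record(clean_short_record, 60):
            assert seg.values.min() == 0.0 and seg.values.max() == 1.0
            assert seg.length_s == 60


class TestSplitHoldout:
    @staticmethod
    def _segments(n_patients=10, per_patient=10):
        return [
            Segment(values=np.zeros(5), labels=np.zeros(5, dtype=int), patient_id=f"p{i}", start_s=j)
            for i in range(n_patients)
            for j in range(per_patient)
        ]

    def test_grouped_split_is_patient_disjoint(self):
        segs = self._segments()
        train, test = split_holdout(segs, 0.2, mode="patient-grouped", seed=3)
        train_pat = {s.patient_id for s in train}
        test_pat = {s.patient_id for s in test}
        assert not (train_pat & test_pat)
        assert len(test_pat) == 2 and len(train_pat) == 8

    def test_segment_mode_partition(self):
        segs = self._segments(10, 10)
        train, test = split_holdout(segs, 0.2, mode="segment-random", seed=0)
        assert len(test) == 20 and len(train) == 80
        assert {id(s) for s in train} | {id(s) for s in test} == {id(s) for s in segs}

    @pytest.mark.parametrize("mode", ["segment-random", "patient-grouped"])
    def test_deterministic_given_seed(self, mode):
        segs = self._segments()
        a = split_holdout(segs, 0.3, mode=mode, seed=42)
        b = split_holdout(segs, 0.3, mode=mode, seed=42)
        assert [id(s) for s in a[0]] == [id(s) for s in b[0]]
        assert [id(s) for s in a[1]] == [id(s) for s in b[1]]

    def test_grouped_needs_two_patients(self):
        segs = [s for s in self._segments(1, 5)]
        with pytest.raises(SplitError):
            split_holdout(segs, 0.2, mode="patient-grouped")
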