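"""Record I/O: dialects, label alignment, and AHI grouping."""

import numpy as np
import pytest

from apnea_bof import (
    EcgRecord,
    GroupRule,
    RecordMeta,
    ahi_rule,
    group_records,
    read_corpus,
    read_record,
    write_record,
)
from apnea_bof.ecg_io import _write_annotations, _ANN_NORMAL, _ANN_APNEA
from apnea_bof.errors import AlignmentError, FormatError, InsufficientMetadataError


def _make_record(n_minutes=2, fs=100.0, labels=None, stages=None):
    rng = np.random.default_rng(0)
    n = int(n_minutes * 60 * fs)
    return EcgRecord(
        record_id="r00",
        samples=np.round(rng.normal(0, 0.5, n), 4),
        fs=fs,
        labels=labels or ["N", "A"][:n_minutes] * (n_minutes // 2 or 1),
        stage_labels=stages,
    )


class TestCsvDialect:
    def test_round_trip_preserves_signal_and_labels(self, tmp_path):
        rec = _make_record(stages=["REM", "NREM"])
        write_record(rec, tmp_path / "r00", dialect="csv")
        back = read_record(tmp_path / "r00", dialect="csv")
        np.testing.assert_allclose(back.samples, rec.samples, atol=1e-6)
        assert back.fs == rec.fs
        assert back.labels == rec.labels
        assert back.stage_labels == rec.stage_labels
        # idempotence: a second write/read cycle is exact
        write_record(back, tmp_path / "r00b", dialect="csv")
        again = read_record(tmp_path / "r00b", dialect="csv")
        np.testing.assert_array_equal(again.samples, back.samples)

    def test_one_minute_record(self, tmp_path):
        rec = EcgRecord("m", np.zeros(6000), 100.0, ["N"])
        write_record(rec, tmp_path / "m", dialect="csv")
        back = read_record(tmp_path / "m", dialect="csv")
        assert back.n_minutes == 1 and len(back.samples) == 6000

    def test_trailing_partial_minute_dropped(self, tmp_path):
        # 1.5 minutes of signal, one label: final 30 s discarded
        rec = EcgRecord("t", np.zeros(6000), 100.0, ["A"])
        p = write_record(rec, tmp_path / "t", dialect="csv")
        t = np.arange(9000) / 100.0
        with open(p, "w") as fh:
            fh.write("t_sec,mv\n")
            for ti in t:
                fh.write(f"{ti:.6f},0.1\n")
        back = read_record(tmp_path / "t", dialect="csv")
        assert back.labels == ["A"]
        assert len(back.samples) == 6000

    def test_label_deficit_raises_alignment_error(self, tmp_path):
        write_record(EcgRecord("d", np.zeros(6000), 100.0, ["N"]), tmp_path / "d")
        t = np.arange(18000) / 100.0  # 3 min of signal, 1 label
        with open(tmp_path / "d.csv", "w") as fh:
            fh.write("t_sec,mv\n")
            fh.writelines(f"{ti:.6f},0.0\n" for ti in t)
        with pytest.raises(AlignmentError, match="2 minutes"):
            read_record(tmp_path / "d", dialect="csv")

    def test_missing_sidecar_is_format_error(self, tmp_path):
        write_record(_make_record(), tmp_path / "x", dialect="csv")
        (tmp_path / "x.labels").unlink()
        with pytest.raises(FormatError, match="sidecar"):
            read_record(tmp_path / "x", dialect="csv")


class TestWfdbDialect:
    def test_round_trip_idempotent(self, tmp_path):
        rec = _make_record(fs=100.0)
        write_record(rec, tmp_path / "w", dialect="wfdb")
        once = read_record(tmp_path / "w", dialect="wfdb")
        write_record(once, tmp_path / "w2", dialect="wfdb")
        twice = read_record(tmp_path / "w2", dialect="wfdb")
        np.testing.assert_array_equal(once.samples, twice.samples)
        assert once.fs == twice.fs == 100.0
        assert once.labels == twice.labels == rec.labels
        # quantization error bounded by half an ADC unit at gain 200
        assert np.abs(once.samples - rec.samples).max() <= 0.5 / 200 + 1e-12

    def test_label_coverage_invariant(self, tmp_path):
        rec = _make_record(n_minutes=4)
        write_record(rec, tmp_path / "c", dialect="wfdb")
        back = read_record(tmp_path / "c", dialect="wfdb")
        spm = int(60 * back.fs)
        assert len(back.labels) * spm <= len(back.samples) < (len(back.labels) + 1) * spm

    def test_annotation_deficit_raises(self, tmp_path):
        rec = _make_record(n_minutes=4)
        write_record(rec, tmp_path / "a", dialect="wfdb")
        # overwrite annotations with a single minute mark: 3-minute deficit
        _write_annotations(tmp_path / "a.apn", [(0, _ANN_NORMAL)])
        with pytest.raises(AlignmentError, match="3 minutes"):
            read_record(tmp_path / "a", dialect="wfdb")

    def test_non_normal_symbols_map_to_apnea(self, tmp_path):
        rec = _make_record(n_minutes=2, labels=["N", "N"])
        write_record(rec, tmp_path / "s", dialect="wfdb")
        spm = 6000
        # hypopnea-family code (here: any non-N code, e.g. 9) merges into A
        _write_annotations(tmp_path / "s.apn", [(0, _ANN_APNEA), (spm, 9)])
        back = read_record(tmp_path / "s", dialect="wfdb")
        assert back.labels == ["A", "A"]

    def test_missing_header_is_format_error(self, tmp_path):
        with pytest.raises(FormatError, match="header"):
            read_record(tmp_path / "nope", dialect="wfdb")


class TestCorpusAndGrouping:
    def test_read_corpus_honours_exclusions(self, tmp_path):
        for rid in ("a01", "b05", "c05"):
            rec = _make_record()
            rec.record_id = rid
            write_record(rec, tmp_path / rid, dialect="csv")
        records = read_corpus(tmp_path, dialect="csv", exclude=["b05", "c05"])
        assert [r.record_id for r in records] == ["a01"]

    def test_grouping_matches_brute_force_filter(self):
        ahis = [5, 15, 25, 35, 45, 55, 65, 75, 85, 95]
        metadata = [(f"s{i}", RecordMeta(ahi=a)) for i, a in enumerate(ahis)]
        groups = group_records(metadata, [ahi_rule("sa", lo=None, hi=None),
                                          ahi_rule("ge10", lo=9.999)])
        brute = [rid for rid, m in metadata if m.ahi >= 10]
        assert list(groups[1].record_ids) == brute
        assert len(groups[1].record_ids) == 9

    def test_severity_band_rule_and_overlap(self):
        metadata = [("x", RecordMeta(ahi=40)), ("y", RecordMeta(ahi=50))]
        groups = group_records(
            metadata, [ahi_rule("A", lo=30, hi=45), ahi_rule("C")]
        )
        assert groups[0].record_ids == ("x",)
        assert set(groups[1].record_ids) == {"x", "y"}  # whole corpus overlaps

    def test_empty_metadata_gives_empty_groups(self):
        groups = group_records([], [ahi_rule("any", lo=10)])
        assert groups[0].record_ids == ()

    def test_missing_ahi_raises_listing_ids(self):
        metadata = [("ok", RecordMeta(ahi=20)), ("bad", RecordMeta())]
        with pytest.raises(InsufficientMetadataError, match="bad"):
            group_records(metadata, [ahi_rule("ge10", lo=10)])


def test_record_validation_rejects_bad_labels():
    with pytest.raises(ValueError, match="unknown labels"):
        EcgRecord("x", np.zeros(6000), 100.0, ["N", "Z"][:1] + ["Z"])
    with pytest.raises(ValueError, match="finite"):
        EcgRecord("x", np.array([np.nan] * 6000), 100.0, ["N"])
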