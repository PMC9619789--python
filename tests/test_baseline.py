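"""Wide-to-long traversal, field classification and the two-step mapping."""

import pandas as pd
import pytest

from biobank_omop.baseline import (BaselineFieldMeta, LongRecord,
                                   PersonRejection, build_person,
                                   classify_field, load_field_dictionary,
                                   run_baseline_etl, transform_baseline_record,
                                   wide_to_long)
from biobank_omop.cdm import CdmStore
from biobank_omop.config import PipelineConfig
from biobank_omop.runlog import EtlLog


@pytest.fixture()
def field_meta():
    return {
        20002: BaselineFieldMeta(20002, "categorical"),
        4080: BaselineFieldMeta(4080, "numeric", unit="mm[Hg]"),
        2443: BaselineFieldMeta(2443, "boolean"),
    }


class TestWideToLong:
    def test_one_record_per_nonempty_clinical_cell(self, field_meta):
        wide = pd.DataFrame([{"eid": "A", "53-0.0": "2008-01-01",
                              "20002-0.0": "1065", "20002-0.1": "1234",
                              "4080-0.0": "136", "2443-0.0": ""}])
        recs = list(wide_to_long(wide, field_meta))
        assert len(recs) == 3
        assert all(r.event_date == "2008-01-01" for r in recs)
        arrays = sorted((r.field_id, r.array_index) for r in recs)
        assert arrays == [(4080, 0), (20002, 0), (20002, 1)]

    def test_all_empty_row_yields_no_records(self, field_meta):
        wide = pd.DataFrame([{"eid": "A", "53-0.0": "2008-01-01",
                              "20002-0.0": "", "4080-0.0": ""}])
        assert list(wide_to_long(wide, field_meta)) == []

    def test_unparseable_header_raises_with_column_name(self, field_meta):
        wide = pd.DataFrame([{"eid": "A", "bogus": "1"}])
        with pytest.raises(ValueError, match="bogus"):
            list(wide_to_long(wide, field_meta))

    def test_instance_date_matches_record_instance(self, field_meta):
        wide = pd.DataFrame([{"eid": "A", "53-0.0": "2008-01-01",
                              "53-1.0": "2012-06-01",
                              "20002-0.0": "1065", "20002-1.0": "1234"}])
        recs = {(r.instance): r.event_date
                for r in wide_to_long(wide, field_meta)}
        assert recs == {0: "2008-01-01", 1: "2012-06-01"}


class TestClassifyField:
    def test_numeric_field_with_numeric_value(self, field_meta):
        assert classify_field(field_meta[4080], "136") == "numeric"

    def test_numeric_field_with_garbage_quarantines(self, field_meta):
        assert classify_field(field_meta[4080], "high") == "quarantine"

    def test_boolean_field(self, field_meta):
        assert classify_field(field_meta[2443], "1") == "boolean"

    def test_unknown_field_is_unmapped(self):
        assert classify_field(None, "7") == "unmapped"


class TestTransform:
    def test_worked_hypertension_example(self, vocab_store):
        """Field 20002 value 1065 maps in two steps: event concept
        'history of clinical finding' 4214956 plus value concept
        'hypertensive disorder' 316866."""
        row = transform_baseline_record(
            LongRecord("A", 20002, 0, 0, "1065", "2008-01-01"), vocab_store)
        assert row.table == "observation"
        assert row.event_concept_id == 4214956
        assert row.value_as_concept_id == 316866
        assert row.source_value == "20002-1065"

    def test_unmapped_field_concept_zero_fallback(self, vocab_store):
        row = transform_baseline_record(
            LongRecord("A", 99999, 0, 0, "7", "2008-01-01"), vocab_store)
        assert (row.table, row.event_concept_id, row.source_value) == \
            ("observation", 0, "99999")

    def test_numeric_field_becomes_measurement_with_unit(self, vocab_store,
                                                         field_meta):
        row = transform_baseline_record(
            LongRecord("A", 4080, 0, 0, "136", "2008-01-01"), vocab_store,
            meta=field_meta[4080])
        assert row.table == "measurement"
        assert row.value_as_number == 136.0
        assert row.unit_concept_id == 8876  # fixture's mm[Hg]

    def test_negative_boolean_emits_nothing(self, vocab_store, field_meta):
        log = EtlLog()
        row = transform_baseline_record(
            LongRecord("A", 2443, 0, 0, "0", "2008-01-01"), vocab_store,
            meta=field_meta[2443], etl_log=log)
        assert row is None
        assert log.streams["baseline"].excluded["negative_boolean"] == 1

    def test_nonnumeric_value_quarantined_not_fatal(self, vocab_store,
                                                    field_meta):
        log = EtlLog()
        row = transform_baseline_record(
            LongRecord("A", 4080, 0, 0, "high", "2008-01-01"), vocab_store,
            meta=field_meta[4080], etl_log=log)
        assert row is None
        assert log.streams["baseline"].quarantined["nonnumeric_value"] == 1


class TestBuildPerson:
    def test_accepted_person(self, vocab_store):
        row = pd.Series({"eid": "A", "34-0.0": "1955", "31-0.0": "0",
                         "21000-0.0": "1001"})
        p = build_person(row, vocab_store, 1)
        assert p.year_of_birth == 1955
        assert p.gender_concept_id == 8532

    def test_missing_year_of_birth_rejects(self, vocab_store):
        row = pd.Series({"eid": "A", "34-0.0": "", "31-0.0": "1"})
        p = build_person(row, vocab_store, 1)
        assert isinstance(p, PersonRejection)
        assert p.reason == "missing_year_of_birth"


class TestRunBaselineEtl:
    def _write(self, tmp_path, rows, header):
        p = tmp_path / "baseline.csv"
        pd.DataFrame(rows, columns=header).to_csv(p, index=False)
        return p

    def test_rejection_cascades_to_zero_rows(self, tmp_path, vocab_store):
        header = ["eid", "31-0.0", "34-0.0", "53-0.0", "20002-0.0"]
        path = self._write(tmp_path, [
            ["A", "0", "1950", "2008-01-01", "1065"],
            ["B", "1", "", "2008-01-01", "1065"],      # missing yob
        ], header)
        cdm = CdmStore()
        log = EtlLog()
        meta = {20002: BaselineFieldMeta(20002, "categorical")}
        ids, rejections = run_baseline_etl(path, meta, vocab_store, cdm,
                                           PipelineConfig(), log)
        assert rejections == {"B": "missing_year_of_birth"}
        assert len(cdm.rows("person")) == 1
        assert all(r["person_id"] == ids["A"]
                   for t in cdm.tables.values() for r in t)
        assert log.streams["baseline"].rejected_person == 1

    def test_withdrawn_participant_excluded_before_transformation(
            self, tmp_path, vocab_store):
        header = ["eid", "31-0.0", "34-0.0", "53-0.0", "20002-0.0"]
        path = self._write(tmp_path, [
            ["A", "0", "1950", "2008-01-01", "1065"],
            ["W", "0", "1950", "2008-01-01", "1065"],
        ], header)
        cdm = CdmStore()
        meta = {20002: BaselineFieldMeta(20002, "categorical")}
        ids, rejections = run_baseline_etl(path, meta, vocab_store, cdm,
                                           withdrawals=["W"])
        assert rejections == {"W": "withdrawn_consent"}
        assert list(ids) == ["A"]

    def test_conservation_identity(self, small_run):
        out, manifest = small_run
        s = manifest.streams["baseline"]
        assert s["conserved"]
        assert s["input"] == (s["emitted"]
                              + sum(s["excluded"].values())
                              + sum(s["quarantined"].values())
                              + s["rejected_person_rows"])
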