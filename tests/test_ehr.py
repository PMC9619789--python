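"""EHR stream transforms: special values, routing, derived tables."""

import random
from datetime import date, timedelta
from pathlib import Path

import pytest

from biobank_omop.cdm import CdmStore
from biobank_omop.config import PipelineConfig
from biobank_omop.ehr import (CovidTest, DeathRecord, GpEvent,
                              HospitalEpisode, Prescription,
                              build_observation_periods, derive_drug_eras,
                              filter_special_values, run_ehr_etl,
                              transform_covid_test, transform_death,
                              transform_gp_event, transform_hospital_episode,
                              transform_prescription)
from biobank_omop.runlog import EtlLog
from biobank_omop.synthetic import CONCEPTS


def _gp(code, vocab="SNOMED", **kw):
    defaults = dict(source_person_id="A", provider="EMIS",
                    event_date="2015-01-01")
    defaults.update(kw)
    return GpEvent(code=code, vocabulary=vocab, **defaults)


class TestSpecialValues:
    @pytest.mark.parametrize("code,reason", [
        ("-99", "missing_code"), ("-3", "invalid_code"),
        ("-1", "sensitive_code"), ("-2", "rare_occupation"),
        ("−3", "invalid_code"),  # unicode minus as seen in extracts
    ])
    def test_special_codes_excluded_with_reason(self, code, reason):
        kept, excluded = filter_special_values([_gp(code)])
        assert kept == []
        assert excluded[0][1] == reason

    def test_ordinary_code_kept(self):
        kept, excluded = filter_special_values([_gp("38341003")])
        assert len(kept) == 1 and excluded == []


class TestGpEvents:
    def test_standard_snomed_condition_routes_to_condition_table(
            self, vocab_store):
        row = transform_gp_event(_gp("38341003"), vocab_store)
        assert row.table == "condition_occurrence"
        assert row.event_concept_id == 316866

    def test_ctv3_cross_map_resolves_through_selection(self, vocab_store):
        row = transform_gp_event(_gp("XE0Uc", vocab="CTV3", provider="TPP"),
                                 vocab_store)
        assert row.event_concept_id == 316866

    def test_proprietary_covid_code_maps_via_custom_table(self, vocab_store):
        row = transform_gp_event(_gp("Y20d1", vocab="TPP", provider="TPP"),
                                 vocab_store)
        assert row.event_concept_id == CONCEPTS["covid19"]

    def test_unmapped_code_falls_back_to_observation(self, vocab_store):
        row = transform_gp_event(_gp("X73lE", vocab="CTV3", provider="TPP"),
                                 vocab_store)
        assert (row.table, row.event_concept_id) == ("observation", 0)
        assert row.source_value == "X73lE"


class TestPrescriptions:
    def test_mapped_dmd_code_lands_in_drug_exposure(self, vocab_store):
        dmd = [c for (v, c) in vocab_store.maps if v == "DMD"][0]
        row = transform_prescription(
            Prescription("A", "EMIS", dmd, "2015-01-01"), vocab_store)
        assert row.table == "drug_exposure"
        assert row.event_concept_id > 0

    def test_unmapped_dmd_stays_in_drug_table_with_concept_zero(
            self, vocab_store):
        row = transform_prescription(
            Prescription("A", "EMIS", "00000000000", "2015-01-01"),
            vocab_store)
        assert (row.table, row.event_concept_id) == ("drug_exposure", 0)

    def test_strict_policy_excludes_out_of_period_issue(self, vocab_store):
        cfg = PipelineConfig(allow_out_of_period=False)
        log = EtlLog()
        row = transform_prescription(
            Prescription("A", "EMIS", "123", "2001-01-01"), vocab_store,
            cfg, period=("2006-01-01", "2020-01-01"), etl_log=log)
        assert row is None
        assert log.streams["gp_scripts"].excluded["out_of_observation"] == 1


class TestHospitalEpisodes:
    def test_visit_plus_routed_rows(self, vocab_store):
        ep = HospitalEpisode(
            "A", "S1", "2015-01-01", "2015-01-05",
            diagnoses=(("U07.1", "ICD10", True), ("X99.9", "ICD10", False)),
            procedures=(("A01.1", "OPCS4", "2015-01-02"),))
        visit, rows, attr_rows = transform_hospital_episode(ep, vocab_store)
        assert visit["start"] == "2015-01-01"
        assert len(rows) == 3
        primary = rows[0]
        assert primary.event_concept_id == CONCEPTS["covid19"]
        assert primary.table == "condition_occurrence"

    def test_reversed_dates_quarantine_episode(self, vocab_store):
        ep = HospitalEpisode("A", "S1", "2015-01-05", "2015-01-01")
        log = EtlLog()
        assert transform_hospital_episode(ep, vocab_store,
                                          etl_log=log) is None
        assert log.streams["hospital_episodes"].quarantined["date_order"] == 1

    def test_unmapped_procedure_code_becomes_observation(self, vocab_store):
        ep = HospitalEpisode("A", "S1", "2015-01-01", "2015-01-02",
                             procedures=(("999", "OPCS3", ""),))
        _, rows, _ = transform_hospital_episode(ep, vocab_store)
        assert (rows[0].table, rows[0].event_concept_id) == \
            ("observation", 0)

    def test_episode_attributes_become_observations(self, vocab_store):
        ep = HospitalEpisode("A", "S1", "2015-01-01", "2015-01-02",
                             admission_method="AD01",
                             discharge_destination="DI01")
        _, _, attr_rows = transform_hospital_episode(ep, vocab_store)
        assert len(attr_rows) == 2
        assert all(r.table == "observation" for r in attr_rows)


class TestDeath:
    def test_three_causes_give_one_death_row_plus_two(self, vocab_store):
        rec = DeathRecord("A", "2020-05-01",
                          causes=(("U07.1", True), ("I21.0", False),
                                  ("J18.9", False)))
        death_row, extra = transform_death(rec, vocab_store)
        assert death_row.table == "death"
        assert death_row.event_concept_id == CONCEPTS["covid19"]
        assert len(extra) == 2

    def test_unmapped_cause_keeps_death_row_with_concept_zero(
            self, vocab_store):
        rec = DeathRecord("A", "2020-05-01", causes=(("Q99.9", True),))
        death_row, _ = transform_death(rec, vocab_store)
        assert death_row.event_concept_id == 0

    def test_conflicting_death_dates_keep_earliest(self, tmp_path,
                                                   vocab_store):
        (tmp_path / "death.csv").write_text(
            "eid,date_of_death,cause_icd10,underlying_flag\n"
            "A,2020-05-02,U07.1,1\n"
            "A,2020-05-01,U07.1,1\n", encoding="utf-8")
        cdm = CdmStore()
        log = EtlLog()
        run_ehr_etl(tmp_path, vocab_store, cdm, {"A": 1}, etl_log=log)
        assert len(cdm.rows("death")) == 1
        assert cdm.rows("death")[0]["death_date"] == "2020-05-01"
        assert log.streams["death"].excluded["conflicting_death_date"] == 1


class TestCovidTests:
    def test_positive_test_measurement_row(self, vocab_store):
        meas, specimen = transform_covid_test(
            CovidTest("A", "2020-06-01", "swab_nasal", "positive"),
            vocab_store)
        assert meas.table == "measurement"
        assert meas.event_concept_id == CONCEPTS["sars_cov2_measurement"]
        assert meas.value_as_concept_id == CONCEPTS["positive"]
        assert specimen.table == "specimen"

    def test_negative_test_symmetric(self, vocab_store):
        meas, _ = transform_covid_test(
            CovidTest("A", "2020-06-01", "swab_nasal", "negative"),
            vocab_store)
        assert meas.value_as_concept_id == CONCEPTS["negative"]

    def test_unknown_result_token_quarantined(self, vocab_store):
        log = EtlLog()
        out = transform_covid_test(
            CovidTest("A", "2020-06-01", "swab_nasal", "inconclusive"),
            vocab_store, etl_log=log)
        assert out is None
        assert log.streams["covid_tests"].quarantined["unknown_result"] == 1

    def test_two_tests_same_day_both_kept(self, tmp_path, vocab_store):
        (tmp_path / "covid_tests.csv").write_text(
            "eid,specdate,spectype,result\n"
            "A,2020-06-01,swab_nasal,positive\n"
            "A,2020-06-01,swab_nasal,positive\n", encoding="utf-8")
        cdm = CdmStore()
        run_ehr_etl(tmp_path, vocab_store, cdm, {"A": 1})
        assert len(cdm.rows("measurement")) == 2


class TestObservationPeriods:
    def test_min_max_span(self):
        periods = build_observation_periods(
            {1: ["2019-05-05", "2006-01-01", "2010-03-03"]})
        assert (periods[0].period_start, periods[0].period_end) == \
            ("2006-01-01", "2019-05-05")

    def test_single_event_zero_length_period(self):
        p = build_observation_periods({1: ["2010-01-01"]})[0]
        assert p.period_start == p.period_end == "2010-01-01"


def _exposure(pid, cid, start, end=None):
    return {"person_id": pid, "drug_concept_id": cid,
            "drug_exposure_start_date": start.isoformat(),
            "drug_exposure_end_date": (end or start).isoformat()}


def era_oracle(spans, gap):
    """Independent interval-union oracle: two exposures chain when their
    gap is at most ``gap`` days; eras are connected components."""
    spans = sorted(spans)
    comps = []
    for s, e in spans:
        placed = False
        for comp in comps:
            if any(not (s > ce + timedelta(days=gap)
                        or e < cs - timedelta(days=gap))
                   for cs, ce in comp):
                comp.append((s, e))
                placed = True
                break
        if not placed:
            comps.append([(s, e)])
    # merge components that became connected transitively
    changed = True
    while changed:
        changed = False
        for i in range(len(comps)):
            for j in range(i + 1, len(comps)):
                if any(not (s1 > e2 + timedelta(days=gap)
                            or e1 < s2 - timedelta(days=gap))
                       for s1, e1 in comps[i] for s2, e2 in comps[j]):
                    comps[i] += comps.pop(j)
                    changed = True
                    break
            if changed:
                break
    return sorted((min(s for s, _ in c), max(e for _, e in c))
                  for c in comps)


class TestDrugEras:
    def test_exposures_within_gap_merge(self):
        rows = [_exposure(1, 5, date(2015, 1, 1)),
                _exposure(1, 5, date(2015, 1, 11))]
        assert len(derive_drug_eras(rows, gap_days=30)) == 1

    def test_exposures_beyond_gap_split(self):
        rows = [_exposure(1, 5, date(2015, 1, 1)),
                _exposure(1, 5, date(2015, 3, 2))]
        assert len(derive_drug_eras(rows, gap_days=30)) == 2

    def test_single_exposure_era_equals_span(self):
        rows = [_exposure(1, 5, date(2015, 1, 1), date(2015, 1, 14))]
        era = derive_drug_eras(rows, gap_days=30)[0]
        assert era["drug_era_start_date"] == "2015-01-01"
        assert era["drug_era_end_date"] == "2015-01-14"

    def test_concept_zero_exposures_form_no_eras(self):
        assert derive_drug_eras([_exposure(1, 0, date(2015, 1, 1))]) == []

    def test_matches_interval_union_oracle_on_random_cases(self):
        rng = random.Random(7)
        for _ in range(300):
            n = rng.randint(1, 5)
            gap = rng.choice([0, 10, 30])
            spans = []
            for _ in range(n):
                s = date(2015, 1, 1) + timedelta(days=rng.randint(0, 200))
                spans.append((s, s + timedelta(days=rng.randint(0, 20))))
            rows = [_exposure(1, 5, s, e) for s, e in spans]
            eras = derive_drug_eras(rows, gap_days=gap)
            got = [(date.fromisoformat(e["drug_era_start_date"]),
                    date.fromisoformat(e["drug_era_end_date"]))
                   for e in eras]
            assert sorted(got) == era_oracle(spans, gap)
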