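"""Coverage arithmetic, prioritization worklist and the DQ check engine."""

import itertools
import json
import random

import pytest

from biobank_omop.cdm import CdmStore, CdmRow, PersonRow
from biobank_omop.quality import (CoverageStats, check_completeness,
                                  check_conformance,
                                  check_gender_plausibility,
                                  coverage_report, format_coverage_markdown,
                                  prioritize_terms, run_dq)
from biobank_omop.runlog import EtlLog
from biobank_omop.synthetic import CONCEPTS


class TestCoverage:
    def test_counts_and_percentages(self):
        log = EtlLog()
        for i in range(8):
            log.record_mapping("CTV3", f"m{i}", True)
        for i in range(2):
            log.record_mapping("CTV3", f"u{i}", False)
        for _ in range(90 - 8):
            log.record_mapping("CTV3", "m0", True)
        for _ in range(10 - 2):
            log.record_mapping("CTV3", "u0", False)
        (stats,) = coverage_report(log)
        assert (stats.used_terms, stats.mapped_terms) == (10, 8)
        assert (stats.events, stats.mapped_events) == (100, 90)
        assert stats.term_pct == 80.0
        assert stats.event_pct == 90.0

    def test_all_unmapped_degenerate(self):
        log = EtlLog()
        log.record_mapping("OPCS3", "a", False)
        (stats,) = coverage_report(log)
        assert stats.term_pct == 0.0 and stats.event_pct == 0.0

    def test_percentages_recomputable_from_counts(self, small_run):
        out, _ = small_run
        run_log = json.loads((out / "run_log.json").read_text())
        for v, c in run_log["coverage"].items():
            s = CoverageStats(v, c["used_terms"], c["mapped_terms"],
                              c["events"], c["mapped_events"])
            if s.events:
                assert s.event_pct == round(
                    100.0 * s.mapped_events / s.events, 2)
        assert "| Source vocab |" in format_coverage_markdown(
            [CoverageStats("CTV3", 1, 1, 1, 1)])

    def test_event_coverage_matches_planted_fraction(self, small_bundle,
                                                     small_run):
        """Per-vocabulary event coverage in the report equals the
        generator's planted mapped counts exactly."""
        _, gt = small_bundle
        out, _ = small_run
        run_log = json.loads((out / "run_log.json").read_text())
        assert run_log["coverage"] == gt["coverage"]


def prefix_oracle(freqs, fraction):
    """Exhaustive minimal-prefix search over the sorted term table."""
    ordered = sorted(((c, n) for c, n in freqs.items() if n > 0),
                     key=lambda kv: (-kv[1], kv[0]))
    total = sum(n for _, n in ordered)
    if total == 0:
        return []
    for k in range(1, len(ordered) + 1):
        if sum(n for _, n in ordered[:k]) >= fraction * total:
            return [c for c, _ in ordered[:k]]
    return [c for c, _ in ordered]


class TestPrioritizeTerms:
    def test_eighty_percent_worklist(self):
        freqs = {"a": 50, "b": 30, "c": 15, "d": 5}
        assert prioritize_terms(freqs, 0.8) == ["a", "b"]

    def test_fraction_one_returns_all_nonzero_terms(self):
        freqs = {"a": 50, "b": 30, "z": 0}
        assert prioritize_terms(freqs, 1.0) == ["a", "b"]

    def test_single_term(self):
        assert prioritize_terms({"only": 7}, 0.1) == ["only"]

    def test_empty_table(self):
        assert prioritize_terms({}, 0.8) == []

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            prioritize_terms({"a": 1}, 0.0)

    def test_matches_exhaustive_oracle_on_small_tables(self):
        rng = random.Random(3)
        for _ in range(200):
            n = rng.randint(1, 10)
            freqs = {f"t{i:02d}": rng.randint(0, 20) for i in range(n)}
            fraction = rng.choice([0.5, 0.8, 0.9, 1.0])
            assert prioritize_terms(freqs, fraction) == \
                prefix_oracle(freqs, fraction)


def _rows(n_zero, n_nonzero, concept=44810000):
    rows = [{"observation_concept_id": 0, "person_id": 1}
            for _ in range(n_zero)]
    rows += [{"observation_concept_id": concept, "person_id": 1}
             for _ in range(n_nonzero)]
    return rows


class TestCompleteness:
    def test_over_threshold_fails(self):
        r = check_completeness(_rows(25, 75), "observation", 0.20)
        assert r.status == "fail"

    def test_zero_unmapped_passes(self):
        assert check_completeness(_rows(0, 10), "observation").status == \
            "pass"

    def test_exactly_at_threshold_passes(self):
        # strict inequality: a 5-row table with exactly 1 concept-0 row
        r = check_completeness(_rows(1, 4), "observation", 0.20)
        assert r.failed_fraction == 0.20
        assert r.status == "pass"


class TestConformance:
    def test_condition_concept_in_measurement_table_fails(self, vocab_store):
        rows = [{"measurement_concept_id": 316866, "person_id": 1}]
        r = check_conformance(rows, "measurement", vocab_store)
        assert r.status == "fail"
        assert r.failing_examples[0]["concept_id"] == 316866

    def test_conformant_table_passes(self, vocab_store):
        rows = [{"condition_concept_id": 316866, "person_id": 1}]
        assert check_conformance(rows, "condition_occurrence",
                                 vocab_store).status == "pass"

    def test_non_unit_concept_in_unit_column_fails(self, vocab_store):
        rows = [{"measurement_concept_id": 0, "person_id": 1,
                 "unit_concept_id": 316866}]
        assert check_conformance(rows, "measurement",
                                 vocab_store).status == "fail"


class TestGenderPlausibility:
    PERSONS = [{"person_id": 1, "gender_concept_id": CONCEPTS["female"]},
               {"person_id": 2, "gender_concept_id": CONCEPTS["male"]},
               {"person_id": 3, "gender_concept_id": 0}]
    SPEC = {CONCEPTS["male_infertility"]: CONCEPTS["male"]}

    def _row(self, pid):
        return {"condition_concept_id": CONCEPTS["male_infertility"],
                "person_id": pid}

    def test_gender_specific_concept_on_other_gender_flagged(self):
        r = check_gender_plausibility([self._row(1)], "condition_occurrence",
                                      self.PERSONS, self.SPEC)
        assert r.status == "fail" and r.severity == "warning"

    def test_matching_gender_passes(self):
        r = check_gender_plausibility([self._row(2)], "condition_occurrence",
                                      self.PERSONS, self.SPEC)
        assert r.status == "pass"

    def test_unknown_gender_not_flagged(self):
        r = check_gender_plausibility([self._row(3)], "condition_occurrence",
                                      self.PERSONS, self.SPEC)
        assert r.status == "pass"


class TestRunDq:
    def test_read_only(self, small_run, vocab_store):
        out, _ = small_run
        cdm = CdmStore.from_csv(out / "cdm")
        before = cdm.content_hash()
        run_dq(cdm, vocab_store)
        assert cdm.content_hash() == before

    def test_planted_unit_defect_detected_by_conformance_only(
            self, small_bundle, small_run, vocab_store):
        _, gt = small_bundle
        out, _ = small_run
        assert gt["defects"]["unit_domain_mismatch_events"] >= 1
        dq = json.loads((out / "dq.json").read_text())
        conf_fails = [c for c in dq["checks"]
                      if c["status"] == "fail" and c["family"] == "conformance"]
        assert [c["table"] for c in conf_fails] == ["measurement"]
        assert conf_fails[0]["n_failed"] == \
            gt["defects"]["unit_domain_mismatch_events"]

    def test_clean_bundle_has_no_error_failures(self, tmp_path):
        from biobank_omop.pipeline import run_pipeline
        from biobank_omop.synthetic import GeneratorConfig, generate_bundle
        cfg = GeneratorConfig(n_participants=30, seed=5)
        generate_bundle(cfg, tmp_path / "b")
        manifest = run_pipeline(tmp_path / "b", tmp_path / "r")
        assert not manifest.dq_error_failure

    def test_gender_status_reported_for_condition_tables(self, small_run,
                                                         vocab_store):
        out, _ = small_run
        dq = json.loads((out / "dq.json").read_text())
        families = {c["family"] for c in dq["checks"]}
        assert families == {"completeness", "conformance", "plausibility"}
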