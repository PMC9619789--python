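"""Mapping resolution: loading, the 1:many selection rules, domain routing.

The selection rules are checked against an independent exhaustive oracle
over every candidate set of size ≤ 4 drawn from a small universe that
mixes preferred/non-preferred, active/inactive, standard/non-standard
targets and all four priority domains.
"""

import itertools
import random

import pytest

from biobank_omop.vocabulary import (Concept, MappingCandidate,
                                     VocabularyLoadError, domain_to_table,
                                     load_vocabulary, resolve_to_standard,
                                     select_single_target, DOMAIN_PRIORITY)


def _c(cid, domain, standard=True, vocab="SNOMED"):
    return Concept(cid, f"code{cid}", vocab, domain, standard)


def _mc(target, preferred=True, active=True):
    return MappingCandidate("SRC", "CTV3", target, preferred, active)


def oracle(candidates, strict=False):
    """Exhaustive re-statement of the selection rules, written as a single
    sort over the filtered set."""
    pool = [c for c in candidates if c.preferred and c.active]
    if not pool:
        pool = [] if strict else list(candidates)
    pool = [c for c in pool if c.target.standard]
    if not pool:
        return None
    ranked = sorted(pool, key=lambda c: (
        DOMAIN_PRIORITY.get(c.target.domain, 4),
        c.target.vocabulary != "SNOMED",
        c.target.concept_id))
    return ranked[0].target


UNIVERSE = [
    _mc(_c(10, "Condition"), True, True),
    _mc(_c(5, "Condition", vocab="ICD10"), True, True),
    _mc(_c(7, "Measurement"), True, True),
    _mc(_c(8, "Observation"), True, True),
    _mc(_c(9, "Procedure"), True, True),
    _mc(_c(11, "Condition", standard=False), True, True),
    _mc(_c(12, "Drug"), True, True),
    _mc(_c(13, "Measurement"), False, True),
    _mc(_c(14, "Condition"), True, False),
    _mc(_c(15, "Condition", standard=False), False, True),
]


class TestSelectSingleTarget:
    def test_single_standard_candidate_is_identity(self):
        c = _mc(_c(1, "Condition"))
        assert select_single_target([c]) == c.target

    def test_preferred_active_filter_beats_domain_priority(self):
        cond = _mc(_c(1, "Condition"), True, True)
        meas = _mc(_c(2, "Measurement"), False, True)
        assert select_single_target([cond, meas]) == cond.target

    def test_domain_priority_measurement_over_condition(self):
        meas = _mc(_c(2, "Measurement"), True, True)
        cond = _mc(_c(1, "Condition"), True, True)
        assert select_single_target([meas, cond]) == meas.target

    def test_same_domain_tie_breaks_to_lowest_concept_id(self):
        a = _mc(_c(20, "Condition"))
        b = _mc(_c(3, "Condition"))
        assert select_single_target([a, b]).concept_id == 3
        assert select_single_target([b, a]).concept_id == 3

    def test_snomed_target_preferred_over_other_vocabulary(self):
        icd = _mc(_c(2, "Condition", vocab="ICD10"))
        sno = _mc(_c(30, "Condition", vocab="SNOMED"))
        assert select_single_target([icd, sno]).concept_id == 30

    def test_all_nonstandard_resolves_to_none(self):
        assert select_single_target(
            [_mc(_c(1, "Condition", standard=False))]) is None

    def test_strict_filter_drops_sets_without_preferred_active(self):
        c = _mc(_c(1, "Condition"), preferred=False)
        assert select_single_target([c], strict_filter=True) is None
        assert select_single_target([c], strict_filter=False) == c.target

    @pytest.mark.parametrize("strict", [False, True])
    def test_equals_exhaustive_oracle_on_all_sets_up_to_four(self, strict):
        for size in (1, 2, 3, 4):
            for combo in itertools.combinations(UNIVERSE, size):
                expected = oracle(combo, strict)
                got = select_single_target(list(combo), strict_filter=strict)
                assert got == expected, combo

    def test_permutation_invariance(self):
        rng = random.Random(0)
        for size in (2, 3, 4):
            for combo in itertools.combinations(UNIVERSE, size):
                base = select_single_target(list(combo))
                shuffled = list(combo)
                rng.shuffle(shuffled)
                assert select_single_target(shuffled) == base

    def test_adding_filtered_out_candidate_never_changes_result(self):
        # for sets containing a preferred+active standard survivor, any
        # added candidate failing rule (1) or rule (2) is inert
        survivors = [c for c in UNIVERSE
                     if c.preferred and c.active and c.target.standard]
        failers = [c for c in UNIVERSE
                   if not (c.preferred and c.active) or not c.target.standard]
        for base_size in (1, 2):
            for base in itertools.combinations(survivors, base_size):
                expected = select_single_target(list(base))
                for extra in failers:
                    assert select_single_target(list(base) + [extra]) == \
                        expected

    def test_empty_candidates_resolve_to_none(self):
        assert select_single_target([]) is None


class TestDomainRouting:
    @pytest.mark.parametrize("domain,table", [
        ("Measurement", "measurement"),
        ("Condition", "condition_occurrence"),
        ("Procedure", "procedure_occurrence"),
        ("Drug", "drug_exposure"),
        ("Device", "device_exposure"),
        ("Observation", "observation"),
        ("Meas Value", "observation"),
        (None, "observation"),
    ])
    def test_domain_to_table(self, domain, table):
        assert domain_to_table(domain) == table


class TestLoadAndResolve:
    def test_fixture_loads_with_expected_shape(self, vocab_store):
        assert len(vocab_store.concepts) > 100
        assert vocab_store.concept_by_id(4214956) is not None
        assert vocab_store.get_custom("UKB", "20002-1065") is not None

    def test_duplicate_concept_key_rejected(self, tmp_path):
        p = tmp_path / "concepts.csv"
        p.write_text("concept_id,concept_code,vocabulary_id,domain_id,"
                     "standard_concept,invalid_reason\n"
                     "1,12345,SNOMED,Condition,S,\n"
                     "2,12345,SNOMED,Condition,S,\n", encoding="utf-8")
        with pytest.raises(VocabularyLoadError, match="12345"):
            load_vocabulary(p)

    def test_only_approved_usagi_rows_load(self, tmp_path):
        c = tmp_path / "concepts.csv"
        c.write_text("concept_id,concept_code,vocabulary_id,domain_id,"
                     "standard_concept,invalid_reason\n"
                     "9,x,SNOMED,Condition,S,\n", encoding="utf-8")
        u = tmp_path / "custom.csv"
        u.write_text("sourceCode,sourceName,sourceVocabularyId,"
                     "targetConceptId,valueConceptId,unitConceptId,"
                     "mappingStatus\n"
                     "a,A,UKB,9,,,APPROVED\n"
                     "b,B,UKB,9,,,FLAGGED\n", encoding="utf-8")
        store = load_vocabulary(c, [], [u])
        assert store.get_custom("UKB", "a") is not None
        assert store.get_custom("UKB", "b") is None

    def test_standard_code_resolves_to_self(self, vocab_store):
        cands = resolve_to_standard(vocab_store, "38341003", "SNOMED")
        assert len(cands) == 1
        assert cands[0].target.concept_id == 316866

    def test_unknown_code_resolves_to_empty(self, vocab_store):
        assert resolve_to_standard(vocab_store, "ZZZZZ", "CTV3") == []

    def test_icd10_dot_insensitive_lookup(self, vocab_store):
        with_dot = resolve_to_standard(vocab_store, "U07.1", "ICD10")
        without = resolve_to_standard(vocab_store, "U071", "ICD10")
        assert with_dot and without
        assert with_dot[0].target == without[0].target

    def test_resolve_then_select_never_returns_nonstandard(self, vocab_store):
        keys = list(vocab_store.maps) + list(vocab_store.custom_maps)
        checked = 0
        for vocab, code in keys:
            target = select_single_target(
                resolve_to_standard(vocab_store, code, vocab))
            if target is not None:
                assert target.standard
                checked += 1
        assert checked > 10
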