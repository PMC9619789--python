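"""Synthetic source-bundle generator with machine-readable ground truth.

Emulates the structure of a biobank-style study — a wide questionnaire
baseline extract plus multi-terminology EHR linkages — without any real
data: multiple coding systems per domain, 1:many cross-map entries
exercising every mapping-selection rule, deprecated and vendor-proprietary
codes, bespoke special values (−1/−2/−3/−99), a participant with a missing
year of birth, and a controllable fraction of unmappable terms per
vocabulary. Planted rates are realized exactly (largest-remainder
rounding) wherever counts permit, and a ground-truth JSON describing every
planted fact is written next to the bundle so each pipeline stage can be
verified end to end.

The generator targets structural fidelity (shapes of files, codes and
mapping pathologies), not epidemiological realism.
"""

from __future__ import annotations

import csv
import json
import math
from collections import defaultdict
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = ["GeneratorConfig", "generate_vocabulary_fixture",
           "generate_source_bundle", "generate_bundle",
           "CONCEPTS", "apportion"]

# ---------------------------------------------------------------------------
# Fixed concept ids (standard OMOP ids where a well-known one exists)
# ---------------------------------------------------------------------------

CONCEPTS = {
    "history_of_clinical_finding": 4214956,   # Observation (event step)
    "hypertensive_disorder": 316866,          # Condition (value step)
    "covid19": 37311061,                      # Condition
    "sars_cov2_measurement": 756055,          # Measurement (OMOP Extension)
    "positive": 45884084,
    "negative": 45878583,
    "male": 8507,
    "female": 8532,
    "male_infertility": 198197,               # gender-specific Condition
}

_UCUM = {"mm[Hg]": 8876, "kg/m2": 9531, "g/dL": 8713,
         "10*9/L": 8848, "mL": 8587}

_DATE0 = date(2006, 1, 1)
_DATE1 = date(2021, 12, 31)
_COVID0 = date(2020, 3, 1)


def apportion(total: int, fractions: list[float]) -> list[int]:
    """Integer allocation of ``total`` across ``fractions`` (which sum to 1)
    by largest-remainder rounding; deterministic tie-break by index."""
    raw = [f * total for f in fractions]
    out = [math.floor(r) for r in raw]
    short = total - sum(out)
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - out[i]), i))
    for i in order[:short]:
        out[i] += 1
    return out


def exact_count(total: int, fraction: float) -> int:
    """Largest-remainder count for a binary split."""
    return apportion(total, [fraction, 1.0 - fraction])[0]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def _default_mapped_fractions() -> dict[str, float]:
    # event-level mapped shares per source vocabulary, echoing the coverage
    # levels typical of UK terminologies (established systems high,
    # deprecated ones lower, vendor-proprietary codes mostly unmapped)
    return {
        "UKB": 0.84, "SNOMED": 0.97, "CTV3": 0.90,
        "ICD10": 0.98, "ICD9": 0.92, "OPCS4": 0.89, "OPCS3": 0.77,
        "DMD": 0.99, "EMIS": 0.20, "TPP": 0.20, "EMIS_UNIT": 0.87,
        "ADMIMETH": 0.95, "ADMISORC": 0.50, "DISDEST": 0.90,
        "ICD10_DEATH": 0.98,
    }


def _default_events_per_person() -> dict[str, float]:
    return {"gp_clinical": 6.0, "gp_scripts": 4.0,
            "hospital_episodes": 1.0, "covid_tests": 0.3}


@dataclass
class GeneratorConfig:
    n_participants: int = 1000
    seed: int = 0
    covid_prevalence: float = 0.05
    mapped_fraction: dict = field(default_factory=_default_mapped_fractions)
    special_value_rate: float = 0.01
    missing_yob_rate: float = 0.001
    one_to_many_rate: float = 0.10
    events_per_person: dict = field(default_factory=_default_events_per_person)
    #: fraction of COVID cases whose only evidence is the unmappable CTV3 code
    unmappable_case_rate: float = 0.0023
    hypertension_prevalence: float = 0.35
    t2dm_prevalence: float = 0.08
    death_rate: float = 0.02
    n_withdrawn: int = 0
    #: planted conformance defects: curated unit entries pointing at a
    #: Condition-domain concept (0 = clean bundle)
    unit_domain_mismatch_count: int = 0

    def validate(self) -> None:
        for name in ("covid_prevalence", "special_value_rate",
                     "missing_yob_rate", "one_to_many_rate",
                     "unmappable_case_rate", "hypertension_prevalence",
                     "t2dm_prevalence", "death_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for k, v in self.mapped_fraction.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"mapped_fraction[{k}] outside [0, 1]")
        if self.n_participants < 1:
            raise ValueError("n_participants must be positive")
        if self.covid_prevalence > 0 and all(
                v <= 0 for v in self.events_per_person.values()):
            raise ValueError("covid_prevalence > 0 requires at least one "
                             "event stream with nonzero mean")


# ---------------------------------------------------------------------------
# Vocabulary fixture
# ---------------------------------------------------------------------------

@dataclass
class VocabFixture:
    """In-memory view of the emitted fixture, used by the bundle generator."""
    concept_rows: list = field(default_factory=list)
    crossmap_rows: list = field(default_factory=list)
    custom_rows: list = field(default_factory=list)
    # per source vocabulary: codes that resolve / that do not
    mapped_terms: dict = field(default_factory=lambda: defaultdict(list))
    unmapped_terms: dict = field(default_factory=lambda: defaultdict(list))
    # baseline value pools
    illness_values_mapped: list = field(default_factory=list)
    illness_values_unmapped: list = field(default_factory=list)
    unit_codes_mapped: list = field(default_factory=list)
    unit_codes_unmapped: list = field(default_factory=list)
    snomed_measurement_codes: list = field(default_factory=list)
    bad_unit_codes: list = field(default_factory=list)
    selection_rule_cases: dict = field(default_factory=dict)
    device_concept: int = 0


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), stream])


def _uniq_codes(rng, n, maker) -> list[str]:
    out, seen = [], set()
    while len(out) < n:
        c = maker(rng)
        if c not in seen:
            seen.add(c)
            out.append(c)
    return out


def _snomed_code(rng) -> str:
    return str(int(rng.integers(10**7, 10**9)))


def _ctv3_code(rng) -> str:
    alphabet = "ABCDEFGHJKLMNPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
    return "".join(alphabet[int(i)] for i in rng.integers(0, len(alphabet), 5))


def _icd10_code(rng) -> str:
    letter = "ABCDEFGHIJKLMN"[int(rng.integers(0, 14))]
    code = f"{letter}{int(rng.integers(0, 100)):02d}"
    if rng.random() < 0.5:
        code += f".{int(rng.integers(0, 10))}"
    return code


def _dmd_code(rng) -> str:
    return str(int(rng.integers(10**10, 10**11)))


def generate_vocabulary_fixture(config: GeneratorConfig,
                                out_dir: str | Path) -> VocabFixture:
    """Emit concepts.csv, crossmaps.csv and custom_maps.csv.

    The concept universe spans every vocabulary the ETL understands; the
    cross-maps include 1:many cases exercising each mapping-selection rule
    (preferred/active filter, standard-target filter, domain priority,
    deterministic tie-break); the custom map ships the worked hypertension
    entry (field 20002, value 1065 → event 4214956, value 316866) and the
    SARS-CoV-2 test concepts.
    """
    config.validate()
    rng = _rng(config.seed, 1)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fx = VocabFixture()
    mf = config.mapped_fraction

    def concept(cid, code, vocab, domain, standard, invalid=""):
        fx.concept_rows.append({
            "concept_id": cid, "concept_code": code, "vocabulary_id": vocab,
            "domain_id": domain, "standard_concept": "S" if standard else "",
            "invalid_reason": invalid})
        return cid

    def crossmap(code, vocab, target, preferred=True, active=True):
        fx.crossmap_rows.append({
            "source_code": code, "source_vocabulary": vocab,
            "target_concept_id": target,
            "preferred": "Y" if preferred else "N",
            "active": "Y" if active else "N"})

    def custom(code, name, target, vocab="UKB", value=0, unit=0,
               status="APPROVED"):
        fx.custom_rows.append({
            "sourceCode": code, "sourceName": name,
            "sourceVocabularyId": vocab, "targetConceptId": target,
            "valueConceptId": value or "", "unitConceptId": unit or "",
            "mappingStatus": status})

    # -- fixed standard concepts ------------------------------------------
    concept(CONCEPTS["history_of_clinical_finding"], "417662000", "SNOMED",
            "Observation", True)
    concept(CONCEPTS["hypertensive_disorder"], "38341003", "SNOMED",
            "Condition", True)
    concept(CONCEPTS["covid19"], "840539006", "SNOMED", "Condition", True)
    concept(CONCEPTS["sars_cov2_measurement"], "OMOP4873969", "OMOP_EXT",
            "Measurement", True)
    concept(CONCEPTS["positive"], "10828004", "SNOMED", "Meas Value", True)
    concept(CONCEPTS["negative"], "260385009", "SNOMED", "Meas Value", True)
    concept(CONCEPTS["male"], "M", "Gender", "Gender", True)
    concept(CONCEPTS["female"], "F", "Gender", "Gender", True)
    concept(CONCEPTS["male_infertility"], "2904007", "SNOMED",
            "Condition", True)
    concept(4133051, "258500001", "SNOMED", "Specimen", True)  # nasal swab
    for code, cid in _UCUM.items():
        concept(cid, code, "UCUM", "Unit", True)

    # -- standard SNOMED/RxNorm pools -------------------------------------
    def pool(n, base_id, domain, vocab="SNOMED", code_maker=_snomed_code):
        ids = []
        for i, code in enumerate(_uniq_codes(rng, n, code_maker)):
            ids.append(concept(base_id + i, code, vocab, domain, True))
        return ids

    cond_ids = pool(40, 44810000, "Condition")
    meas_ids = pool(15, 44820000, "Measurement")
    obs_ids = pool(10, 44830000, "Observation")
    proc_ids = pool(15, 44840000, "Procedure")
    drug_ids = pool(25, 44850000, "Drug", vocab="RxNorm",
                    code_maker=lambda r: str(int(r.integers(10**5, 10**7))))
    dev_ids = pool(3, 44860000, "Device")
    fx.device_concept = dev_ids[0]

    # standard SNOMED source codes used directly in EMIS GP data: the
    # concept rows above double as the mapped SNOMED term pool
    snomed_codes = [r["concept_code"] for r in fx.concept_rows
                    if r["vocabulary_id"] == "SNOMED"
                    and r["standard_concept"] == "S"
                    and r["concept_id"] in set(cond_ids + meas_ids + obs_ids)]
    fx.snomed_measurement_codes = [r["concept_code"] for r in fx.concept_rows
                                   if r["concept_id"] in set(meas_ids)]
    # deprecated, non-standard SNOMED terms (unmapped: no cross-map entry)
    n_sn_unmapped = max(1, exact_count(
        len(snomed_codes), 1.0 - mf.get("SNOMED", 0.97)))
    for i, code in enumerate(_uniq_codes(rng, n_sn_unmapped, _snomed_code)):
        concept(45900000 + i, code, "SNOMED", "Condition", False, invalid="D")
        fx.unmapped_terms["SNOMED"].append(code)
    fx.mapped_terms["SNOMED"] = ["38341003", "840539006"] + snomed_codes

    # -- CTV3: cross-mapped, with 1:many shapes ---------------------------
    n_ctv3 = 40
    ctv3_codes = _uniq_codes(rng, n_ctv3, _ctv3_code)
    n_ctv3_mapped = exact_count(n_ctv3, mf.get("CTV3", 0.90))
    ctv3_mapped, ctv3_unmapped = (ctv3_codes[:n_ctv3_mapped],
                                  ctv3_codes[n_ctv3_mapped:])
    ctv3_mapped = ["XE0Uc"] + ctv3_mapped          # hypertension, 1:1
    ctv3_unmapped = ["X73lE"] + ctv3_unmapped      # coronavirus, unmappable
    for i, code in enumerate(ctv3_mapped + ctv3_unmapped):
        concept(45000000 + i, code, "CTV3", "Condition", False)
    crossmap("XE0Uc", "CTV3", CONCEPTS["hypertensive_disorder"])

    n_1many = exact_count(len(ctv3_mapped) - 1, config.one_to_many_rate)
    shaped = ctv3_mapped[1:1 + n_1many]
    plain = ctv3_mapped[1 + n_1many:]
    shapes = ["preferred_filter", "domain_priority", "tie_break",
              "strict_fallback"]
    for j, code in enumerate(shaped):
        shape = shapes[j % len(shapes)]
        fx.selection_rule_cases[code] = shape
        if shape == "preferred_filter":
            # rule (1): the non-preferred Measurement must lose to the
            # preferred+active Condition
            crossmap(code, "CTV3", cond_ids[j % len(cond_ids)],
                     preferred=True, active=True)
            crossmap(code, "CTV3", meas_ids[j % len(meas_ids)],
                     preferred=False, active=True)
        elif shape == "domain_priority":
            # rule (3): Measurement outranks Condition
            crossmap(code, "CTV3", meas_ids[j % len(meas_ids)])
            crossmap(code, "CTV3", cond_ids[j % len(cond_ids)])
        elif shape == "tie_break":
            # residual tie inside one domain → lowest concept id wins
            crossmap(code, "CTV3", cond_ids[(j + 1) % len(cond_ids)])
            crossmap(code, "CTV3", cond_ids[j % len(cond_ids)])
        else:
            # no preferred+active entry at all: maps only because the
            # default policy falls back to the unfiltered set; the strict
            # filter leaves it unmapped
            crossmap(code, "CTV3", cond_ids[j % len(cond_ids)],
                     preferred=False, active=True)
    for j, code in enumerate(plain):
        crossmap(code, "CTV3", cond_ids[j % len(cond_ids)])
    if n_1many >= 1 and ctv3_unmapped[1:]:
        # rule (2) exerciser: survivors of the preferred/active filter are
        # all non-standard, so the term resolves to nothing
        code = ctv3_unmapped[1]
        fx.selection_rule_cases[code] = "standard_filter"
        concept(45990001, _uniq_codes(rng, 1, _snomed_code)[0], "SNOMED",
                "Condition", False, invalid="U")
        crossmap(code, "CTV3", 45990001, preferred=True, active=True)
        crossmap(code, "CTV3", cond_ids[0], preferred=False, active=True)
    fx.mapped_terms["CTV3"] = ctv3_mapped
    fx.unmapped_terms["CTV3"] = ctv3_unmapped

    # -- ICD-10 / ICD-9 / OPCS --------------------------------------------
    def source_pool(vocab, n, base_id, code_maker, targets, fixed_mapped=()):
        codes = _uniq_codes(rng, n, code_maker)
        n_mapped = exact_count(n, mf.get(vocab, 0.9))
        if mf.get(vocab, 0.9) < 1.0:
            n_mapped = min(n_mapped, n - 1)  # keep ≥1 unmappable term
        mapped = list(fixed_mapped) + codes[:n_mapped]
        unmapped = codes[n_mapped:]
        for i, code in enumerate(mapped + unmapped):
            concept(base_id + i, code, vocab,
                    "Procedure" if vocab.startswith("OPCS") else "Condition",
                    False)
        for j, code in enumerate(mapped):
            if code == "U07.1":
                crossmap(code, vocab, CONCEPTS["covid19"])
            else:
                crossmap(code, vocab, targets[j % len(targets)])
        fx.mapped_terms[vocab] = mapped
        fx.unmapped_terms[vocab] = unmapped

    source_pool("ICD10", 30, 45100000, _icd10_code, cond_ids,
                fixed_mapped=("U07.1",))
    source_pool("ICD9", 10, 45200000,
                lambda r: str(int(r.integers(100, 999))) +
                (f".{int(r.integers(0, 10))}" if r.random() < 0.5 else ""),
                cond_ids)
    source_pool("OPCS4", 15, 45300000,
                lambda r: "ABCDEFGHJKLM"[int(r.integers(0, 12))] +
                f"{int(r.integers(0, 100)):02d}.{int(r.integers(0, 10))}",
                proc_ids)
    source_pool("OPCS3", 8, 45400000,
                lambda r: f"{int(r.integers(100, 1000))}", proc_ids)
    source_pool("DMD", 25, 45500000, _dmd_code, drug_ids)

    # -- vendor-proprietary codes (custom-mapped COVID subset) ------------
    for vocab, base_id, covid_code in (("EMIS", 45700000, "EMISNQCO303"),
                                       ("TPP", 45800000, "Y20d1")):
        codes = [covid_code] + _uniq_codes(rng, 5, _ctv3_code)
        n_mapped = max(1, exact_count(len(codes), mf.get(vocab, 0.2)))
        for i, code in enumerate(codes):
            concept(base_id + i, code, vocab, "Observation", False)
        for code in codes[:n_mapped]:
            custom(code, f"{vocab} COVID-19 related code",
                   CONCEPTS["covid19"], vocab=vocab)
        fx.mapped_terms[vocab] = codes[:n_mapped]
        fx.unmapped_terms[vocab] = codes[n_mapped:]

    # -- baseline custom maps (two-step field/value mapping) --------------
    custom("20002-1065", "Non-cancer illness: hypertension",
           CONCEPTS["history_of_clinical_finding"],
           value=CONCEPTS["hypertensive_disorder"])
    n_ill = 20
    ill_values = [str(1000 + i) for i in range(n_ill) if 1000 + i != 1065]
    n_ill_mapped = exact_count(len(ill_values), mf.get("UKB", 0.84))
    for j, v in enumerate(ill_values[:n_ill_mapped]):
        custom(f"20002-{v}", f"Non-cancer illness code {v}",
               CONCEPTS["history_of_clinical_finding"],
               value=cond_ids[j % len(cond_ids)])
    fx.illness_values_mapped = ["1065"] + ill_values[:n_ill_mapped]
    fx.illness_values_unmapped = ill_values[n_ill_mapped:]
    # non-standard source concepts for the bespoke questionnaire entries
    for i, v in enumerate(fx.illness_values_mapped + fx.illness_values_unmapped):
        concept(45600000 + i, f"20002-{v}", "UKB", "Observation", False)

    custom("4080", "Systolic blood pressure", meas_ids[0], unit=_UCUM["mm[Hg]"])
    custom("4079", "Diastolic blood pressure", meas_ids[1], unit=_UCUM["mm[Hg]"])
    custom("21001", "Body mass index", meas_ids[2], unit=_UCUM["kg/m2"])
    custom("30020", "Haemoglobin concentration", meas_ids[3], unit=_UCUM["g/dL"])
    custom("30021", "Freeze-thaw cycles", obs_ids[0])
    custom("30023", "Haematology device id", fx.device_concept)
    custom("2443", "Diabetes diagnosed by doctor", obs_ids[1])
    custom("20116-0", "Smoking status: never", obs_ids[2],
           value=CONCEPTS["negative"])
    custom("20116-1", "Smoking status: previous", obs_ids[2])
    custom("20116-2", "Smoking status: current", obs_ids[2],
           value=CONCEPTS["positive"])
    custom("31-0", "Sex: female", CONCEPTS["female"])
    custom("31-1", "Sex: male", CONCEPTS["male"])
    for i, eth in enumerate(("1001", "2001", "3001", "4001")):
        concept(46000000 + i, f"eth-{eth}", "UKB_ETH", "Ethnicity", True)
        custom(f"21000-{eth}", f"Ethnic background {eth}", 46000000 + i)

    # -- COVID test & specimen maps ---------------------------------------
    custom("sars-cov-2-test", "SARS-CoV-2 measurement",
           CONCEPTS["sars_cov2_measurement"], vocab="COVID_TEST")
    custom("positive", "Detected", CONCEPTS["positive"], vocab="COVID_TEST",
           value=CONCEPTS["positive"])
    custom("negative", "Not detected", CONCEPTS["negative"],
           vocab="COVID_TEST", value=CONCEPTS["negative"])
    custom("swab_nasal", "Nasal swab", 4133051, vocab="SPECIMEN")

    # -- hospital episode attributes --------------------------------------
    for vocab, n_codes in (("ADMIMETH", 5), ("ADMISORC", 4), ("DISDEST", 4)):
        codes = [f"{vocab[:2]}{k:02d}" for k in range(1, n_codes + 1)]
        n_mapped = exact_count(n_codes, mf.get(vocab, 0.8))
        if mf.get(vocab, 0.8) < 1.0:
            n_mapped = min(n_mapped, n_codes - 1)
        for code in codes[:n_mapped]:
            custom(code, f"{vocab} {code}", obs_ids[3], vocab=vocab)
        fx.mapped_terms[vocab] = codes[:n_mapped]
        fx.unmapped_terms[vocab] = codes[n_mapped:]

    # -- measurement units -------------------------------------------------
    ucum_units = ["mm[Hg]", "g/dL", "10*9/L"]       # resolve via UCUM itself
    vendor_units = ["mmHg", "grams/dl"]             # curated vendor spellings
    odd_units = ["MEA156", "MEA161"]                # unmapped vendor codes
    for code, ucum in zip(vendor_units, ("mm[Hg]", "g/dL")):
        custom(code, f"vendor unit {code}", _UCUM[ucum], vocab="EMIS_UNIT",
               unit=_UCUM[ucum])
    fx.unit_codes_mapped = ucum_units + vendor_units
    fx.unit_codes_unmapped = list(odd_units)
    for k in range(config.unit_domain_mismatch_count):
        # planted conformance defect: a unit entry curated onto a
        # Condition-domain concept
        bad = f"MEABAD{k:02d}"
        custom(bad, "mis-curated unit", cond_ids[k % len(cond_ids)],
               vocab="EMIS_UNIT", unit=cond_ids[k % len(cond_ids)])
        fx.bad_unit_codes.append(bad)

    # -- write files -------------------------------------------------------
    def write(name, rows, header):
        with open(out / name, "w", newline="", encoding="utf-8") as fh:
            w = csv.DictWriter(fh, fieldnames=header)
            w.writeheader()
            w.writerows(rows)

    write("concepts.csv", fx.concept_rows,
          ["concept_id", "concept_code", "vocabulary_id", "domain_id",
           "standard_concept", "invalid_reason"])
    write("crossmaps.csv", fx.crossmap_rows,
          ["source_code", "source_vocabulary", "target_concept_id",
           "preferred", "active"])
    write("custom_maps.csv", fx.custom_rows,
          ["sourceCode", "sourceName", "sourceVocabularyId",
           "targetConceptId", "valueConceptId", "unitConceptId",
           "mappingStatus"])
    return fx


# ---------------------------------------------------------------------------
# Source bundle
# ---------------------------------------------------------------------------

class _Tally:
    """Mirror of the ETL's coverage accounting, filled at generation time."""

    def __init__(self):
        self.used: dict[str, set] = defaultdict(set)
        self.mapped: dict[str, set] = defaultdict(set)
        self.events: dict[str, int] = defaultdict(int)
        self.mapped_events: dict[str, int] = defaultdict(int)

    def record(self, vocab: str, code: str, mapped: bool) -> None:
        self.used[vocab].add(code)
        self.events[vocab] += 1
        if mapped:
            self.mapped[vocab].add(code)
            self.mapped_events[vocab] += 1

    def as_dict(self) -> dict:
        return {v: {"used_terms": len(self.used[v]),
                    "mapped_terms": len(self.mapped[v]),
                    "events": self.events[v],
                    "mapped_events": self.mapped_events[v]}
                for v in sorted(self.used)}


def _iso(d: date) -> str:
    return d.isoformat()


def _rand_date(rng, start: date = _DATE0, end: date = _DATE1) -> date:
    span = (end - start).days
    return start + timedelta(days=int(rng.integers(0, span + 1)))


def _cycle(pool: list, k: int, offset: int = 0) -> list:
    if not pool:
        return []
    return [pool[(offset + i) % len(pool)] for i in range(k)]


def generate_source_bundle(config: GeneratorConfig, fx: VocabFixture,
                           out_dir: str | Path) -> dict:
    """Emit the participant-level extracts plus ground_truth.json.

    Returns the ground-truth dictionary. Every planted rate (COVID
    prevalence, per-vocabulary mapped fractions, special-value rate,
    missing year-of-birth rate) is realized exactly by largest-remainder
    allocation over the relevant pool of rows.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n = config.n_participants
    mf = config.mapped_fraction
    tally = _Tally()
    rng_p = _rng(config.seed, 10)     # person roles
    rng_b = _rng(config.seed, 11)     # baseline values
    rng_g = _rng(config.seed, 12)     # GP clinical
    rng_rx = _rng(config.seed, 13)    # prescriptions
    rng_h = _rng(config.seed, 14)     # hospital
    rng_d = _rng(config.seed, 15)     # death
    rng_c = _rng(config.seed, 16)     # covid tests

    eids = [f"P{i:06d}" for i in range(1, n + 1)]

    # -- person roles ------------------------------------------------------
    order = list(rng_p.permutation(n))
    withdrawn = set(eids[i] for i in order[:config.n_withdrawn])
    remaining = [eids[i] for i in order[config.n_withdrawn:]]
    n_missing = exact_count(n, config.missing_yob_rate)
    missing_yob = set(remaining[:n_missing])
    eligible = remaining[n_missing:]          # accepted by the ETL
    n_cases = exact_count(len(eligible), config.covid_prevalence)
    cases = list(eligible[:n_cases])
    n_unmappable = exact_count(n_cases, config.unmappable_case_rate)
    unmappable_only = set(cases[:n_unmappable])
    n_ht = exact_count(len(eligible), config.hypertension_prevalence)
    ht_set = set(rng_p.permutation(eligible)[:n_ht])
    n_t2dm = exact_count(len(eligible), config.t2dm_prevalence)
    t2dm_set = set(rng_p.permutation(eligible)[:n_t2dm])
    provider = {e: ("EMIS" if i % 2 == 0 else "TPP")
                for i, e in enumerate(sorted(eids))}
    for e in unmappable_only:                 # X73lE lives in TPP systems
        provider[e] = "TPP"

    # evidence streams per case
    evidence: dict[str, list] = {e: [] for e in cases}
    for e in cases:
        if e in unmappable_only:
            continue
        streams = [s for s in ("test", "gp", "hospital", "death")
                   if rng_p.random() < 0.5]
        if not streams:
            streams = [("test", "gp", "hospital", "death")[
                int(rng_p.integers(0, 4))]]
        for s in streams:
            evidence[e].append(s)
    for e in unmappable_only:
        evidence[e] = ["gp_unmappable"]

    accepted = sorted(set(eids) - withdrawn - missing_yob)
    n_acc = len(accepted)
    rejected_with_data = sorted(missing_yob | withdrawn)

    # -- baseline ----------------------------------------------------------
    dev_pool = ["dev1", "dev2", "dev3"]
    smoke_pool = ["0", "1", "2"]
    visit_date = {e: _iso(_rand_date(rng_b, date(2006, 3, 1),
                                     date(2010, 10, 1))) for e in sorted(eids)}
    # 20002 slot allocation to hit the bespoke-vocabulary event share
    fixed_per_person = 7                      # 5 numerics + device + smoking
    total_ukb = (fixed_per_person + 3) * n_acc + len(t2dm_set)
    target_mapped = exact_count(total_ukb, mf.get("UKB", 0.84))
    n_ht_acc = len(ht_set)
    m_ill = min(max(target_mapped - fixed_per_person * n_acc
                    - len(t2dm_set), n_ht_acc), 3 * n_acc)
    slots = [(e, a) for e in accepted for a in range(3)
             if not (e in ht_set and a == 0)]
    slot_order = list(rng_b.permutation(len(slots)))
    ill_value: dict[tuple, str] = {}
    pool_m = [v for v in fx.illness_values_mapped if v != "1065"]
    pool_u = list(fx.illness_values_unmapped)
    im = iu = 0
    for k, idx in enumerate(slot_order):
        e, a = slots[idx]
        if k < m_ill - n_ht_acc and pool_m:
            ill_value[(e, a)] = pool_m[im % len(pool_m)]
            im += 1
        else:
            src = pool_u or pool_m
            ill_value[(e, a)] = src[iu % len(src)]
            iu += 1
    for e in ht_set:
        ill_value[(e, 0)] = "1065"

    header = (["eid", "31-0.0", "34-0.0", "53-0.0", "21000-0.0",
               "4080-0.0", "4079-0.0", "21001-0.0", "30020-0.0",
               "30021-0.0", "30023-0.0", "2443-0.0", "20116-0.0",
               "20002-0.0", "20002-0.1", "20002-0.2"])
    eth_pool = ["1001", "2001", "3001", "4001"]
    baseline_rows = []
    for e in sorted(eids):
        sex = int(rng_b.integers(0, 2))
        yob = "" if e in missing_yob else str(1937 + int(rng_b.integers(0, 34)))
        vals = {
            "eid": e, "31-0.0": str(sex), "34-0.0": yob,
            "53-0.0": visit_date[e],
            "21000-0.0": eth_pool[int(rng_b.integers(0, 4))],
            "4080-0.0": str(int(rng_b.normal(136, 18))),
            "4079-0.0": str(int(rng_b.normal(81, 10))),
            "21001-0.0": f"{rng_b.normal(27, 4.5):.1f}",
            "30020-0.0": f"{rng_b.normal(14, 1.5):.1f}",
            "30021-0.0": str(int(rng_b.integers(0, 4))),
            "30023-0.0": dev_pool[int(rng_b.integers(0, 3))],
            "2443-0.0": "1" if e in t2dm_set else "",
            "20116-0.0": smoke_pool[int(rng_b.integers(0, 3))],
        }
        for a in range(3):
            v = ill_value.get((e, a), "")
            if e in rejected_with_data and a == 0:
                v = pool_m[0] if pool_m else "1065"
            vals[f"20002-0.{a}"] = v
        baseline_rows.append(vals)
        if e in accepted:
            for fid in ("4080", "4079", "21001", "30020", "30021"):
                tally.record("UKB", fid, True)
            tally.record("UKB", f"30023-{vals['30023-0.0']}", True)
            tally.record("UKB", f"20116-{vals['20116-0.0']}", True)
            if e in t2dm_set:
                tally.record("UKB", "2443", True)
            for a in range(3):
                v = vals[f"20002-0.{a}"]
                if v:
                    tally.record("UKB", f"20002-{v}",
                                 v in fx.illness_values_mapped)
    with open(out / "baseline.csv", "w", newline="", encoding="utf-8") as fh:
        w = csv.DictWriter(fh, fieldnames=header)
        w.writeheader()
        w.writerows(baseline_rows)

    with open(out / "field_dictionary.csv", "w", newline="",
              encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["field_id", "value_kind", "ucum_unit", "date_field_id"])
        for row in (("4080", "numeric", "mm[Hg]", "53"),
                    ("4079", "numeric", "mm[Hg]", "53"),
                    ("21001", "numeric", "kg/m2", "53"),
                    ("30020", "numeric", "g/dL", "53"),
                    ("30021", "numeric", "", "53"),
                    ("30023", "categorical", "", "53"),
                    ("2443", "boolean", "", "53"),
                    ("20116", "categorical", "", "53"),
                    ("20002", "categorical", "", "53")):
            w.writerow(row)

    with open(out / "withdrawals.csv", "w", newline="",
              encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["eid"])
        for e in sorted(withdrawn):
            w.writerow([e])
    return _generate_ehr_files(config, fx, out, tally, dict(
        eids=eids, accepted=accepted, withdrawn=withdrawn,
        missing_yob=missing_yob, cases=cases,
        unmappable_only=unmappable_only, evidence=evidence,
        ht_set=ht_set, t2dm_set=t2dm_set, provider=provider,
        visit_date=visit_date,
        rngs=dict(g=rng_g, rx=rng_rx, h=rng_h, d=rng_d, c=rng_c)))


def _generate_ehr_files(config: GeneratorConfig, fx: VocabFixture,
                        out: Path, tally: _Tally, ctx: dict) -> dict:
    mf = config.mapped_fraction
    epp = config.events_per_person
    accepted = ctx["accepted"]
    cases = ctx["cases"]
    evidence = ctx["evidence"]
    unmappable_only = ctx["unmappable_only"]
    provider = ctx["provider"]
    ht_set = ctx["ht_set"]
    rejected_with_data = sorted(ctx["missing_yob"] | ctx["withdrawn"])
    rng_g, rng_rx, rng_h, rng_d, rng_c = (ctx["rngs"][k]
                                          for k in ("g", "rx", "h", "d", "c"))
    n_acc = len(accepted)
    last_event: dict[str, date] = {}
    gt_evidence: dict[str, list] = defaultdict(list)

    def touch(eid: str, d: date) -> None:
        if eid not in last_event or d > last_event[eid]:
            last_event[eid] = d

    # ---------------- GP clinical ----------------------------------------
    gp_rows: list[dict] = []

    def gp(eid, code, vocab, d: date, value="", unit="", do_tally=True,
           mapped=None):
        gp_rows.append({"eid": eid, "data_provider": provider[eid],
                        "code": code, "vocab": vocab, "event_dt": _iso(d),
                        "value": value, "unit": unit})
        touch(eid, d)
        if do_tally:
            tally.record(vocab, code, mapped)

    for e in sorted(cases):
        if "gp" in evidence[e]:
            d = _rand_date(rng_g, _COVID0, date(2021, 11, 30))
            if provider[e] == "EMIS":
                # native SNOMED coding or the curated proprietary code
                code, vocab = (("840539006", "SNOMED")
                               if rng_g.random() < 0.5
                               else ("EMISNQCO303", "EMIS"))
            else:
                code, vocab = "Y20d1", "TPP"
            gp(e, code, vocab, d, mapped=True)
            gt_evidence[e].append(("primary_care", code, True, _iso(d)))
        if "gp_unmappable" in evidence[e]:
            d = _rand_date(rng_g, _COVID0, date(2021, 11, 30))
            gp(e, "X73lE", "CTV3", d, mapped=False)
            gt_evidence[e].append(("primary_care", "X73lE", False, _iso(d)))
    for e in sorted(ht_set):
        d = _rand_date(rng_g, _DATE0, date(2019, 12, 31))
        if provider[e] == "EMIS":
            gp(e, "38341003", "SNOMED", d, mapped=True)
        else:
            gp(e, "XE0Uc", "CTV3", d, mapped=True)

    e_total = int(round(epp.get("gp_clinical", 0.0) * n_acc))
    n_filler = max(0, e_total - len(gp_rows))
    filler_assign: list[tuple[str, str]] = []   # (eid, vocab)
    for i in range(n_filler):
        e = accepted[int(rng_g.integers(0, n_acc))]
        main = "SNOMED" if provider[e] == "EMIS" else "CTV3"
        vocab = (provider[e] if i % 20 == 19 else main)
        filler_assign.append((e, vocab))
    by_vocab: dict[str, list[str]] = defaultdict(list)
    for e, v in filler_assign:
        by_vocab[v].append(e)
    filler_pools = {
        "SNOMED": ([c for c in fx.mapped_terms["SNOMED"]
                    if c not in ("38341003", "840539006")],
                   list(fx.unmapped_terms["SNOMED"])),
        "CTV3": ([c for c in fx.mapped_terms["CTV3"] if c != "XE0Uc"],
                 [c for c in fx.unmapped_terms["CTV3"] if c != "X73lE"]),
        "EMIS": ([], list(fx.unmapped_terms["EMIS"])),
        "TPP": ([], list(fx.unmapped_terms["TPP"])),
    }
    meas_codes = set(fx.snomed_measurement_codes)
    unit_slots: list[int] = []                  # indices into gp_rows
    for vocab in sorted(by_vocab):
        persons = by_vocab[vocab]
        pool_m, pool_u = filler_pools[vocab]
        total_v = tally.events[vocab] + len(persons)
        quota = exact_count(total_v, mf.get(vocab, 0.9))
        n_map = min(max(quota - tally.mapped_events[vocab], 0), len(persons))
        if not pool_m:
            n_map = 0
        for j, e in enumerate(persons):
            d = _rand_date(rng_g, _DATE0, date(2019, 12, 31))
            if j < n_map:
                code = pool_m[j % len(pool_m)]
                if code in meas_codes:
                    gp(e, code, vocab, d,
                       value=f"{rng_g.normal(100, 20):.1f}", mapped=True)
                    unit_slots.append(len(gp_rows) - 1)
                else:
                    gp(e, code, vocab, d, mapped=True)
            else:
                code = pool_u[j % len(pool_u)] if pool_u else pool_m[0]
                gp(e, code, vocab, d, mapped=bool(not pool_u))
    # units on measurement-domain filler rows
    n_units = len(unit_slots)
    unit_quota = exact_count(n_units, mf.get("EMIS_UNIT", 0.87))
    bad_used = 0
    for k, idx in enumerate(unit_slots):
        if bad_used < len(fx.bad_unit_codes):
            code, mapped = fx.bad_unit_codes[bad_used], True
            bad_used += 1
        elif k < unit_quota:
            code = fx.unit_codes_mapped[k % len(fx.unit_codes_mapped)]
            mapped = True
        else:
            code = fx.unit_codes_unmapped[k % len(fx.unit_codes_unmapped)]
            mapped = False
        gp_rows[idx]["unit"] = code
        tally.record("EMIS_UNIT", code, mapped)
    # special values (excluded before mapping; never tallied)
    n_special = exact_count(e_total, config.special_value_rate)
    special_codes = ["-1", "-2", "-3", "-99"]
    for i in range(n_special):
        e = accepted[int(rng_g.integers(0, n_acc))]
        gp(e, special_codes[i % 4],
           "SNOMED" if provider[e] == "EMIS" else "CTV3",
           _rand_date(rng_g, _DATE0, date(2019, 12, 31)), do_tally=False)
    for e in rejected_with_data:
        pool_m, _ = filler_pools["SNOMED" if provider[e] == "EMIS" else "CTV3"]
        gp(e, pool_m[0], "SNOMED" if provider[e] == "EMIS" else "CTV3",
           _rand_date(rng_g, _DATE0, date(2019, 12, 31)), do_tally=False)

    with open(out / "gp_clinical.csv", "w", newline="",
              encoding="utf-8") as fh:
        w = csv.DictWriter(fh, fieldnames=["eid", "data_provider", "code",
                                           "vocab", "event_dt", "value",
                                           "unit"])
        w.writeheader()
        w.writerows(gp_rows)

    # ---------------- GP prescriptions -----------------------------------
    rx_rows = []
    e_rx = int(round(epp.get("gp_scripts", 0.0) * n_acc))
    n_map_rx = exact_count(e_rx, mf.get("DMD", 0.99))
    pool_m, pool_u = fx.mapped_terms["DMD"], fx.unmapped_terms["DMD"]
    for i in range(e_rx):
        e = accepted[int(rng_rx.integers(0, n_acc))]
        code = (pool_m[i % len(pool_m)] if i < n_map_rx
                else (pool_u[i % len(pool_u)] if pool_u else pool_m[0]))
        d = _rand_date(rng_rx, _DATE0, _DATE1)
        rx_rows.append({"eid": e, "data_provider": provider[e],
                        "dmd_code": code, "issue_date": _iso(d),
                        "quantity": int(rng_rx.integers(10, 100))})
        touch(e, d)
        tally.record("DMD", code, i < n_map_rx or not pool_u)
    for e in rejected_with_data:
        rx_rows.append({"eid": e, "data_provider": provider[e],
                        "dmd_code": pool_m[0], "issue_date": "2015-05-05",
                        "quantity": 10})
    with open(out / "gp_scripts.csv", "w", newline="",
              encoding="utf-8") as fh:
        w = csv.DictWriter(fh, fieldnames=["eid", "data_provider",
                                           "dmd_code", "issue_date",
                                           "quantity"])
        w.writeheader()
        w.writerows(rx_rows)

    # ---------------- Hospital episodes ----------------------------------
    ep_rows, dp_rows = [], []
    spell_no = 0
    diag_slots: list[tuple[str, int]] = []      # (spell, position)
    proc_slots: list[str] = []

    def episode(eid, admi: date, dis: date) -> str:
        nonlocal spell_no
        spell_no += 1
        spell = f"S{spell_no:06d}"
        ep_rows.append({"eid": eid, "spell_id": spell,
                        "admidate": _iso(admi), "disdate": _iso(dis),
                        "admimeth": "", "admisorc": "", "disdest": ""})
        touch(eid, dis)
        return spell

    covid_hosp = [e for e in sorted(cases) if "hospital" in evidence[e]]
    for e in covid_hosp:
        admi = _rand_date(rng_h, _COVID0, date(2021, 11, 30))
        spell = episode(e, admi, admi + timedelta(int(rng_h.integers(1, 15))))
        dp_rows.append({"spell_id": spell, "kind": "diag", "code": "U07.1",
                        "vocab": "ICD10", "position": "1"})
        tally.record("ICD10", "U07.1", True)
        gt_evidence[e].append(("hospital", "U07.1", True, _iso(admi)))
    n_ep_total = int(round(epp.get("hospital_episodes", 0.0) * n_acc))
    n_ep_filler = max(0, n_ep_total - len(covid_hosp))
    filler_spells = []
    for _ in range(n_ep_filler):
        e = accepted[int(rng_h.integers(0, n_acc))]
        admi = _rand_date(rng_h, _DATE0, date(2019, 12, 31))
        spell = episode(e, admi, admi + timedelta(int(rng_h.integers(0, 11))))
        filler_spells.append(spell)
        diag_slots.append((spell, 1))
        for extra in range(int(rng_h.integers(0, 3))):
            diag_slots.append((spell, 2 + extra))
        if rng_h.random() < 0.5:
            proc_slots.append(spell)

    # diagnoses: a deprecated-terminology (ICD-9) share, the rest ICD-10
    n_diag = len(diag_slots)
    n_icd9 = exact_count(n_diag, 0.08)
    perm = list(rng_h.permutation(n_diag))
    icd9_idx = set(perm[:n_icd9])
    vocab_of = {i: ("ICD9" if i in icd9_idx else "ICD10")
                for i in range(n_diag)}
    counters = defaultdict(int)
    quotas = {}
    for v in ("ICD10", "ICD9"):
        total_v = tally.events[v] + sum(1 for i in range(n_diag)
                                        if vocab_of[i] == v)
        quotas[v] = exact_count(total_v, mf.get(v, 0.9))
    for i, (spell, pos) in enumerate(diag_slots):
        v = vocab_of[i]
        pool_m = [c for c in fx.mapped_terms[v] if c != "U07.1"]
        pool_u = fx.unmapped_terms[v]
        j = counters[v]
        counters[v] += 1
        mapped = tally.mapped_events[v] < quotas[v] and bool(pool_m)
        code = (pool_m[j % len(pool_m)] if mapped
                else (pool_u[j % len(pool_u)] if pool_u else pool_m[0]))
        dp_rows.append({"spell_id": spell, "kind": "diag", "code": code,
                        "vocab": v, "position": str(pos)})
        tally.record(v, code, mapped or not pool_u)
    # procedures
    n_proc = len(proc_slots)
    n_opcs3 = exact_count(n_proc, 0.10)
    pq = {}
    for v in ("OPCS3", "OPCS4"):
        total_v = (n_opcs3 if v == "OPCS3" else n_proc - n_opcs3)
        pq[v] = exact_count(total_v, mf.get(v, 0.8))
    counters = defaultdict(int)
    for i, spell in enumerate(proc_slots):
        v = "OPCS3" if i < n_opcs3 else "OPCS4"
        pool_m, pool_u = fx.mapped_terms[v], fx.unmapped_terms[v]
        j = counters[v]
        counters[v] += 1
        mapped = tally.mapped_events[v] < pq[v] and bool(pool_m)
        code = (pool_m[j % len(pool_m)] if mapped
                else (pool_u[j % len(pool_u)] if pool_u else pool_m[0]))
        dp_rows.append({"spell_id": spell, "kind": "proc", "code": code,
                        "vocab": v, "position": ""})
        tally.record(v, code, mapped or not pool_u)
    # episode attributes (every episode carries all three)
    for v, col in (("ADMIMETH", "admimeth"), ("ADMISORC", "admisorc"),
                   ("DISDEST", "disdest")):
        pool_m, pool_u = fx.mapped_terms[v], fx.unmapped_terms[v]
        n_eps = len(ep_rows)
        quota = exact_count(n_eps, mf.get(v, 0.8))
        for i, row in enumerate(ep_rows):
            mapped = i < quota and bool(pool_m)
            code = (pool_m[i % len(pool_m)] if mapped
                    else (pool_u[i % len(pool_u)] if pool_u
                          else pool_m[0]))
            row[col] = code
            tally.record(v, code, mapped or not pool_u)
    for e in rejected_with_data:
        spell = episode(e, date(2014, 2, 1), date(2014, 2, 3))
        # attributes set directly; rows of rejected participants are never
        # mapped by the ETL, so nothing is tallied here
        ep_rows[-1].update(admimeth=fx.mapped_terms["ADMIMETH"][0],
                           admisorc=fx.mapped_terms["ADMISORC"][0],
                           disdest=fx.mapped_terms["DISDEST"][0])
        dp_rows.append({"spell_id": spell, "kind": "diag",
                        "code": fx.mapped_terms["ICD10"][1], "vocab": "ICD10",
                        "position": "1"})
    with open(out / "hesin.csv", "w", newline="", encoding="utf-8") as fh:
        w = csv.DictWriter(fh, fieldnames=["eid", "spell_id", "admidate",
                                           "disdate", "admimeth", "admisorc",
                                           "disdest"])
        w.writeheader()
        w.writerows(ep_rows)
    with open(out / "hesin_diag_proc.csv", "w", newline="",
              encoding="utf-8") as fh:
        w = csv.DictWriter(fh, fieldnames=["spell_id", "kind", "code",
                                           "vocab", "position"])
        w.writeheader()
        w.writerows(dp_rows)
    return _generate_registry_files(config, fx, out, tally, ctx, gp_rows,
                                    last_event, gt_evidence)


def _generate_registry_files(config: GeneratorConfig, fx: VocabFixture,
                             out: Path, tally: _Tally, ctx: dict,
                             gp_rows: list, last_event: dict,
                             gt_evidence: dict) -> dict:
    mf = config.mapped_fraction
    epp = config.events_per_person
    accepted = ctx["accepted"]
    cases = ctx["cases"]
    evidence = ctx["evidence"]
    unmappable_only = ctx["unmappable_only"]
    rng_d, rng_c = ctx["rngs"]["d"], ctx["rngs"]["c"]
    n_acc = len(accepted)

    # ---------------- Death registry -------------------------------------
    covid_dead = [e for e in sorted(cases) if "death" in evidence[e]]
    n_dead_total = max(exact_count(n_acc, config.death_rate),
                       len(covid_dead))
    non_case_pool = [e for e in accepted if e not in set(cases)]
    perm = list(rng_d.permutation(len(non_case_pool)))
    filler_dead = [non_case_pool[i]
                   for i in perm[:n_dead_total - len(covid_dead)]]
    death_rows = []
    cause_slots = []      # (eid, underlying, fixed_code or None)
    for e in covid_dead:
        cause_slots.append((e, True, "U07.1"))
        if rng_d.random() < 0.3:
            cause_slots.append((e, False, None))
    for e in sorted(filler_dead):
        cause_slots.append((e, True, None))
        if rng_d.random() < 0.3:
            cause_slots.append((e, False, None))
    n_open = sum(1 for _, _, c in cause_slots if c is None)
    total_dc = len(cause_slots)
    quota = exact_count(total_dc, mf.get("ICD10_DEATH", 0.98))
    planted_mapped = sum(1 for _, _, c in cause_slots if c == "U07.1")
    n_map_open = min(max(quota - planted_mapped, 0), n_open)
    pool_m = [c for c in fx.mapped_terms["ICD10"] if c != "U07.1"]
    pool_u = fx.unmapped_terms["ICD10"]
    death_date: dict[str, str] = {}
    j = 0
    for e, underlying, fixed in cause_slots:
        if e not in death_date:
            base = last_event.get(e, date(2015, 1, 1))
            if e in covid_dead:
                base = max(base, _COVID0)
            dd = base + timedelta(int(rng_d.integers(7, 90)))
            death_date[e] = _iso(dd)
        if fixed is not None:
            code, mapped = fixed, True
        else:
            mapped = j < n_map_open and bool(pool_m)
            code = (pool_m[j % len(pool_m)] if mapped
                    else (pool_u[j % len(pool_u)] if pool_u else pool_m[0]))
            mapped = mapped or not pool_u
            j += 1
        death_rows.append({"eid": e, "date_of_death": death_date[e],
                           "cause_icd10": code,
                           "underlying_flag": "1" if underlying else "0"})
        tally.record("ICD10_DEATH", code, mapped)
        if e in covid_dead and fixed == "U07.1":
            gt_evidence[e].append(("death", "U07.1", True, death_date[e]))
    with open(out / "death.csv", "w", newline="", encoding="utf-8") as fh:
        w = csv.DictWriter(fh, fieldnames=["eid", "date_of_death",
                                           "cause_icd10", "underlying_flag"])
        w.writeheader()
        w.writerows(death_rows)

    # ---------------- COVID-19 tests -------------------------------------
    test_rows = []
    covid_tested = [e for e in sorted(cases) if "test" in evidence[e]]
    for e in covid_tested:
        d = _rand_date(rng_c, _COVID0, date(2021, 11, 30))
        test_rows.append({"eid": e, "specdate": _iso(d),
                          "spectype": "swab_nasal", "result": "positive"})
        gt_evidence[e].append(("covid_tests", "positive", True, _iso(d)))
    n_tests = int(round(epp.get("covid_tests", 0.0) * n_acc))
    n_neg = max(0, n_tests - len(covid_tested))
    neg_pool = [e for e in accepted if e not in set(cases)]
    for i in range(n_neg):
        e = neg_pool[i % len(neg_pool)] if neg_pool else accepted[0]
        d = _rand_date(rng_c, _COVID0, date(2021, 11, 30))
        test_rows.append({"eid": e, "specdate": _iso(d),
                          "spectype": "swab_nasal", "result": "negative"})
    with open(out / "covid_tests.csv", "w", newline="",
              encoding="utf-8") as fh:
        w = csv.DictWriter(fh, fieldnames=["eid", "specdate", "spectype",
                                           "result"])
        w.writeheader()
        w.writerows(test_rows)

    # ---------------- phenotype definition fixtures ----------------------
    pheno_dir = out / "phenotypes"
    pheno_dir.mkdir(exist_ok=True)
    (pheno_dir / "covid19.yaml").write_text(
        "name: covid19\n"
        "concept_ids:\n"
        f"  - {CONCEPTS['covid19']}\n"
        f"  - {CONCEPTS['sars_cov2_measurement']}\n"
        "sources:\n"
        "  - covid_tests\n  - hospital\n  - primary_care\n  - death\n",
        encoding="utf-8")
    (pheno_dir / "hypertension.yaml").write_text(
        "name: hypertension\n"
        "concept_ids:\n"
        f"  - {CONCEPTS['hypertensive_disorder']}\n"
        "codelists:\n"
        "  UKB:\n    - '20002-1065'\n"
        "sources:\n"
        "  - baseline\n  - primary_care\n",
        encoding="utf-8")

    # ---------------- ground truth ---------------------------------------
    n_special = exact_count(int(round(epp.get("gp_clinical", 0.0) * n_acc)),
                            config.special_value_rate)
    gt = {
        "config": asdict(config),
        "n_participants": config.n_participants,
        "n_accepted": n_acc,
        "rejections": {
            "missing_year_of_birth": sorted(ctx["missing_yob"]),
            "withdrawn_consent": sorted(ctx["withdrawn"]),
        },
        "covid_cases": sorted(cases),
        "unmappable_only_cases": sorted(unmappable_only),
        "expected_cdm_covid_cases": len(cases) - len(unmappable_only),
        "hypertension": sorted(ctx["ht_set"]),
        "t2dm": sorted(ctx["t2dm_set"]),
        "dead": sorted(death_date),
        "evidence": {e: [{"stream": s, "code": c, "mappable": m, "date": d}
                         for s, c, m, d in ev]
                     for e, ev in sorted(gt_evidence.items())},
        "coverage": tally.as_dict(),
        "special_values": {"count": n_special},
        "defects": {"unit_domain_mismatch_events": len(fx.bad_unit_codes)},
        "provider": {e: ctx["provider"][e] for e in sorted(ctx["provider"])},
        "visit_date": {e: ctx["visit_date"][e]
                       for e in sorted(ctx["visit_date"])},
    }
    with open(out / "ground_truth.json", "w", encoding="utf-8") as fh:
        json.dump(gt, fh, indent=1, sort_keys=True)
    return gt


def generate_bundle(config: GeneratorConfig,
                    out_dir: str | Path) -> dict:
    """One-shot generation: vocabulary fixture under ``out_dir/vocabulary``
    plus the full source bundle and ground truth under ``out_dir``."""
    out = Path(out_dir)
    fx = generate_vocabulary_fixture(config, out / "vocabulary")
    return generate_source_bundle(config, fx, out)
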