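"""EHR ETL: primary care, prescriptions, hospital episodes, deaths, tests.

Routing is concept-driven: each source code resolves through the
vocabulary store (directly for natively standard SNOMED-CT, via official
cross-maps for CTV3/ICD/OPCS/dm+d, via curated custom maps for
vendor-proprietary codes) and the record lands in the CDM table matching
the target concept's domain, with observation as the default sink for
unmapped codes (concept id 0, source code preserved).

Source rows carrying bespoke special values (−1 sensitive, −2 rare
occupation, −3 invalid code, −99 missing code) are excluded before mapping
and individually logged, keeping the stream conservation identity exact.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .cdm import CdmRow, CdmStore, ObservationPeriodRow
from .config import PipelineConfig
from .runlog import EtlLog
from .vocabulary import (VocabularyStore, domain_to_table, resolve_to_standard,
                         select_single_target)

__all__ = [
    "GpEvent", "Prescription", "HospitalEpisode", "DeathRecord", "CovidTest",
    "SPECIAL_VALUES", "filter_special_values",
    "transform_gp_event", "transform_prescription",
    "transform_hospital_episode", "transform_death", "transform_covid_test",
    "build_observation_periods", "derive_drug_eras", "run_ehr_etl",
]

#: bespoke special values and their exclusion reasons
SPECIAL_VALUES = {
    "-1": "sensitive_code",
    "-2": "rare_occupation",
    "-3": "invalid_code",
    "-99": "missing_code",
}

# minus sign variants seen in UK extracts
_MINUS = str.maketrans({"−": "-", "–": "-"})


def _canon_code(code) -> str:
    return str(code).strip().translate(_MINUS)


@dataclass(frozen=True)
class GpEvent:
    source_person_id: str
    provider: str            # EMIS | TPP
    code: str
    vocabulary: str          # SNOMED | CTV3 | EMIS | TPP
    event_date: str
    value: Optional[float] = None
    unit_code: Optional[str] = None


@dataclass(frozen=True)
class Prescription:
    source_person_id: str
    provider: str
    dmd_code: str
    issue_date: str
    quantity: Optional[float] = None


@dataclass(frozen=True)
class HospitalEpisode:
    source_person_id: str
    spell_id: str
    admission_date: str
    discharge_date: str
    diagnoses: tuple = ()     # (code, vocabulary, primary: bool)
    procedures: tuple = ()    # (code, vocabulary, date)
    admission_method: str = ""
    admission_source: str = ""
    discharge_destination: str = ""


@dataclass(frozen=True)
class DeathRecord:
    source_person_id: str
    death_date: str
    causes: tuple = ()        # (icd10 code, underlying: bool)


@dataclass(frozen=True)
class CovidTest:
    source_person_id: str
    test_date: str
    specimen_code: str
    result: str               # positive | negative


# --------------------------------------------------------------------------
# Special values
# --------------------------------------------------------------------------

def filter_special_values(events: Iterable, stream: str = "gp_clinical",
                          etl_log: EtlLog | None = None,
                          ) -> tuple[list, list[tuple[object, str]]]:
    """Drop events whose code is a bespoke special value.

    Returns (kept, exclusions) where each exclusion is (event, reason).
    """
    kept, excluded = [], []
    for ev in events:
        reason = SPECIAL_VALUES.get(_canon_code(ev.code))
        if reason is None:
            kept.append(ev)
        else:
            excluded.append((ev, reason))
            if etl_log is not None:
                etl_log.count_excluded(stream, reason,
                                       f"{ev.source_person_id}:{ev.code}")
    return kept, excluded


# --------------------------------------------------------------------------
# Per-record transforms
# --------------------------------------------------------------------------

def _resolve(store: VocabularyStore, code: str, vocabulary: str,
             config: PipelineConfig):
    cands = resolve_to_standard(store, code, vocabulary)
    return select_single_target(cands, strict_filter=config.strict_filter)


def _source_concept_id(store: VocabularyStore, vocabulary: str, code: str) -> int:
    c = store.get_concept(vocabulary, code)
    return c.concept_id if c else 0


def _resolve_unit(store: VocabularyStore, unit_code: Optional[str],
                  etl_log: EtlLog | None = None) -> int:
    """UCUM first, then the curated vendor-unit map; failures become 0."""
    if not unit_code:
        return 0
    c = store.get_concept("UCUM", unit_code)
    if c is not None and c.standard:
        mapped, cid = True, c.concept_id
    else:
        m = store.get_custom("EMIS_UNIT", unit_code)
        mapped = m is not None
        cid = m.unit_concept_id or m.event_concept_id if m else 0
    if etl_log is not None:
        etl_log.record_mapping("EMIS_UNIT", unit_code, mapped)
    return cid


def transform_gp_event(event: GpEvent, store: VocabularyStore,
                       config: PipelineConfig | None = None,
                       person_id: int = 0,
                       etl_log: EtlLog | None = None) -> CdmRow:
    """Route one primary-care event by its target concept's domain."""
    config = config or PipelineConfig()
    code = _canon_code(event.code)
    target = _resolve(store, code, event.vocabulary, config)
    mapped = target is not None
    if etl_log is not None:
        etl_log.record_mapping(event.vocabulary, code, mapped)
    table = domain_to_table(target.domain) if mapped else "observation"
    row = CdmRow(
        table=table, person_id=person_id,
        event_concept_id=target.concept_id if mapped else 0,
        source_value=code,
        source_concept_id=_source_concept_id(store, event.vocabulary, code),
        start_date=event.event_date,
        type_concept_id=config.type_concepts["gp_clinical"])
    if event.value is not None and table in ("measurement", "observation"):
        row.value_as_number = float(event.value)
        row.unit_concept_id = _resolve_unit(store, event.unit_code, etl_log)
    return row


def transform_prescription(rx: Prescription, store: VocabularyStore,
                           config: PipelineConfig | None = None,
                           person_id: int = 0,
                           period: Optional[tuple[str, str]] = None,
                           etl_log: EtlLog | None = None,
                           ) -> Optional[CdmRow]:
    """dm+d prescription → drug_exposure row (RxNorm target, concept-0
    fallback stays in the drug table). Under the strict observation-period
    policy, issues outside the supplied period are excluded."""
    config = config or PipelineConfig()
    code = _canon_code(rx.dmd_code)
    if (not config.allow_out_of_period and period is not None
            and not (period[0] <= rx.issue_date <= period[1])):
        if etl_log is not None:
            etl_log.count_excluded("gp_scripts", "out_of_observation",
                                   f"{rx.source_person_id}:{code}")
        return None
    target = _resolve(store, code, "DMD", config)
    mapped = target is not None
    if etl_log is not None:
        etl_log.record_mapping("DMD", code, mapped)
    return CdmRow(
        table="drug_exposure", person_id=person_id,
        event_concept_id=target.concept_id if mapped else 0,
        source_value=code,
        source_concept_id=_source_concept_id(store, "DMD", code),
        start_date=rx.issue_date, end_date=rx.issue_date,
        quantity=rx.quantity,
        type_concept_id=config.type_concepts["gp_scripts"])


_EPISODE_ATTRS = (("admission_method", "ADMIMETH"),
                  ("admission_source", "ADMISORC"),
                  ("discharge_destination", "DISDEST"))


def transform_hospital_episode(ep: HospitalEpisode, store: VocabularyStore,
                               config: PipelineConfig | None = None,
                               person_id: int = 0,
                               etl_log: EtlLog | None = None,
                               ) -> Optional[tuple[dict, list[CdmRow], list[CdmRow]]]:
    """One episode → a visit, routed diagnosis/procedure rows, and
    episode-attribute observation rows (admission method/source, discharge
    destination, mapped through the curated attribute maps).

    The returned visit is a plain dict (insert via ``CdmStore.insert_visit``);
    the rows carry ``visit_id=None`` and are linked by the caller once the
    visit id is known. An episode whose admission date follows its
    discharge date is quarantined.
    """
    config = config or PipelineConfig()
    if ep.admission_date > ep.discharge_date:
        if etl_log is not None:
            etl_log.count_quarantined("hospital_episodes", "date_order",
                                      f"{ep.source_person_id}:{ep.spell_id}")
        return None
    visit = {"person_id": person_id, "start": ep.admission_date,
             "end": ep.discharge_date,
             "admitting_source_value": ep.admission_source,
             "discharge_to_source_value": ep.discharge_destination,
             "type_concept_id": config.type_concepts["hospital"]}
    rows: list[CdmRow] = []
    for code, vocab, primary in ep.diagnoses:
        code = _canon_code(code)
        target = _resolve(store, code, vocab, config)
        mapped = target is not None
        if etl_log is not None:
            etl_log.record_mapping(vocab, code, mapped)
        rows.append(CdmRow(
            table=domain_to_table(target.domain) if mapped else "observation",
            person_id=person_id,
            event_concept_id=target.concept_id if mapped else 0,
            source_value=code,
            source_concept_id=_source_concept_id(store, vocab, code),
            start_date=ep.admission_date,
            type_concept_id=config.type_concepts[
                "hospital_primary" if primary else "hospital_secondary"]))
    for code, vocab, pdate in ep.procedures:
        code = _canon_code(code)
        target = _resolve(store, code, vocab, config)
        mapped = target is not None
        if etl_log is not None:
            etl_log.record_mapping(vocab, code, mapped)
        rows.append(CdmRow(
            table=domain_to_table(target.domain) if mapped else "observation",
            person_id=person_id,
            event_concept_id=target.concept_id if mapped else 0,
            source_value=code,
            source_concept_id=_source_concept_id(store, vocab, code),
            start_date=pdate or ep.admission_date,
            type_concept_id=config.type_concepts["hospital"]))
    attr_rows: list[CdmRow] = []
    for attr, vocab in _EPISODE_ATTRS:
        raw = getattr(ep, attr)
        if not str(raw).strip():
            continue
        raw = str(raw).strip()
        m = store.get_custom(vocab, raw)
        mapped = m is not None
        if etl_log is not None:
            etl_log.record_mapping(vocab, raw, mapped)
        attr_rows.append(CdmRow(
            table="observation", person_id=person_id,
            event_concept_id=m.event_concept_id if mapped else 0,
            value_as_concept_id=(m.value_concept_id or None) if mapped else None,
            source_value=raw, start_date=ep.admission_date,
            type_concept_id=config.type_concepts["hospital"]))
    return visit, rows, attr_rows


def transform_death(rec: DeathRecord, store: VocabularyStore,
                    config: PipelineConfig | None = None,
                    person_id: int = 0,
                    etl_log: EtlLog | None = None,
                    ) -> tuple[CdmRow, list[CdmRow]]:
    """Death record → one death-table row (underlying cause) plus routed
    rows for the secondary causes, all dated at death."""
    config = config or PipelineConfig()
    causes = list(rec.causes) or [("", True)]
    underlying = next((c for c in causes if c[1]), causes[0])
    secondary = [c for c in causes if c is not underlying]

    def _cause(code):
        code = _canon_code(code)
        target = _resolve(store, code, "ICD10", config) if code else None
        if etl_log is not None and code:
            etl_log.record_mapping("ICD10_DEATH", code, target is not None)
        return code, target

    ucode, utarget = _cause(underlying[0])
    death_row = CdmRow(
        table="death", person_id=person_id,
        event_concept_id=utarget.concept_id if utarget else 0,
        source_value=ucode or "unknown",
        source_concept_id=_source_concept_id(store, "ICD10", ucode),
        start_date=rec.death_date,
        type_concept_id=config.type_concepts["death"])
    extra: list[CdmRow] = []
    for code, _ in secondary:
        scode, starget = _cause(code)
        extra.append(CdmRow(
            table=domain_to_table(starget.domain) if starget else "observation",
            person_id=person_id,
            event_concept_id=starget.concept_id if starget else 0,
            source_value=scode,
            source_concept_id=_source_concept_id(store, "ICD10", scode),
            start_date=rec.death_date,
            type_concept_id=config.type_concepts["death"]))
    return death_row, extra


def transform_covid_test(t: CovidTest, store: VocabularyStore,
                         config: PipelineConfig | None = None,
                         person_id: int = 0,
                         etl_log: EtlLog | None = None,
                         ) -> Optional[tuple[CdmRow, Optional[CdmRow]]]:
    """Test result → SARS-CoV-2 measurement row (+ linked specimen row).

    The common measurement concept and the positive/negative value
    concepts come from the curated map (vocabulary tag COVID_TEST); an
    unrecognised result token quarantines the record.
    """
    config = config or PipelineConfig()
    result = str(t.result).strip().lower()
    value_map = store.get_custom("COVID_TEST", result)
    if value_map is None:
        if etl_log is not None:
            etl_log.count_quarantined("covid_tests", "unknown_result",
                                      f"{t.source_person_id}:{t.result}")
        return None
    event_map = store.get_custom("COVID_TEST", "sars-cov-2-test")
    meas = CdmRow(
        table="measurement", person_id=person_id,
        event_concept_id=event_map.event_concept_id if event_map else 0,
        value_as_concept_id=value_map.value_concept_id or value_map.event_concept_id,
        source_value=f"covid_test:{result}",
        start_date=t.test_date,
        type_concept_id=config.type_concepts["covid_test"])
    specimen_row = None
    spec = str(t.specimen_code).strip()
    if spec:
        sm = store.get_custom("SPECIMEN", spec)
        specimen_row = CdmRow(
            table="specimen", person_id=person_id,
            event_concept_id=sm.event_concept_id if sm else 0,
            source_value=spec, start_date=t.test_date,
            type_concept_id=config.type_concepts["covid_test"])
    return meas, specimen_row


# --------------------------------------------------------------------------
# Derived tables
# --------------------------------------------------------------------------

def build_observation_periods(event_dates: dict[int, list[str]],
                              ) -> list[ObservationPeriodRow]:
    """One period per person spanning min to max known event date
    (baseline visit and death included by the caller)."""
    periods = []
    for pid in sorted(event_dates):
        dates = [d for d in event_dates[pid] if d]
        if not dates:
            continue
        periods.append(ObservationPeriodRow(pid, min(dates), max(dates)))
    return periods


def derive_drug_eras(drug_rows: Sequence[dict], gap_days: int = 30,
                     ) -> list[dict]:
    """Merge per-person, per-drug exposures separated by ≤ gap_days into
    continuous eras. Concept-0 exposures never form eras."""
    groups: dict[tuple[int, int], list[tuple[date, date]]] = defaultdict(list)
    for r in drug_rows:
        cid = r.get("drug_concept_id") or 0
        if cid == 0:
            continue
        start = date.fromisoformat(r["drug_exposure_start_date"])
        end_s = r.get("drug_exposure_end_date")
        end = date.fromisoformat(end_s) if end_s else start
        groups[(r["person_id"], cid)].append((start, max(start, end)))
    eras: list[dict] = []
    era_id = 1
    for (pid, cid) in sorted(groups):
        spans = sorted(groups[(pid, cid)])
        cur_start, cur_end, n = spans[0][0], spans[0][1], 1
        merged = []
        for s, e in spans[1:]:
            if (s - cur_end).days <= gap_days:
                cur_end = max(cur_end, e)
                n += 1
            else:
                merged.append((cur_start, cur_end, n))
                cur_start, cur_end, n = s, e, 1
        merged.append((cur_start, cur_end, n))
        for s, e, n in merged:
            eras.append({"drug_era_id": era_id, "person_id": pid,
                         "drug_concept_id": cid,
                         "drug_era_start_date": s.isoformat(),
                         "drug_era_end_date": e.isoformat(),
                         "drug_exposure_count": n, "gap_days": gap_days})
            era_id += 1
    return eras


# --------------------------------------------------------------------------
# Stream runner
# --------------------------------------------------------------------------

def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str).fillna("")


def run_ehr_etl(bundle_dir: str | Path,
                store: VocabularyStore,
                cdm: CdmStore,
                person_ids: dict[str, int],
                config: PipelineConfig | None = None,
                etl_log: EtlLog | None = None,
                baseline_visit_dates: dict[int, str] | None = None,
                ) -> None:
    """Run every EHR stream found in ``bundle_dir`` and derive the
    observation periods and drug eras.

    ``person_ids`` maps accepted source ids to surrogate ids; rows of any
    other participant are counted against the rejected-person term of the
    conservation identity.
    """
    config = config or PipelineConfig()
    etl_log = etl_log or EtlLog()
    bundle = Path(bundle_dir)
    event_dates: dict[int, list[str]] = defaultdict(list)
    if baseline_visit_dates:
        for pid, d in baseline_visit_dates.items():
            event_dates[pid].append(d)

    def _pid(stream: str, eid: str) -> Optional[int]:
        pid = person_ids.get(str(eid))
        if pid is None:
            etl_log.count_rejected_person(stream)
        return pid

    # -- GP clinical -------------------------------------------------------
    gp_path = bundle / "gp_clinical.csv"
    if gp_path.exists():
        events = []
        for _, r in _read_csv(gp_path).iterrows():
            etl_log.count_input("gp_clinical")
            events.append(GpEvent(
                source_person_id=str(r["eid"]), provider=r["data_provider"],
                code=r["code"], vocabulary=r["vocab"],
                event_date=r["event_dt"],
                value=float(r["value"]) if r["value"] else None,
                unit_code=r["unit"] or None))
        kept, _ = filter_special_values(events, "gp_clinical", etl_log)
        for ev in kept:
            pid = _pid("gp_clinical", ev.source_person_id)
            if pid is None:
                continue
            row = transform_gp_event(ev, store, config, pid, etl_log)
            cdm.insert_row(row)
            etl_log.count_emitted("gp_clinical")
            event_dates[pid].append(ev.event_date)

    # -- GP prescriptions --------------------------------------------------
    rx_path = bundle / "gp_scripts.csv"
    if rx_path.exists():
        for _, r in _read_csv(rx_path).iterrows():
            etl_log.count_input("gp_scripts")
            rx = Prescription(str(r["eid"]), r["data_provider"],
                              r["dmd_code"], r["issue_date"],
                              float(r["quantity"]) if r["quantity"] else None)
            pid = _pid("gp_scripts", rx.source_person_id)
            if pid is None:
                continue
            row = transform_prescription(rx, store, config, pid,
                                         etl_log=etl_log)
            if row is not None:
                cdm.insert_row(row)
                etl_log.count_emitted("gp_scripts")
                event_dates[pid].append(rx.issue_date)

    # -- Hospital episodes -------------------------------------------------
    ep_path = bundle / "hesin.csv"
    dp_path = bundle / "hesin_diag_proc.csv"
    if ep_path.exists():
        diag_proc: dict[str, list[dict]] = defaultdict(list)
        if dp_path.exists():
            for _, r in _read_csv(dp_path).iterrows():
                etl_log.count_input("hospital_records")
                diag_proc[str(r["spell_id"])].append(dict(r))
        for _, r in _read_csv(ep_path).iterrows():
            etl_log.count_input("hospital_episodes")
            spell = str(r["spell_id"])
            entries = diag_proc.get(spell, [])
            diagnoses = tuple(
                (d["code"], d["vocab"], str(d.get("position")) == "1")
                for d in entries if d["kind"] == "diag")
            procedures = tuple(
                (d["code"], d["vocab"], r["admidate"])
                for d in entries if d["kind"] == "proc")
            ep = HospitalEpisode(
                source_person_id=str(r["eid"]), spell_id=spell,
                admission_date=r["admidate"], discharge_date=r["disdate"],
                diagnoses=diagnoses, procedures=procedures,
                admission_method=r.get("admimeth", ""),
                admission_source=r.get("admisorc", ""),
                discharge_destination=r.get("disdest", ""))
            pid = _pid("hospital_episodes", ep.source_person_id)
            if pid is None:
                etl_log.count_rejected_person("hospital_records", len(entries))
                continue
            result = transform_hospital_episode(ep, store, config, pid,
                                                etl_log)
            if result is None:
                # episode itself was quarantined inside the transform; its
                # diagnosis/procedure rows are quarantined with it
                for _ in entries:
                    etl_log.count_quarantined(
                        "hospital_records", "episode_quarantined", spell)
                continue
            visit, rows, attr_rows = result
            vid = cdm.insert_visit(
                visit["person_id"], visit["start"], visit["end"],
                visit["type_concept_id"],
                admitting_source_value=visit["admitting_source_value"],
                discharge_to_source_value=visit["discharge_to_source_value"])
            etl_log.count_emitted("hospital_episodes")
            for row in rows + attr_rows:
                row.visit_id = vid
                cdm.insert_row(row)
            etl_log.count_emitted("hospital_records", len(rows))
            etl_log.count_input("hospital_attributes", len(attr_rows))
            etl_log.count_emitted("hospital_attributes", len(attr_rows))
            event_dates[pid].extend([ep.admission_date, ep.discharge_date])

    # -- Death registry ----------------------------------------------------
    death_path = bundle / "death.csv"
    if death_path.exists():
        by_person: dict[str, list[dict]] = defaultdict(list)
        for _, r in _read_csv(death_path).iterrows():
            etl_log.count_input("death")
            by_person[str(r["eid"])].append(dict(r))
        for eid in sorted(by_person):
            rows_in = by_person[eid]
            pid = _pid("death", eid)
            if pid is None:
                etl_log.count_rejected_person("death", len(rows_in) - 1)
                continue
            dates = sorted({r["date_of_death"] for r in rows_in})
            if len(dates) > 1:
                for r in rows_in:
                    if r["date_of_death"] != dates[0]:
                        etl_log.count_excluded(
                            "death", "conflicting_death_date",
                            f"{eid}:{r['date_of_death']}")
                rows_in = [r for r in rows_in if r["date_of_death"] == dates[0]]
            causes = tuple((r["cause_icd10"],
                            str(r.get("underlying_flag")) == "1")
                           for r in rows_in)
            rec = DeathRecord(eid, dates[0], causes)
            death_row, extra = transform_death(rec, store, config, pid,
                                               etl_log)
            cdm.insert_row(death_row)
            for row in extra:
                cdm.insert_row(row)
            etl_log.count_emitted("death", len(rows_in))
            event_dates[pid].append(dates[0])

    # -- COVID-19 tests ----------------------------------------------------
    ct_path = bundle / "covid_tests.csv"
    if ct_path.exists():
        for _, r in _read_csv(ct_path).iterrows():
            etl_log.count_input("covid_tests")
            t = CovidTest(str(r["eid"]), r["specdate"], r["spectype"],
                          r["result"])
            pid = _pid("covid_tests", t.source_person_id)
            if pid is None:
                continue
            result = transform_covid_test(t, store, config, pid, etl_log)
            if result is None:
                continue
            meas, specimen = result
            cdm.insert_row(meas)
            if specimen is not None:
                cdm.insert_row(specimen)
            etl_log.count_emitted("covid_tests")
            event_dates[pid].append(t.test_date)

    # -- derived tables ----------------------------------------------------
    for rec in cdm.rows("death"):
        event_dates[rec["person_id"]].append(rec["death_date"])
    for p in build_observation_periods(event_dates):
        cdm.insert_observation_period(p, config.type_concepts["baseline"])
    for era in derive_drug_eras(cdm.rows("drug_exposure"),
                                config.drug_era_gap_days):
        cdm.tables["drug_era"].append(era)
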