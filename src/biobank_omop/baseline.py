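"""Baseline questionnaire ETL: wide-to-long traversal and two-step mapping.

The baseline extract is one row per participant with columns named
``<field>-<instance>.<array>`` (field id, repeat visit index, repeat answer
index). Each non-empty cell becomes one long-format record dated at the
matching visit's assessment date. Records then map to standard concepts in
two steps: the bespoke field/value pair is first annotated with its source
(non-standard) concept, then a curated custom mapping table supplies the
standard event concept and, for categorical answers, the
``value_as_concept_id``. Numeric fields additionally resolve their declared
UCUM unit. Anything without a curated mapping falls back to an observation
row with concept id 0 and the field id as source value, so no record is
silently dropped.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd

from .cdm import CdmRow, CdmStore, PersonRow
from .config import PipelineConfig
from .runlog import EtlLog
from .vocabulary import VocabularyStore, domain_to_table

__all__ = [
    "BaselineFieldMeta",
    "LongRecord",
    "PersonRejection",
    "load_field_dictionary",
    "wide_to_long",
    "classify_field",
    "transform_baseline_record",
    "build_person",
    "run_baseline_etl",
    "GENDER_FIELD",
    "YOB_FIELD",
    "ETHNICITY_FIELD",
    "VISIT_DATE_FIELD",
]

# bespoke field ids carrying person-level demographics; their cells feed the
# person table rather than long clinical records
GENDER_FIELD = 31
YOB_FIELD = 34
ETHNICITY_FIELD = 21000
VISIT_DATE_FIELD = 53

_HEADER_RE = re.compile(r"^(\d+)-(\d+)\.(\d+)$")
_TRUE_TOKENS = {"1", "yes", "true", "y"}
_FALSE_TOKENS = {"0", "no", "false", "n"}
#: bespoke special answers (prefer-not-to-answer, unknown, ...)
_SPECIAL_ANSWERS = {"-1", "-2", "-3", "-99"}


@dataclass(frozen=True)
class BaselineFieldMeta:
    field_id: int
    value_kind: str  # numeric | boolean | categorical
    unit: Optional[str] = None          # UCUM code for numeric fields
    date_source: int = VISIT_DATE_FIELD  # field id of the visit-date field


@dataclass(frozen=True)
class LongRecord:
    source_person_id: str
    field_id: int
    instance: int
    array_index: int
    raw_value: str
    event_date: str


@dataclass(frozen=True)
class PersonRejection:
    source_person_id: str
    reason: str


def load_field_dictionary(path: str | Path) -> dict[int, BaselineFieldMeta]:
    """Field dictionary CSV: field_id, value_kind, ucum_unit, date_field_id."""
    meta: dict[int, BaselineFieldMeta] = {}
    with open(path, encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            fid = int(row["field_id"])
            meta[fid] = BaselineFieldMeta(
                field_id=fid,
                value_kind=row["value_kind"].strip(),
                unit=(row.get("ucum_unit") or "").strip() or None,
                date_source=int(row.get("date_field_id") or VISIT_DATE_FIELD),
            )
    return meta


def _parse_header(col: str) -> tuple[int, int, int]:
    m = _HEADER_RE.match(col)
    if not m:
        raise ValueError(f"unparseable baseline column header: {col!r}")
    return int(m.group(1)), int(m.group(2)), int(m.group(3))


def wide_to_long(wide: pd.DataFrame,
                 field_dictionary: dict[int, BaselineFieldMeta],
                 ) -> Iterator[LongRecord]:
    """Traverse the wide table into one record per non-empty clinical cell.

    Cells of demographic fields (sex, year of birth, ethnicity) and of
    visit-date fields are treated as person- and date-level metadata, not
    clinical events. The event date is taken from the record's own
    instance; a missing date column of that instance falls back to the
    instance-0 date.
    """
    cols = [c for c in wide.columns if c != "eid"]
    parsed = {c: _parse_header(c) for c in cols}
    date_fields = {m.date_source for m in field_dictionary.values()}
    date_fields.add(VISIT_DATE_FIELD)
    meta_fields = {GENDER_FIELD, YOB_FIELD, ETHNICITY_FIELD} | date_fields

    date_cols: dict[tuple[int, int], str] = {
        (f, inst): c for c, (f, inst, arr) in parsed.items()
        if f in date_fields and arr == 0}

    for _, row in wide.iterrows():
        eid = str(row["eid"])
        for c in cols:
            fid, inst, arr = parsed[c]
            if fid in meta_fields:
                continue
            v = row[c]
            if pd.isna(v) or str(v).strip() == "":
                continue
            meta = field_dictionary.get(fid)
            dsrc = meta.date_source if meta else VISIT_DATE_FIELD
            dcol = date_cols.get((dsrc, inst)) or date_cols.get((dsrc, 0))
            event_date = ""
            if dcol is not None and not pd.isna(row[dcol]):
                event_date = str(row[dcol]).strip()
            yield LongRecord(eid, fid, inst, arr, str(v).strip(), event_date)


def classify_field(meta: Optional[BaselineFieldMeta], raw_value: str,
                   store: Optional[VocabularyStore] = None,
                   field_id: Optional[int] = None) -> str:
    """Dispatch tag for one record: numeric|boolean|categorical|unmapped."""
    if meta is None:
        if store is not None and field_id is not None and (
                store.get_custom("UKB", f"{field_id}-{raw_value}") is not None
                or store.get_custom("UKB", str(field_id)) is not None):
            return "categorical"
        return "unmapped"
    if meta.value_kind == "numeric":
        try:
            float(raw_value)
            return "numeric"
        except ValueError:
            return "quarantine"
    return meta.value_kind


def transform_baseline_record(record: LongRecord, store: VocabularyStore,
                              meta: Optional[BaselineFieldMeta] = None,
                              config: PipelineConfig | None = None,
                              person_id: int | None = None,
                              etl_log: EtlLog | None = None,
                              ) -> Optional[CdmRow]:
    """Map one long record to a routed CDM row (two-step mapping).

    Returns None only for a quarantined or negative-boolean record; every
    mappable or unmappable record yields a row (concept-0 fallback).
    """
    config = config or PipelineConfig()
    tag = classify_field(meta, record.raw_value, store, record.field_id)
    type_cid = config.type_concepts["baseline"]
    pid = person_id if person_id is not None else 0
    value_key = f"{record.field_id}-{record.raw_value}"
    field_key = str(record.field_id)

    def _source_concept(code: str) -> int:
        c = store.get_concept("UKB", code)
        return c.concept_id if c else 0

    def _log(code: str, mapped: bool) -> None:
        if etl_log is not None:
            etl_log.record_mapping("UKB", code, mapped)

    if tag == "quarantine":
        if etl_log is not None:
            etl_log.count_quarantined(
                "baseline", "nonnumeric_value",
                f"{record.source_person_id}:{value_key}")
        return None

    if tag == "numeric":
        custom = store.get_custom("UKB", field_key)
        unit_cid = 0
        if meta is not None and meta.unit:
            unit_concept = store.get_concept("UCUM", meta.unit)
            unit_cid = unit_concept.concept_id if unit_concept else 0
        if custom is not None:
            event = store.concept_by_id(custom.event_concept_id)
            _log(field_key, True)
            return CdmRow(
                table=domain_to_table(event.domain if event else None),
                person_id=pid,
                event_concept_id=custom.event_concept_id,
                source_value=field_key,
                source_concept_id=_source_concept(field_key),
                start_date=record.event_date,
                value_as_number=float(record.raw_value),
                unit_concept_id=(custom.unit_concept_id or unit_cid),
                type_concept_id=type_cid)
        _log(field_key, False)
        return CdmRow(table="observation", person_id=pid,
                      event_concept_id=0, source_value=field_key,
                      source_concept_id=_source_concept(field_key),
                      start_date=record.event_date,
                      value_as_number=float(record.raw_value),
                      unit_concept_id=unit_cid, type_concept_id=type_cid)

    if tag == "boolean":
        token = record.raw_value.strip().lower()
        if token not in _TRUE_TOKENS and not config.emit_negative_booleans:
            if etl_log is not None:
                etl_log.count_excluded(
                    "baseline", "negative_boolean",
                    f"{record.source_person_id}:{value_key}")
            return None
        custom = store.get_custom("UKB", field_key)
        mapped = custom is not None
        _log(field_key, mapped)
        event = store.concept_by_id(custom.event_concept_id) if mapped else None
        return CdmRow(
            table=domain_to_table(event.domain if event else None),
            person_id=pid,
            event_concept_id=custom.event_concept_id if mapped else 0,
            value_as_concept_id=(custom.value_concept_id or None) if mapped else None,
            source_value=field_key,
            source_concept_id=_source_concept(field_key),
            start_date=record.event_date, type_concept_id=type_cid)

    # categorical (value-level, falling back to field-level) and unmapped
    custom = (store.get_custom("UKB", value_key)
              or store.get_custom("UKB", field_key))
    if custom is not None:
        event = store.concept_by_id(custom.event_concept_id)
        _log(value_key, True)
        return CdmRow(
            table=domain_to_table(event.domain if event else None),
            person_id=pid,
            event_concept_id=custom.event_concept_id,
            value_as_concept_id=custom.value_concept_id or None,
            source_value=value_key,
            source_concept_id=_source_concept(value_key),
            start_date=record.event_date, type_concept_id=type_cid)
    _log(value_key, False)

    # unmapped fallback: observation row, concept 0, field id preserved
    return CdmRow(table="observation", person_id=pid,
                  event_concept_id=0, source_value=field_key,
                  source_concept_id=_source_concept(value_key),
                  start_date=record.event_date, type_concept_id=type_cid)


def build_person(wide_row: pd.Series, store: VocabularyStore,
                 person_id: int) -> PersonRow | PersonRejection:
    """Demographics for one participant, or a rejection that cascades.

    A missing or special-valued year of birth rejects the participant with
    all associated data across every source stream.
    """
    eid = str(wide_row["eid"])
    yob_raw = wide_row.get(f"{YOB_FIELD}-0.0")
    yob_str = "" if yob_raw is None or pd.isna(yob_raw) else str(yob_raw).strip()
    if yob_str == "" or yob_str in _SPECIAL_ANSWERS:
        return PersonRejection(eid, "missing_year_of_birth")
    try:
        yob = int(float(yob_str))
    except ValueError:
        return PersonRejection(eid, "missing_year_of_birth")

    gender_raw = wide_row.get(f"{GENDER_FIELD}-0.0")
    gender_sv = "" if gender_raw is None or pd.isna(gender_raw) else str(gender_raw).strip()
    gender_cid = 0
    gm = store.get_custom("UKB", f"{GENDER_FIELD}-{gender_sv}")
    if gm is not None:
        gender_cid = gm.event_concept_id

    eth_raw = wide_row.get(f"{ETHNICITY_FIELD}-0.0")
    eth_sv = "" if eth_raw is None or pd.isna(eth_raw) else str(eth_raw).strip()
    eth_cid = 0
    em = store.get_custom("UKB", f"{ETHNICITY_FIELD}-{eth_sv}")
    if em is not None:
        eth_cid = em.event_concept_id

    return PersonRow(person_id=person_id, source_person_id=eid,
                     gender_concept_id=gender_cid, year_of_birth=yob,
                     ethnicity_concept_id=eth_cid,
                     gender_source_value=gender_sv)


def run_baseline_etl(baseline_csv: str | Path,
                     field_dictionary: str | Path | dict,
                     store: VocabularyStore,
                     cdm: CdmStore,
                     config: PipelineConfig | None = None,
                     etl_log: EtlLog | None = None,
                     withdrawals: Iterable[str] = (),
                     ) -> tuple[dict[str, int], dict[str, str]]:
    """Full baseline stage.

    Returns ``(person_ids, rejections)``: accepted source id → surrogate
    person_id (assigned by lexicographic enumeration of source ids, so
    re-runs are reproducible), and rejected source id → reason.
    """
    config = config or PipelineConfig()
    etl_log = etl_log or EtlLog()
    meta = (field_dictionary if isinstance(field_dictionary, dict)
            else load_field_dictionary(field_dictionary))
    wide = pd.read_csv(baseline_csv, dtype=str)
    withdrawn = {str(w) for w in withdrawals}

    # pass 1: person acceptance and surrogate id assignment
    rejections: dict[str, str] = {}
    accepted_rows: dict[str, pd.Series] = {}
    for _, row in wide.iterrows():
        eid = str(row["eid"])
        if eid in withdrawn:
            rejections[eid] = "withdrawn_consent"
            continue
        accepted_rows[eid] = row
    person_ids = {eid: i + 1
                  for i, eid in enumerate(sorted(accepted_rows))}
    persons: dict[str, PersonRow] = {}
    for eid in sorted(accepted_rows):
        p = build_person(accepted_rows[eid], store, person_ids[eid])
        if isinstance(p, PersonRejection):
            rejections[eid] = p.reason
            del person_ids[eid]
        else:
            persons[eid] = p
    # re-enumerate after rejections so surrogate ids stay dense
    person_ids = {eid: i + 1 for i, eid in enumerate(sorted(person_ids))}
    for eid, p in persons.items():
        p.person_id = person_ids[eid]
        cdm.insert_person(p)

    # pass 2: long records
    for rec in wide_to_long(wide, meta):
        etl_log.count_input("baseline")
        if rec.source_person_id in rejections:
            etl_log.count_rejected_person("baseline")
            continue
        row = transform_baseline_record(
            rec, store, meta.get(rec.field_id), config,
            person_id=person_ids[rec.source_person_id], etl_log=etl_log)
        if row is not None:
            cdm.insert_row(row)
            etl_log.count_emitted("baseline")
    return person_ids, rejections
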