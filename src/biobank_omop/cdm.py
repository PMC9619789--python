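"""OMOP CDM v5.3 schema, row types and a lightweight relational store.

The CDM organises 23 tables into four groups: clinical data (15 tables,
person-centric events), derived elements (3, e.g. drug eras), health-system
tables (3, providers/locations) and health economics (2, created here but
never populated). Event records produced by the ETL are represented by a
single generic :class:`CdmRow` and routed to a concrete table; per-table
column names (``observation_concept_id`` vs ``condition_concept_id`` ...)
are applied on insertion.
"""

from __future__ import annotations

import csv
import sqlite3
from dataclasses import dataclass, field, asdict
from datetime import date
from pathlib import Path
from typing import Iterable, Optional

__all__ = [
    "CdmTableDef",
    "CdmRow",
    "PersonRow",
    "ObservationPeriodRow",
    "CdmStore",
    "build_schema",
    "validate_row",
    "TABLE_GROUPS",
    "ROUTED_TABLES",
]


# --------------------------------------------------------------------------
# Schema definition
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CdmTableDef:
    """One CDM table: name, top-level group and ordered column spec.

    ``columns`` is a tuple of ``(column_name, logical_type, required)``;
    ``primary_key`` names the surrogate-key column (first column by
    convention for event tables).
    """

    name: str
    group: str  # clinical | derived | health_system | health_economics
    columns: tuple[tuple[str, str, bool], ...]
    primary_key: str

    def column_names(self) -> list[str]:
        return [c[0] for c in self.columns]

    def required_columns(self) -> list[str]:
        return [c[0] for c in self.columns if c[2]]


def _event_columns(prefix: str, *, value: bool = False, unit: bool = False,
                   visit: bool = True, end_date: bool = False,
                   extra: tuple = ()) -> tuple:
    cols = [
        (f"{prefix}_id", "integer", True),
        ("person_id", "integer", True),
        (f"{prefix}_concept_id", "integer", True),
        (f"{prefix}_date" if not end_date else f"{prefix}_start_date", "date", True),
    ]
    if end_date:
        cols.append((f"{prefix}_end_date", "date", False))
    cols.append((f"{prefix}_type_concept_id", "integer", True))
    if value:
        cols.append(("value_as_number", "float", False))
        cols.append(("value_as_concept_id", "integer", False))
    if unit:
        cols.append(("unit_concept_id", "integer", False))
    cols.append((f"{prefix}_source_value", "string", True))
    cols.append((f"{prefix}_source_concept_id", "integer", False))
    if visit:
        cols.append(("visit_occurrence_id", "integer", False))
    cols.extend(extra)
    return tuple(cols)


def build_schema() -> dict[str, CdmTableDef]:
    """Return the complete 23-table CDM v5.3 schema keyed by table name.

    Group cardinalities are clinical=15, derived=3, health_system=3,
    health_economics=2. Only the populated subset carries a full column
    spec; the remaining tables get their key columns so DDL emission still
    creates all 23.
    """
    t: list[CdmTableDef] = []

    def add(name, group, columns, pk=None):
        t.append(CdmTableDef(name, group, tuple(columns), pk or columns[0][0]))

    # -- clinical (15)
    add("person", "clinical", [
        ("person_id", "integer", True),
        ("gender_concept_id", "integer", True),
        ("year_of_birth", "integer", True),
        ("race_concept_id", "integer", False),
        ("ethnicity_concept_id", "integer", False),
        ("person_source_value", "string", False),
        ("gender_source_value", "string", False),
    ])
    add("observation_period", "clinical", [
        ("observation_period_id", "integer", True),
        ("person_id", "integer", True),
        ("observation_period_start_date", "date", True),
        ("observation_period_end_date", "date", True),
        ("period_type_concept_id", "integer", True),
    ])
    add("visit_occurrence", "clinical", [
        ("visit_occurrence_id", "integer", True),
        ("person_id", "integer", True),
        ("visit_concept_id", "integer", True),
        ("visit_start_date", "date", True),
        ("visit_end_date", "date", True),
        ("visit_type_concept_id", "integer", True),
        ("admitting_source_value", "string", False),
        ("discharge_to_source_value", "string", False),
    ])
    add("visit_detail", "clinical", [
        ("visit_detail_id", "integer", True),
        ("person_id", "integer", True),
        ("visit_detail_concept_id", "integer", True),
        ("visit_detail_start_date", "date", True),
        ("visit_detail_end_date", "date", True),
    ])
    add("condition_occurrence", "clinical",
        _event_columns("condition", end_date=True))
    add("drug_exposure", "clinical", [
        ("drug_exposure_id", "integer", True),
        ("person_id", "integer", True),
        ("drug_concept_id", "integer", True),
        ("drug_exposure_start_date", "date", True),
        ("drug_exposure_end_date", "date", False),
        ("drug_type_concept_id", "integer", True),
        ("quantity", "float", False),
        ("drug_source_value", "string", True),
        ("drug_source_concept_id", "integer", False),
        ("visit_occurrence_id", "integer", False),
    ])
    add("procedure_occurrence", "clinical", _event_columns("procedure"))
    add("device_exposure", "clinical", [
        ("device_exposure_id", "integer", True),
        ("person_id", "integer", True),
        ("device_concept_id", "integer", True),
        ("device_exposure_start_date", "date", True),
        ("device_type_concept_id", "integer", True),
        ("device_source_value", "string", True),
        ("device_source_concept_id", "integer", False),
        ("visit_occurrence_id", "integer", False),
    ])
    add("measurement", "clinical",
        _event_columns("measurement", value=True, unit=True))
    add("observation", "clinical",
        _event_columns("observation", value=True, unit=True))
    add("death", "clinical", [
        ("person_id", "integer", True),
        ("death_date", "date", True),
        ("death_type_concept_id", "integer", True),
        ("cause_concept_id", "integer", False),
        ("cause_source_value", "string", False),
        ("cause_source_concept_id", "integer", False),
    ], pk="person_id")
    add("note", "clinical", [
        ("note_id", "integer", True),
        ("person_id", "integer", True),
        ("note_date", "date", True),
        ("note_text", "string", True),
    ])
    add("note_nlp", "clinical", [
        ("note_nlp_id", "integer", True),
        ("note_id", "integer", True),
        ("lexical_variant", "string", True),
    ])
    add("specimen", "clinical", [
        ("specimen_id", "integer", True),
        ("person_id", "integer", True),
        ("specimen_concept_id", "integer", True),
        ("specimen_date", "date", True),
        ("specimen_type_concept_id", "integer", True),
        ("specimen_source_value", "string", False),
    ])
    add("fact_relationship", "clinical", [
        ("fact_relationship_id", "integer", True),
        ("domain_concept_id_1", "integer", True),
        ("fact_id_1", "integer", True),
        ("domain_concept_id_2", "integer", True),
        ("fact_id_2", "integer", True),
        ("relationship_concept_id", "integer", True),
    ])

    # -- derived elements (3)
    add("drug_era", "derived", [
        ("drug_era_id", "integer", True),
        ("person_id", "integer", True),
        ("drug_concept_id", "integer", True),
        ("drug_era_start_date", "date", True),
        ("drug_era_end_date", "date", True),
        ("drug_exposure_count", "integer", False),
        ("gap_days", "integer", False),
    ])
    add("dose_era", "derived", [
        ("dose_era_id", "integer", True),
        ("person_id", "integer", True),
        ("drug_concept_id", "integer", True),
        ("dose_era_start_date", "date", True),
        ("dose_era_end_date", "date", True),
    ])
    add("condition_era", "derived", [
        ("condition_era_id", "integer", True),
        ("person_id", "integer", True),
        ("condition_concept_id", "integer", True),
        ("condition_era_start_date", "date", True),
        ("condition_era_end_date", "date", True),
    ])

    # -- health system (3)
    add("location", "health_system", [
        ("location_id", "integer", True),
        ("city", "string", False),
        ("zip", "string", False),
    ])
    add("care_site", "health_system", [
        ("care_site_id", "integer", True),
        ("care_site_name", "string", False),
        ("location_id", "integer", False),
    ])
    add("provider", "health_system", [
        ("provider_id", "integer", True),
        ("provider_name", "string", False),
        ("care_site_id", "integer", False),
    ])

    # -- health economics (2): schema-only, never populated by this ETL
    add("payer_plan_period", "health_economics", [
        ("payer_plan_period_id", "integer", True),
        ("person_id", "integer", True),
        ("payer_plan_period_start_date", "date", True),
        ("payer_plan_period_end_date", "date", True),
    ])
    add("cost", "health_economics", [
        ("cost_id", "integer", True),
        ("cost_event_id", "integer", True),
        ("cost_domain_id", "string", True),
        ("total_cost", "float", False),
    ])

    schema = {d.name: d for d in t}
    assert len(schema) == 23
    return schema


TABLE_GROUPS = ("clinical", "derived", "health_system", "health_economics")

#: event tables a routed CdmRow may land in, with the column-name prefix used
ROUTED_TABLES = {
    "measurement": "measurement",
    "condition_occurrence": "condition",
    "observation": "observation",
    "procedure_occurrence": "procedure",
    "drug_exposure": "drug",
    "device_exposure": "device",
    "specimen": "specimen",
}


# --------------------------------------------------------------------------
# Row types
# --------------------------------------------------------------------------

@dataclass
class PersonRow:
    person_id: int
    source_person_id: str
    gender_concept_id: int
    year_of_birth: int
    ethnicity_concept_id: int = 0
    gender_source_value: str = ""


@dataclass
class ObservationPeriodRow:
    person_id: int
    period_start: str  # ISO date
    period_end: str


@dataclass
class CdmRow:
    """A routed clinical event record destined for one CDM table."""

    table: str
    person_id: int
    event_concept_id: int
    source_value: str
    start_date: str  # ISO-8601
    source_concept_id: int = 0
    end_date: Optional[str] = None
    value_as_number: Optional[float] = None
    value_as_concept_id: Optional[int] = None
    unit_concept_id: Optional[int] = None
    type_concept_id: int = 0
    visit_id: Optional[int] = None
    quantity: Optional[float] = None


def _parse_iso(s) -> Optional[date]:
    try:
        return date.fromisoformat(str(s))
    except (ValueError, TypeError):
        return None


def validate_row(table: CdmTableDef, row) -> list[str]:
    """Structural validation; returns a list of violation codes (empty = valid).

    Pure function of its inputs. Understands the three row dataclasses and
    plain per-table dicts.
    """
    violations: list[str] = []
    if isinstance(row, CdmRow):
        if row.table != table.name:
            violations.append(f"table_mismatch:{row.table}")
        if not str(row.source_value):
            violations.append("missing_required:source_value")
        if not row.start_date or _parse_iso(row.start_date) is None:
            violations.append("missing_required:start_date"
                              if not row.start_date else "bad_date:start_date")
        if row.end_date is not None:
            d2 = _parse_iso(row.end_date)
            d1 = _parse_iso(row.start_date)
            if d2 is None:
                violations.append("bad_date:end_date")
            elif d1 is not None and d2 < d1:
                violations.append("date_order")
        return violations
    if isinstance(row, PersonRow):
        if row.year_of_birth is None:
            violations.append("missing_required:year_of_birth")
        elif not (1900 <= int(row.year_of_birth) <= date.today().year):
            violations.append("implausible:year_of_birth")
        return violations
    if isinstance(row, ObservationPeriodRow):
        d1, d2 = _parse_iso(row.period_start), _parse_iso(row.period_end)
        if d1 is None:
            violations.append("missing_required:period_start")
        if d2 is None:
            violations.append("missing_required:period_end")
        if d1 and d2 and d2 < d1:
            violations.append("date_order")
        return violations
    # dict row against the table's column spec
    for name in table.required_columns():
        v = row.get(name) if isinstance(row, dict) else None
        if v is None or v == "":
            violations.append(f"missing_required:{name}")
    return violations


# --------------------------------------------------------------------------
# Store
# --------------------------------------------------------------------------

class CdmStore:
    """In-memory CDM instance: dict-of-lists of concrete per-table rows.

    Routed :class:`CdmRow` records are translated to the target table's
    column names on insertion; surrogate ids are assigned sequentially per
    table so re-runs over identically ordered input are reproducible.
    """

    def __init__(self, schema: dict[str, CdmTableDef] | None = None):
        self.schema = schema or build_schema()
        self.tables: dict[str, list[dict]] = {n: [] for n in self.schema}
        self._next_id = {n: 1 for n in self.schema}

    # -- insertion ---------------------------------------------------------
    def _take_id(self, table: str) -> int:
        i = self._next_id[table]
        self._next_id[table] = i + 1
        return i

    def insert_person(self, p: PersonRow) -> None:
        self.tables["person"].append({
            "person_id": p.person_id,
            "gender_concept_id": p.gender_concept_id,
            "year_of_birth": p.year_of_birth,
            "race_concept_id": 0,
            "ethnicity_concept_id": p.ethnicity_concept_id,
            "person_source_value": p.source_person_id,
            "gender_source_value": p.gender_source_value,
        })

    def insert_observation_period(self, p: ObservationPeriodRow,
                                  type_concept_id: int = 0) -> None:
        self.tables["observation_period"].append({
            "observation_period_id": self._take_id("observation_period"),
            "person_id": p.person_id,
            "observation_period_start_date": p.period_start,
            "observation_period_end_date": p.period_end,
            "period_type_concept_id": type_concept_id,
        })

    def insert_row(self, row: CdmRow) -> dict:
        """Route a generic event row into its target table; returns the
        concrete stored record."""
        if row.table == "death":
            rec = {
                "person_id": row.person_id,
                "death_date": row.start_date,
                "death_type_concept_id": row.type_concept_id,
                "cause_concept_id": row.event_concept_id,
                "cause_source_value": row.source_value,
                "cause_source_concept_id": row.source_concept_id,
            }
            self.tables["death"].append(rec)
            return rec
        prefix = ROUTED_TABLES.get(row.table)
        if prefix is None:
            raise KeyError(f"cannot route CdmRow to table {row.table!r}")
        rec: dict = {f"{prefix}_id": self._take_id(row.table),
                     "person_id": row.person_id,
                     f"{prefix}_concept_id": row.event_concept_id}
        if row.table == "drug_exposure":
            rec["drug_exposure_start_date"] = row.start_date
            rec["drug_exposure_end_date"] = row.end_date or row.start_date
            rec["quantity"] = row.quantity
        elif row.table == "device_exposure":
            rec["device_exposure_start_date"] = row.start_date
        elif row.table == "specimen":
            rec["specimen_date"] = row.start_date
        elif row.table == "condition_occurrence":
            rec["condition_start_date"] = row.start_date
            rec["condition_end_date"] = row.end_date
        else:
            rec[f"{prefix}_date"] = row.start_date
        rec[f"{prefix}_type_concept_id"] = row.type_concept_id
        table_cols = set(self.schema[row.table].column_names())
        if "value_as_number" in table_cols:
            rec["value_as_number"] = row.value_as_number
            rec["value_as_concept_id"] = row.value_as_concept_id
        if "unit_concept_id" in table_cols:
            rec["unit_concept_id"] = row.unit_concept_id
        rec[f"{prefix}_source_value"] = row.source_value
        if f"{prefix}_source_concept_id" in table_cols:
            rec[f"{prefix}_source_concept_id"] = row.source_concept_id
        if "visit_occurrence_id" in table_cols:
            rec["visit_occurrence_id"] = row.visit_id
        self.tables[row.table].append(rec)
        return rec

    def insert_visit(self, person_id: int, start: str, end: str,
                     type_concept_id: int = 0, visit_concept_id: int = 9201,
                     admitting_source_value: str = "",
                     discharge_to_source_value: str = "") -> int:
        vid = self._take_id("visit_occurrence")
        self.tables["visit_occurrence"].append({
            "visit_occurrence_id": vid,
            "person_id": person_id,
            "visit_concept_id": visit_concept_id,
            "visit_start_date": start,
            "visit_end_date": end,
            "visit_type_concept_id": type_concept_id,
            "admitting_source_value": admitting_source_value,
            "discharge_to_source_value": discharge_to_source_value,
        })
        return vid

    # -- access ------------------------------------------------------------
    def rows(self, table: str) -> list[dict]:
        return self.tables[table]

    def row_counts(self) -> dict[str, int]:
        return {n: len(r) for n, r in self.tables.items() if r}

    def content_hash(self) -> int:
        """Order-sensitive hash over all table contents (DQ read-only check)."""
        items = []
        for name in sorted(self.tables):
            for rec in self.tables[name]:
                items.append((name, tuple(sorted(rec.items(),
                                                 key=lambda kv: kv[0]))))
        return hash(tuple(items))

    # -- DDL / persistence -------------------------------------------------
    _SQL_TYPES = {"integer": "INTEGER", "float": "REAL",
                  "string": "TEXT", "date": "TEXT"}

    def ddl(self) -> list[str]:
        stmts = []
        for d in self.schema.values():
            cols = ", ".join(
                f"{n} {self._SQL_TYPES[t]}" + (" NOT NULL" if req and n == d.primary_key else "")
                for n, t, req in d.columns)
            stmts.append(f"CREATE TABLE {d.name} ({cols})")
        return stmts

    def to_sqlite(self, path: str | Path = ":memory:") -> sqlite3.Connection:
        conn = sqlite3.connect(str(path))
        for stmt in self.ddl():
            conn.execute(stmt)
        for name, recs in self.tables.items():
            cols = self.schema[name].column_names()
            placeholders = ", ".join("?" for _ in cols)
            for rec in recs:
                conn.execute(
                    f"INSERT INTO {name} ({', '.join(cols)}) VALUES ({placeholders})",
                    [rec.get(c) for c in cols])
        conn.commit()
        return conn

    def to_csv(self, out_dir: str | Path) -> list[Path]:
        """One RFC-4180 CSV per table, header row, UTF-8. Empty tables get a
        header-only file so the 23-file contract is visible on disk."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = []
        for name, d in self.schema.items():
            p = out / f"{name}.csv"
            cols = d.column_names()
            with open(p, "w", newline="", encoding="utf-8") as fh:
                w = csv.writer(fh, quoting=csv.QUOTE_MINIMAL)
                w.writerow(cols)
                for rec in self.tables[name]:
                    w.writerow(["" if rec.get(c) is None else rec.get(c)
                                for c in cols])
            written.append(p)
        return written

    @classmethod
    def from_csv(cls, in_dir: str | Path) -> "CdmStore":
        """Rebuild a store from a per-table CSV export, coercing column
        values back to their logical types."""
        store = cls()
        in_dir = Path(in_dir)
        for name, d in store.schema.items():
            p = in_dir / f"{name}.csv"
            if not p.exists():
                continue
            types = {c: t for c, t, _ in d.columns}
            with open(p, newline="", encoding="utf-8") as fh:
                for rec in csv.DictReader(fh):
                    row = {}
                    for c, v in rec.items():
                        if v == "" or v is None:
                            # numeric blanks are nulls; string columns are
                            # never null in the store, only empty
                            row[c] = "" if types.get(c) == "string" else None
                        elif types.get(c) == "integer":
                            row[c] = int(float(v))
                        elif types.get(c) == "float":
                            row[c] = float(v)
                        else:
                            row[c] = v
                    store.tables[name].append(row)
        return store

    @classmethod
    def from_sqlite(cls, conn: sqlite3.Connection) -> "CdmStore":
        store = cls()
        for name, d in store.schema.items():
            cols = d.column_names()
            cur = conn.execute(f"SELECT {', '.join(cols)} FROM {name}")
            for r in cur.fetchall():
                store.tables[name].append(dict(zip(cols, r)))
        return store
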