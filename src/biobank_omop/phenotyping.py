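"""Codelist-driven cohort ascertainment over CDM tables.

A phenotype definition couples standard concept sets (evaluated against
the transformed CDM) with per-vocabulary source code lists (evaluated
against source values), optionally restricted to particular source
streams. COVID-19 status is ascertained by union over four evidence
streams — positive SARS-CoV-2 test measurements, hospital diagnoses,
primary-care codes (including mapped vendor-proprietary ones) and cause
of death — keeping the earliest evidence date. A negative test never
overrides case status.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import yaml

from .cdm import CdmStore
from .config import TYPE_CONCEPTS

__all__ = [
    "PhenotypeDefinition",
    "CohortMembership",
    "load_phenotype_definition",
    "ascertain_covid_status",
    "apply_codelist_phenotype",
    "compare_cohorts",
    "format_concordance_report",
]

#: evidence streams → (CDM tables scanned, provenance type concepts)
_SOURCE_STREAMS = {
    "covid_tests": (("measurement",), (TYPE_CONCEPTS["covid_test"],)),
    "hospital": (("condition_occurrence", "observation", "measurement",
                  "procedure_occurrence"),
                 (TYPE_CONCEPTS["hospital"], TYPE_CONCEPTS["hospital_primary"],
                  TYPE_CONCEPTS["hospital_secondary"])),
    "primary_care": (("condition_occurrence", "observation", "measurement",
                      "procedure_occurrence"),
                     (TYPE_CONCEPTS["gp_clinical"],)),
    "death": (("death",), (TYPE_CONCEPTS["death"],)),
    "baseline": (("condition_occurrence", "observation", "measurement"),
                 (TYPE_CONCEPTS["baseline"],)),
}


@dataclass(frozen=True)
class PhenotypeDefinition:
    name: str
    concept_sets: frozenset = frozenset()           # standard concept ids
    codelists: tuple = ()                           # ((vocabulary, frozenset(codes)), ...)
    sources: tuple = tuple(_SOURCE_STREAMS)

    def __post_init__(self):
        if not self.concept_sets and not any(c for _, c in self.codelists):
            raise ValueError(
                f"phenotype {self.name!r} has no concepts and no codes")

    def all_codes(self) -> frozenset:
        out = set()
        for _, codes in self.codelists:
            out |= set(codes)
        return frozenset(out)


@dataclass
class CohortMembership:
    person_id: int
    first_event_date: str
    evidence: list = field(default_factory=list)  # (stream, code_or_concept, date)


def load_phenotype_definition(path: str | Path) -> PhenotypeDefinition:
    """YAML layout: name, concept_ids list, codelists {vocab: [codes]},
    sources list (optional)."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return PhenotypeDefinition(
        name=data["name"],
        concept_sets=frozenset(int(c) for c in data.get("concept_ids", [])),
        codelists=tuple(sorted(
            (v, frozenset(str(c) for c in codes))
            for v, codes in (data.get("codelists") or {}).items())),
        sources=tuple(data.get("sources") or _SOURCE_STREAMS),
    )


def _row_concept(table: str, rec: dict) -> int:
    for key in ("measurement_concept_id", "condition_concept_id",
                "observation_concept_id", "procedure_concept_id",
                "cause_concept_id"):
        if key in rec:
            return rec[key] or 0
    return 0


def _row_date(table: str, rec: dict) -> str:
    for key in ("measurement_date", "condition_start_date",
                "observation_date", "procedure_date", "death_date"):
        if key in rec:
            return rec[key]
    return ""


def _row_source_value(rec: dict) -> str:
    for key in ("measurement_source_value", "condition_source_value",
                "observation_source_value", "procedure_source_value",
                "cause_source_value"):
        if key in rec:
            return str(rec[key])
    return ""


def _row_type(rec: dict) -> int:
    for key in rec:
        if key.endswith("type_concept_id"):
            return rec[key] or 0
    return 0


def _scan(cdm: CdmStore, definition: PhenotypeDefinition,
          positive_value_concepts: frozenset = frozenset(),
          ) -> dict[int, CohortMembership]:
    """Shared evidence scan: a row is evidence when its standard concept is
    in the definition's concept sets or its source value is in a codelist,
    restricted to the definition's source streams. When
    ``positive_value_concepts`` is non-empty, measurement rows must
    additionally carry one of them as value (test-positivity)."""
    members: dict[int, CohortMembership] = {}
    codes = definition.all_codes()
    for stream in definition.sources:
        tables, type_ids = _SOURCE_STREAMS[stream]
        for table in tables:
            for rec in cdm.rows(table):
                if _row_type(rec) not in type_ids:
                    continue
                concept = _row_concept(table, rec)
                sv = _row_source_value(rec)
                hit = (concept in definition.concept_sets and concept != 0) \
                    or (sv in codes)
                if not hit:
                    continue
                if positive_value_concepts and table == "measurement":
                    if (rec.get("value_as_concept_id") or 0) \
                            not in positive_value_concepts:
                        continue
                pid = rec["person_id"]
                d = _row_date(table, rec)
                m = members.get(pid)
                if m is None:
                    members[pid] = CohortMembership(pid, d,
                                                    [(stream, concept or sv, d)])
                else:
                    m.evidence.append((stream, concept or sv, d))
                    if d and (not m.first_event_date or d < m.first_event_date):
                        m.first_event_date = d
    return members


def ascertain_covid_status(cdm: CdmStore, definition: PhenotypeDefinition,
                           positive_value_concepts: Iterable[int],
                           ) -> dict[int, CohortMembership]:
    """COVID-19 cases by union over the definition's evidence streams.

    Test measurements count only when their value concept is in
    ``positive_value_concepts``; all other streams count on the event
    concept / source code alone. Earliest evidence date is retained.
    """
    return _scan(cdm, definition,
                 frozenset(int(c) for c in positive_value_concepts))


def apply_codelist_phenotype(cdm: CdmStore, definition: PhenotypeDefinition,
                             ) -> dict[int, CohortMembership]:
    """Comorbidity cohort: membership on any matching standard concept or
    source code in the definition's streams."""
    return _scan(cdm, definition)


def compare_cohorts(source_cohort: Iterable[int], cdm_cohort: Iterable[int],
                    continuous_metrics: dict[str, tuple] | None = None,
                    universe_size: int | None = None,
                    missing_codes: dict[int, str] | None = None) -> dict:
    """Concordance between source-defined and CDM-defined cohorts.

    ``continuous_metrics`` maps metric name → (source values, cdm values);
    medians, IQRs and SDs are reported side by side.
    ``missing_codes`` optionally names the unmapped source code that
    explains a source-only person.
    """
    src, cdm_set = set(source_cohort), set(cdm_cohort)
    both = src & cdm_set
    source_only = sorted(src - cdm_set)
    cdm_only = sorted(cdm_set - src)
    n_universe = universe_size or len(src | cdm_set) or 1
    report = {
        "n_source": len(src),
        "n_cdm": len(cdm_set),
        "n_both": len(both),
        "source_only": len(source_only),
        "cdm_only": len(cdm_only),
        "source_only_persons": source_only,
        "cdm_only_persons": cdm_only,
        "pct_source": round(100.0 * len(src) / n_universe, 2),
        "pct_cdm": round(100.0 * len(cdm_set) / n_universe, 2),
        "metrics": {},
    }
    if missing_codes:
        report["source_only_codes"] = {
            p: missing_codes[p] for p in source_only if p in missing_codes}
    for name, (sv, cv) in (continuous_metrics or {}).items():
        def _stats(vals):
            arr = np.asarray(list(vals), dtype=float)
            if arr.size == 0:
                return {"median": None, "iqr": None, "sd": None}
            q1, q3 = np.percentile(arr, [25, 75])
            return {"median": round(float(np.median(arr)), 3),
                    "iqr": round(float(q3 - q1), 3),
                    "sd": round(float(np.std(arr, ddof=1)), 3)
                    if arr.size > 1 else 0.0}
        report["metrics"][name] = {"source": _stats(sv), "cdm": _stats(cv)}
    return report


def format_concordance_report(report: dict) -> str:
    """Human-readable table for a :func:`compare_cohorts` report."""
    lines = [
        "cohort concordance",
        "------------------",
        f"source cohort : {report['n_source']} ({report['pct_source']}%)",
        f"cdm cohort    : {report['n_cdm']} ({report['pct_cdm']}%)",
        f"in both       : {report['n_both']}",
        f"source only   : {report['source_only']}",
        f"cdm only      : {report['cdm_only']}",
    ]
    for p, code in (report.get("source_only_codes") or {}).items():
        lines.append(f"  source-only person {p}: unmapped code {code}")
    for name, m in report["metrics"].items():
        s, c = m["source"], m["cdm"]
        lines.append(f"{name}: source median {s['median']} (IQR {s['iqr']}, "
                     f"SD {s['sd']}) vs cdm median {c['median']} "
                     f"(IQR {c['iqr']}, SD {c['sd']})")
    return "\n".join(lines)
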