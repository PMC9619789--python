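"""Mapping-coverage reporting, the 80% review worklist, and DQ checks.

Coverage is reported at two levels per source vocabulary: term coverage
(distinct source codes that resolved to a nonzero standard concept) and
event coverage (individual records emitted with a nonzero standard
concept). The prioritization worklist returns the shortest frequency-
ordered prefix of terms covering a target share of all events — the rule
used to focus manual mapping effort on the codes that account for at
least 80% of records.

The data-quality engine is a compact registry of checks in three
families: completeness (share of concept-0 records per table, strict
threshold 20%), conformance (a nonzero standard concept's domain must
match its table; unit columns must hold Unit-domain concepts; severity
error), and plausibility (gender-specific concepts on persons of the
recorded other gender; severity warning — such rows are source-data
artifacts and are reported, not removed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .cdm import CdmStore, ROUTED_TABLES
from .runlog import EtlLog
from .vocabulary import VocabularyStore

__all__ = [
    "CoverageStats",
    "DqResult",
    "DqReport",
    "coverage_report",
    "format_coverage_markdown",
    "coverage_to_csv",
    "prioritize_terms",
    "check_completeness",
    "check_conformance",
    "check_gender_plausibility",
    "run_dq",
]


# --------------------------------------------------------------------------
# Coverage
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CoverageStats:
    vocabulary: str
    used_terms: int
    mapped_terms: int
    events: int
    mapped_events: int

    @property
    def term_pct(self) -> float:
        return round(100.0 * self.mapped_terms / self.used_terms, 2) \
            if self.used_terms else 0.0

    @property
    def event_pct(self) -> float:
        return round(100.0 * self.mapped_events / self.events, 2) \
            if self.events else 0.0


def coverage_report(etl_log: EtlLog) -> list[CoverageStats]:
    """One row per source vocabulary seen during the run."""
    out = []
    for vocab in sorted(etl_log.coverage):
        cov = etl_log.coverage[vocab]
        out.append(CoverageStats(vocab, len(cov.used_terms),
                                 len(cov.mapped_terms),
                                 cov.events, cov.mapped_events))
    return out


_COV_HEADER = ("Source vocab", "Used source terms #", "Mapped used terms # (%)",
               "Events #", "Mapped event # (%)")


def format_coverage_markdown(stats: Sequence[CoverageStats]) -> str:
    lines = ["| " + " | ".join(_COV_HEADER) + " |",
             "|" + "|".join("---" for _ in _COV_HEADER) + "|"]
    for s in stats:
        lines.append(
            f"| {s.vocabulary} | {s.used_terms} "
            f"| {s.mapped_terms} ({s.term_pct}%) "
            f"| {s.events} | {s.mapped_events} ({s.event_pct}%) |")
    return "\n".join(lines)


def coverage_to_csv(stats: Sequence[CoverageStats], path: str | Path) -> None:
    import csv
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(("vocabulary", "used_terms", "mapped_terms",
                    "mapped_terms_pct", "events", "mapped_events",
                    "mapped_events_pct"))
        for s in stats:
            w.writerow((s.vocabulary, s.used_terms, s.mapped_terms,
                        s.term_pct, s.events, s.mapped_events, s.event_pct))


def prioritize_terms(term_frequencies: dict[str, int] | Sequence[tuple[str, int]],
                     fraction: float = 0.80) -> list[str]:
    """Shortest descending-frequency prefix whose cumulative event share
    reaches ``fraction``; ties break lexicographically by code. Terms with
    zero frequency never enter the worklist."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    items = (term_frequencies.items()
             if isinstance(term_frequencies, dict) else term_frequencies)
    ordered = sorted(((code, int(n)) for code, n in items if int(n) > 0),
                     key=lambda kv: (-kv[1], kv[0]))
    total = sum(n for _, n in ordered)
    if total == 0:
        return []
    worklist, cum = [], 0
    for code, n in ordered:
        worklist.append(code)
        cum += n
        if cum >= fraction * total:
            break
    return worklist


# --------------------------------------------------------------------------
# Data-quality checks
# --------------------------------------------------------------------------

@dataclass
class DqResult:
    check_id: str
    family: str          # completeness | conformance | plausibility
    table: str
    failed_fraction: float
    threshold: float
    severity: str = "error"
    n_rows: int = 0
    n_failed: int = 0
    failing_examples: list = field(default_factory=list)

    @property
    def status(self) -> str:
        return "fail" if self.failed_fraction > self.threshold else "pass"


@dataclass
class DqReport:
    results: list[DqResult]

    @property
    def n_pass(self) -> int:
        return sum(1 for r in self.results if r.status == "pass")

    @property
    def n_fail(self) -> int:
        return sum(1 for r in self.results if r.status == "fail")

    def has_error_failure(self) -> bool:
        return any(r.status == "fail" and r.severity == "error"
                   for r in self.results)

    def to_json(self) -> str:
        payload = {"summary": {"pass": self.n_pass, "fail": self.n_fail},
                   "checks": [dict(asdict(r), status=r.status)
                              for r in self.results]}
        return json.dumps(payload, indent=2)

    def to_markdown(self) -> str:
        lines = ["| check | family | table | failed fraction | threshold "
                 "| severity | status |",
                 "|---|---|---|---|---|---|---|"]
        for r in self.results:
            lines.append(f"| {r.check_id} | {r.family} | {r.table} "
                         f"| {r.failed_fraction:.4f} | {r.threshold} "
                         f"| {r.severity} | {r.status} |")
        lines.append(f"\n{self.n_pass} passed, {self.n_fail} failed")
        return "\n".join(lines)


def _concept_column(table: str) -> Optional[str]:
    prefix = ROUTED_TABLES.get(table)
    return f"{prefix}_concept_id" if prefix else None


def check_completeness(rows: Sequence[dict], table: str,
                       threshold: float = 0.20,
                       concept_column: str | None = None) -> DqResult:
    """Share of records with a standard concept of 0; fails when the share
    strictly exceeds the threshold (an exactly-at-threshold table passes)."""
    col = concept_column or _concept_column(table) or "concept_id"
    n = len(rows)
    failed = sum(1 for r in rows if (r.get(col) or 0) == 0)
    # expected consequence of residual unmapped codes (the observation
    # table is the concept-0 sink), so reported as a warning, not fatal
    return DqResult(check_id=f"completeness_{table}", family="completeness",
                    table=table,
                    failed_fraction=(failed / n) if n else 0.0,
                    threshold=threshold, severity="warning",
                    n_rows=n, n_failed=failed)


#: domains a nonzero event concept may carry per routed table; observation
#: is the default sink and accepts anything
_TABLE_DOMAINS = {
    "measurement": {"Measurement"},
    "condition_occurrence": {"Condition"},
    "procedure_occurrence": {"Procedure"},
    "drug_exposure": {"Drug"},
    "device_exposure": {"Device"},
}


def check_conformance(rows: Sequence[dict], table: str,
                      store: VocabularyStore) -> DqResult:
    """Nonzero standard concepts must conform with the table's domain, and
    nonzero unit concepts must be Unit-domain; any violation fails."""
    col = _concept_column(table)
    expected = _TABLE_DOMAINS.get(table)
    n = len(rows)
    failed = 0
    examples = []
    for i, r in enumerate(rows):
        bad = False
        cid = (r.get(col) or 0) if col else 0
        if expected and cid:
            c = store.concept_by_id(cid)
            if c is None or c.domain not in expected:
                bad = True
        ucid = r.get("unit_concept_id") or 0
        if ucid:
            u = store.concept_by_id(ucid)
            if u is None or u.domain != "Unit":
                bad = True
        if bad:
            failed += 1
            if len(examples) < 10:
                examples.append({"row_index": i, "concept_id": cid,
                                 "unit_concept_id": ucid})
    return DqResult(check_id=f"conformance_{table}", family="conformance",
                    table=table,
                    failed_fraction=(failed / n) if n else 0.0,
                    threshold=0.0, severity="error",
                    n_rows=n, n_failed=failed, failing_examples=examples)


def check_gender_plausibility(rows: Sequence[dict], table: str,
                              persons: Sequence[dict],
                              gender_specific_concepts: dict[int, int],
                              ) -> DqResult:
    """Flag rows whose concept requires a gender differing from the
    person's recorded gender; persons of unknown gender are never flagged.
    Reported as a warning — such rows come from the source data and are
    kept."""
    gender_of = {p["person_id"]: p.get("gender_concept_id") or 0
                 for p in persons}
    col = _concept_column(table)
    n = len(rows)
    failed = 0
    examples = []
    for i, r in enumerate(rows):
        cid = (r.get(col) or 0) if col else 0
        required = gender_specific_concepts.get(cid)
        if required is None:
            continue
        actual = gender_of.get(r["person_id"], 0)
        if actual and actual != required:
            failed += 1
            if len(examples) < 10:
                examples.append({"row_index": i, "concept_id": cid,
                                 "person_id": r["person_id"]})
    return DqResult(check_id=f"plausibility_gender_{table}",
                    family="plausibility", table=table,
                    failed_fraction=(failed / n) if n else 0.0,
                    threshold=0.0, severity="warning",
                    n_rows=n, n_failed=failed, failing_examples=examples)


def run_dq(cdm: CdmStore, store: VocabularyStore,
           completeness_threshold: float = 0.20,
           gender_specific_concepts: dict[int, int] | None = None,
           ) -> DqReport:
    """Execute the registered check suite over all populated event tables.

    Read-only: the store's contents are untouched. One completeness and
    one conformance check per routed table, plus gender plausibility on
    the condition and observation tables.
    """
    results: list[DqResult] = []
    event_tables = [t for t in ROUTED_TABLES if t != "specimen"]
    for table in event_tables:
        rows = cdm.rows(table)
        results.append(check_completeness(rows, table,
                                          completeness_threshold))
        results.append(check_conformance(rows, table, store))
    persons = cdm.rows("person")
    for table in ("condition_occurrence", "observation"):
        results.append(check_gender_plausibility(
            cdm.rows(table), table, persons,
            gender_specific_concepts or {}))
    return DqReport(results)
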