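"""Structured run accounting for the ETL stages.

Every source stream must satisfy the conservation identity

    input rows = emitted rows + excluded rows + quarantined rows
                 + rows of rejected participants

and every (vocabulary, code) lookup is tallied so term- and event-level
mapping coverage can be reported after the run. Log lines carry
(stage, reason_code, count) so the identities are machine-checkable from
the log alone.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field

log = logging.getLogger(__name__)

__all__ = ["StreamCounts", "VocabCoverage", "EtlLog"]


@dataclass
class StreamCounts:
    input: int = 0
    emitted: int = 0
    excluded: Counter = field(default_factory=Counter)   # reason -> count
    quarantined: Counter = field(default_factory=Counter)
    rejected_person: int = 0

    @property
    def excluded_total(self) -> int:
        return sum(self.excluded.values())

    @property
    def quarantined_total(self) -> int:
        return sum(self.quarantined.values())

    def conserved(self) -> bool:
        return self.input == (self.emitted + self.excluded_total
                              + self.quarantined_total + self.rejected_person)


@dataclass
class VocabCoverage:
    used_terms: set = field(default_factory=set)
    mapped_terms: set = field(default_factory=set)
    events: int = 0
    mapped_events: int = 0


class EtlLog:
    def __init__(self):
        self.streams: dict[str, StreamCounts] = defaultdict(StreamCounts)
        self.coverage: dict[str, VocabCoverage] = defaultdict(VocabCoverage)
        self.exclusion_records: list[tuple[str, str, str]] = []  # stream, reason, detail

    # -- conservation ------------------------------------------------------
    def count_input(self, stream: str, n: int = 1) -> None:
        self.streams[stream].input += n

    def count_emitted(self, stream: str, n: int = 1) -> None:
        self.streams[stream].emitted += n

    def count_excluded(self, stream: str, reason: str, detail: str = "") -> None:
        self.streams[stream].excluded[reason] += 1
        self.exclusion_records.append((stream, reason, detail))
        log.info("stage=%s reason=%s detail=%s count=1", stream, reason, detail)

    def count_quarantined(self, stream: str, reason: str, detail: str = "") -> None:
        self.streams[stream].quarantined[reason] += 1
        self.exclusion_records.append((stream, reason, detail))
        log.info("stage=%s reason=quarantine:%s detail=%s count=1",
                 stream, reason, detail)

    def count_rejected_person(self, stream: str, n: int = 1) -> None:
        self.streams[stream].rejected_person += n

    # -- coverage ----------------------------------------------------------
    def record_mapping(self, vocabulary: str, code: str, mapped: bool) -> None:
        cov = self.coverage[vocabulary]
        cov.used_terms.add(code)
        cov.events += 1
        if mapped:
            cov.mapped_terms.add(code)
            cov.mapped_events += 1

    def conservation_ok(self) -> dict[str, bool]:
        return {s: c.conserved() for s, c in self.streams.items()}

    def summary(self) -> dict:
        return {
            s: {"input": c.input, "emitted": c.emitted,
                "excluded": dict(c.excluded),
                "quarantined": dict(c.quarantined),
                "rejected_person_rows": c.rejected_person,
                "conserved": c.conserved()}
            for s, c in sorted(self.streams.items())
        }
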