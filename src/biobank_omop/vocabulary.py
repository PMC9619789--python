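"""Vocabulary store and source-to-standard concept resolution.

Three mapping routes exist, mirroring how UK source terminologies reach
standard OMOP concepts:

* codes whose own concept is already standard (SNOMED-CT, RxNorm, UCUM)
  resolve to themselves;
* non-standard codes (CTV3, ICD-10/9, OPCS-3/4, dm+d) resolve through
  cross-map tables, which may contain 1:many entries;
* bespoke codes (questionnaire field/value pairs, vendor-proprietary EMIS
  and TPP codes, episode attributes) resolve through manually curated
  custom mapping tables in the Usagi export layout. Custom entries take
  precedence over cross-maps for the same code.

1:many candidates are narrowed by three filters applied in order: keep
preferred-and-active entries, keep standard targets, then prefer the target
domain in the order Measurement > Condition > Observation > Procedure.
Residual ties are broken deterministically (SNOMED target first, then
lowest concept id).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

log = logging.getLogger(__name__)

__all__ = [
    "Concept",
    "MappingCandidate",
    "CustomMapping",
    "VocabularyStore",
    "VocabularyLoadError",
    "load_vocabulary",
    "resolve_to_standard",
    "select_single_target",
    "domain_to_table",
    "DOMAIN_PRIORITY",
]

#: filter-rule (3) priority; anything absent ranks behind Procedure
DOMAIN_PRIORITY = {"Measurement": 0, "Condition": 1,
                   "Observation": 2, "Procedure": 3}

#: ICD-style vocabularies where E11.9 and E119 are the same code
_DOTTED_VOCABS = {"ICD10", "ICD9", "OPCS3", "OPCS4"}


@dataclass(frozen=True)
class Concept:
    concept_id: int
    code: str
    vocabulary: str
    domain: str
    standard: bool
    valid: bool = True


@dataclass(frozen=True)
class MappingCandidate:
    source_code: str
    source_vocabulary: str
    target: Concept
    preferred: bool = True
    active: bool = True


@dataclass(frozen=True)
class CustomMapping:
    """One curated field/value-level entry (Usagi export row)."""
    source_code: str
    source_vocabulary: str
    event_concept_id: int
    value_concept_id: int = 0
    unit_concept_id: int = 0


class VocabularyLoadError(ValueError):
    pass


def _norm_code(vocabulary: str, code: str) -> str:
    code = str(code).strip()
    if vocabulary in _DOTTED_VOCABS:
        code = code.replace(".", "")
    return code


@dataclass
class VocabularyStore:
    concepts: dict[tuple[str, str], Concept] = field(default_factory=dict)
    by_id: dict[int, Concept] = field(default_factory=dict)
    maps: dict[tuple[str, str], list[MappingCandidate]] = field(default_factory=dict)
    custom_maps: dict[tuple[str, str], CustomMapping] = field(default_factory=dict)

    def add_concept(self, c: Concept) -> None:
        key = (c.vocabulary, _norm_code(c.vocabulary, c.code))
        if key in self.concepts:
            raise VocabularyLoadError(f"duplicate concept key {key}")
        self.concepts[key] = c
        # first writer wins so source (non-standard) duplicates of an id
        # never shadow the standard concept
        self.by_id.setdefault(c.concept_id, c)

    def get_concept(self, vocabulary: str, code: str) -> Optional[Concept]:
        return self.concepts.get((vocabulary, _norm_code(vocabulary, code)))

    def concept_by_id(self, concept_id: int) -> Optional[Concept]:
        return self.by_id.get(concept_id)

    def add_map(self, cand: MappingCandidate) -> None:
        key = (cand.source_vocabulary,
               _norm_code(cand.source_vocabulary, cand.source_code))
        self.maps.setdefault(key, []).append(cand)

    def add_custom(self, m: CustomMapping) -> None:
        key = (m.source_vocabulary,
               _norm_code(m.source_vocabulary, m.source_code))
        self.custom_maps[key] = m

    def get_custom(self, vocabulary: str, code: str) -> Optional[CustomMapping]:
        return self.custom_maps.get((vocabulary, _norm_code(vocabulary, code)))


# --------------------------------------------------------------------------
# File loading
# --------------------------------------------------------------------------

def _open_rows(path: str | Path):
    """Yield dict rows from a comma- or tab-delimited file (auto-detected)."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        head = fh.readline()
        delim = "\t" if head.count("\t") >= head.count(",") and "\t" in head else ","
        fh.seek(0)
        reader = csv.DictReader(fh, delimiter=delim)
        for i, row in enumerate(reader, start=2):
            yield i, row


def _require(row: dict, cols: Sequence[str], path, lineno) -> None:
    missing = [c for c in cols if row.get(c) in (None, "")]
    if missing:
        raise VocabularyLoadError(
            f"{path}:{lineno}: missing value(s) for {missing}")


def load_vocabulary(concept_file: str | Path,
                    map_files: Iterable[str | Path] = (),
                    custom_map_files: Iterable[str | Path] = ()) -> VocabularyStore:
    """Build a :class:`VocabularyStore` from fixture files.

    ``concept_file`` follows the Athena CONCEPT dialect (``concept_id``,
    ``concept_code``, ``vocabulary_id``, ``domain_id``, ``standard_concept``,
    ``invalid_reason``; comma or tab delimited). ``map_files`` carry
    cross-map rows (``source_code``, ``source_vocabulary``,
    ``target_concept_id``, ``preferred`` Y/N, ``active`` Y/N). Custom map
    files use the Usagi export layout; only rows with mappingStatus
    APPROVED are loaded.
    """
    store = VocabularyStore()
    n = 0
    for lineno, row in _open_rows(concept_file):
        _require(row, ("concept_id", "concept_code", "vocabulary_id",
                       "domain_id"), concept_file, lineno)
        try:
            cid = int(row["concept_id"])
        except ValueError as e:
            raise VocabularyLoadError(
                f"{concept_file}:{lineno}: bad concept_id {row['concept_id']!r}") from e
        store.add_concept(Concept(
            concept_id=cid,
            code=str(row["concept_code"]).strip(),
            vocabulary=row["vocabulary_id"].strip(),
            domain=row["domain_id"].strip(),
            standard=(row.get("standard_concept") or "").strip().upper() == "S",
            valid=(row.get("invalid_reason") or "").strip() == "",
        ))
        n += 1
    log.info("loaded %d concepts from %s", n, concept_file)

    for mf in map_files:
        n = 0
        for lineno, row in _open_rows(mf):
            _require(row, ("source_code", "source_vocabulary",
                           "target_concept_id"), mf, lineno)
            tid = int(row["target_concept_id"])
            target = store.concept_by_id(tid)
            if target is None:
                raise VocabularyLoadError(
                    f"{mf}:{lineno}: target concept {tid} not in concept file")
            store.add_map(MappingCandidate(
                source_code=str(row["source_code"]).strip(),
                source_vocabulary=row["source_vocabulary"].strip(),
                target=target,
                preferred=(row.get("preferred") or "Y").strip().upper() == "Y",
                active=(row.get("active") or "Y").strip().upper() == "Y",
            ))
            n += 1
        log.info("loaded %d cross-map candidates from %s", n, mf)

    for cf in custom_map_files:
        n = 0
        for lineno, row in _open_rows(cf):
            status = (row.get("mappingStatus") or "").strip().upper()
            if status != "APPROVED":
                continue
            _require(row, ("sourceCode", "targetConceptId"), cf, lineno)
            store.add_custom(CustomMapping(
                source_code=str(row["sourceCode"]).strip(),
                source_vocabulary=(row.get("sourceVocabularyId") or "UKB").strip(),
                event_concept_id=int(row["targetConceptId"]),
                value_concept_id=int(row.get("valueConceptId") or 0),
                unit_concept_id=int(row.get("unitConceptId") or 0),
            ))
            n += 1
        log.info("loaded %d approved custom mappings from %s", n, cf)
    return store


# --------------------------------------------------------------------------
# Resolution
# --------------------------------------------------------------------------

def resolve_to_standard(store: VocabularyStore, code: str,
                        vocabulary: str) -> list[MappingCandidate]:
    """All standard-concept candidates for a source code; [] = unmapped.

    Custom (manually curated) entries take precedence over cross-maps.
    A code whose own concept is standard resolves to a single
    self-candidate.
    """
    code = str(code).strip()
    custom = store.get_custom(vocabulary, code)
    if custom is not None:
        target = store.concept_by_id(custom.event_concept_id)
        if target is not None:
            return [MappingCandidate(code, vocabulary, target)]
    own = store.get_concept(vocabulary, code)
    if own is not None and own.standard:
        return [MappingCandidate(code, vocabulary, own)]
    return list(store.maps.get(
        (vocabulary, _norm_code(vocabulary, code)), []))


def select_single_target(candidates: Sequence[MappingCandidate],
                         strict_filter: bool = False) -> Optional[Concept]:
    """Narrow 1:many mapping candidates to at most one standard concept.

    Filters, in order: (1) preferred and active entries only; (2) standard
    targets only; (3) target domain priority Measurement > Condition >
    Observation > Procedure > anything else. With ``strict_filter`` off
    (default), an empty result of filter (1) falls back to the unfiltered
    set so manually rescuable codes are not silently dropped; with it on,
    such codes resolve to nothing. Residual ties break deterministically:
    SNOMED-vocabulary target first, then lowest concept id.
    """
    cands = list(candidates)
    if not cands:
        return None
    kept = [c for c in cands if c.preferred and c.active]
    if not kept:
        if strict_filter:
            return None
        kept = cands
    kept = [c for c in kept if c.target.standard]
    if not kept:
        return None
    best_rank = min(DOMAIN_PRIORITY.get(c.target.domain, 4) for c in kept)
    kept = [c for c in kept
            if DOMAIN_PRIORITY.get(c.target.domain, 4) == best_rank]
    if len(kept) > 1:
        log.debug("tie-break applied for source code %r (%d survivors)",
                  kept[0].source_code, len(kept))
    return min(kept, key=lambda c: (c.target.vocabulary != "SNOMED",
                                    c.target.concept_id)).target


_DOMAIN_TABLE = {
    "Measurement": "measurement",
    "Condition": "condition_occurrence",
    "Procedure": "procedure_occurrence",
    "Drug": "drug_exposure",
    "Device": "device_exposure",
}


def domain_to_table(domain: str | None) -> str:
    """CDM table for a concept domain; observation is the default sink."""
    return _DOMAIN_TABLE.get(domain or "", "observation")
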