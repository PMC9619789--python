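# biobank-omop

An ETL toolkit that converts a biobank-style research study — a wide
questionnaire baseline extract (one row per participant, columns
`<field>-<instance>.<array>`) plus linked electronic health records coded
in multiple UK clinical terminologies — into the OMOP Common Data Model
v5.3, the person-centric relational schema used for federated
observational research (including COVID-19 studies run across many data
partners).

It is aimed at data engineers and health-informatics researchers who need
to harmonize questionnaire + EHR-linkage studies into OMOP and to *prove*
the harmonization is sound: every stage is paired with mapping-coverage
reporting, conservation accounting, data-quality checks and a
synthetic-data generator with planted ground truth, so the pipeline is
fully testable without access to restricted participant data.

## What it implements

- **CDM v5.3 schema** — all 23 tables in 4 groups (15 clinical, 3 derived,
  3 health-system, 2 health-economics), with DDL emission to SQLite and
  CSV-per-table export.
- **Vocabulary resolution** — source codes resolve to at most one standard
  concept: natively standard codes (SNOMED-CT, RxNorm, UCUM) map to
  themselves; CTV3/ICD-10/ICD-9/OPCS-3/OPCS-4/dm+d resolve through
  cross-map tables; bespoke questionnaire field/value pairs and
  vendor-proprietary EMIS/TPP codes resolve through curated custom maps in
  the Usagi export layout. 1:many cross-map entries are narrowed by three
  ordered filters — keep *Preferred* ∧ *Active* entries, keep standard
  targets, prefer the domain in the order Measurement > Condition >
  Observation > Procedure — with a deterministic tie-break (SNOMED target,
  then lowest concept id).
- **Baseline ETL** — wide→long traversal (one record per non-empty cell,
  dated at the matching visit), field classification
  (numeric/boolean/categorical), and the two-step event + value/unit
  mapping. Unmapped records fall back to an observation row with concept
  id 0 and the field id as source value; nothing is silently dropped.
- **EHR ETL** — GP clinical events, dm+d prescriptions (→ drug_exposure
  via RxNorm), hospital episodes (visit + routed diagnosis/procedure/
  attribute rows), death registry (underlying + secondary causes) and
  SARS-CoV-2 test results (common measurement concept, positive/negative
  value concepts, linked specimen). Records with bespoke special values
  (−1, −2, −3, −99) are excluded and logged before mapping. Observation
  periods (min–max span per person) and drug eras (30-day gap merge) are
  derived.
- **Phenotyping** — codelist/concept-set cohort ascertainment, the
  multi-source COVID-19 status algorithm (union over positive tests,
  hospital diagnoses, primary-care codes incl. mapped proprietary ones,
  and cause of death), and source-vs-CDM concordance reports.
- **Quality & coverage** — term- and event-level mapping coverage per
  vocabulary, the 80% term-prioritization worklist, and a compact
  data-quality engine with completeness (concept-0 share vs a strict 20%
  threshold), conformance (concept domain vs table; unit columns must be
  Unit-domain) and gender-plausibility checks.
- **Synthetic data** — a generator that emulates the source structure with
  exact largest-remainder realization of every planted rate, and a
  ground-truth JSON that the test suite checks the whole pipeline against.

## Worked example

Generate a 200-participant synthetic study and run the full pipeline:

```
$ biobank-omop generate --n 200 --seed 1 --out-dir demo/bundle
bundle written to demo/bundle: 200 participants, 10 planted COVID-19 cases

$ biobank-omop etl --bundle demo/bundle --out-dir demo/run
ETL finished; conservation_ok=True, dq 13 passed / 1 failed
```

`conservation_ok=True` says every stream satisfied
`input = emitted + excluded + quarantined + rejected-participant rows`.
The single failing check is the completeness warning on the observation
table — expected, because observation is the sink for every concept-0
fallback record. `demo/run/coverage.md` then shows term- and event-level
coverage per vocabulary, e.g.:

```
| Source vocab | Used source terms # | Mapped used terms # (%) | Events # | Mapped event # (%) |
| CTV3         | 41 | 37 (90.24%) | 566  | 509 (89.93%)  |
| DMD          | 25 | 24 (96.0%)  | 800  | 792 (99.0%)   |
| SNOMED       | 69 | 67 (97.1%)  | 574  | 557 (97.04%)  |
| TPP          | 6  | 1 (16.67%)  | 32   | 2 (6.25%)     |
| UKB          | 33 | 30 (90.91%) | 2016 | 1693 (83.98%) |
```

established terminologies map near-completely, vendor-proprietary codes
barely at all (only the curated COVID-19 subset), mirroring real UK
primary-care extracts. `demo/run/phenotypes/covid19.json` reports the
ascertained cohort (here all 10 planted cases recovered, `source_only=0`,
`cdm_only=0`).

The canonical single-record example: baseline field 20002 (*self-reported
non-cancer illness*) with value 1065 (*hypertension*) becomes an
observation row with `observation_concept_id` **4214956** (*History of
clinical finding in subject*) and `value_as_concept_id` **316866**
(*Hypertensive disorder*) — the two-step field/value mapping through the
shipped custom table. An unmapped field (say 99999) becomes an observation
row with concept id 0 and `"99999"` as the source value.

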