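# Methods

## The harmonization problem

Biobank-style studies couple a cross-sectional questionnaire baseline
(bespoke numeric field/value coding, wide layout, explicit missingness
codes) with longitudinal EHR linkages that use whatever terminology each
provider system records in: SNOMED-CT and vendor-proprietary codes in
EMIS practices, CTV3 (Read v3) and proprietary codes in TPP practices,
dm+d for prescriptions, ICD-10/ICD-9 for hospital diagnoses and death
causes, OPCS-3/OPCS-4 for procedures. Harmonizing this into OMOP CDM
v5.3 requires (a) a syntactic reshaping into person-centric event tables
and (b) a semantic mapping of every source code onto at most one standard
concept, whose domain then decides the destination table.

## Mapping resolution

Resolution is a precedence chain: curated custom-map entry (manual
curation overrides automated maps) → the code's own concept if standard →
cross-map candidates. 1:many cross-map candidates are narrowed by three
ordered filters: (1) keep entries labelled Preferred and Active; (2) keep
entries whose target concept is standard; (3) keep the best target domain
in the priority order Measurement > Condition > Observation > Procedure >
anything else.

Two situations need decisions the filter rules do not make:

* **Residual ties.** When several candidates survive all three filters,
  the original workflow resolved them by manual review. A pipeline needs
  a deterministic stand-in: we prefer a SNOMED-vocabulary target, then
  the lowest concept id. Ties are logged so a curator can revisit them.
* **Rule-(1) wipe-out.** When *no* candidate is Preferred+Active, a
  literal reading drops the code entirely. Because such codes were
  historically rescued by review, the default policy applies filters
  (2)–(3) to the unfiltered set instead; the `strict_filter` flag
  restores the literal all-or-nothing behaviour. Filter (2) has no such
  fallback — a non-standard target is never emitted.

Unmapped codes are not dropped: they land in the observation table (the
default sink) with standard concept 0 and the verbatim source code
preserved, except prescriptions, which stay in drug_exposure with concept
0 so the drug stream remains in one table. Unit resolution failures set
`unit_concept_id` 0 without failing the record. ICD/OPCS codes are looked
up dot-insensitively (E11.9 ≡ E119), since UK extracts mix both dialects.

## Baseline specifics

Numeric fields map in two steps: an event concept for the field (custom
map) and a UCUM unit concept from the field dictionary. Categorical
fields map at the (field, value) level to an event concept plus
`value_as_concept_id`. Boolean fields emit a row only when true; negative
or unanswered values emit nothing by default (`emit_negative_booleans`
reverses this), because the CDM does not conventionally store explicit
negation. Self-reported events are dated at the assessment-centre visit
of their instance — the source gives no onset date, so pre-recruitment
events are date-distorted toward the visit; a known limitation.
Multi-attribute hematology measurements split into separate rows (value →
measurement, freeze-thaw cycles → observation, device → device_exposure)
linked only by person and date: the populated CDM subset has no
fact-relationship wiring, a documented limitation.

A participant with a missing year of birth (or on the withdrawal list) is
rejected with *all* associated data in every stream; surrogate person ids
are assigned by lexicographic enumeration of the accepted source ids so
re-runs are reproducible.

## EHR specifics

Special values −1 (sensitive), −2 (rare occupation), −3 (invalid code),
−99 (missing code) are excluded before mapping and individually logged.
Hospital episodes produce one visit_occurrence plus routed rows linked by
visit id; primary vs secondary diagnoses are distinguished via the type
concept; admission method/source and discharge destination are mapped as
ordinary custom-map vocabularies. GP events get no visits (the source
describes none). Death records keep the earliest date on conflict;
secondary causes route by concept domain like any other code.

Observation periods use a min/max policy — one period per person from the
earliest known event (including the baseline visit) to the latest
(including death). The source method's exact construction rule is not
public, so this explicit stand-in is used; `allow_out_of_period`
(default true) controls whether events outside an externally supplied
period are kept, reflecting current OMOP practice of allowing them. Drug
eras merge same-person, same-drug exposures separated by ≤ 30 days (the
common OHDSI gap convention); grouping is at the drug-concept level since
the fixture vocabulary carries no ingredient hierarchy.

## Quality model

Coverage is double-booked: terms (distinct source codes) and events
(individual records), a mapped term/event being one that resolved to a
nonzero standard concept. Worklist prioritization returns the shortest
descending-frequency prefix of terms covering ≥ 80% of events (ties by
code), the rule used to focus manual mapping effort.

The DQ engine implements the three check families compactly (~14 checks)
rather than a full multi-thousand-check catalogue:

* **completeness** — share of concept-0 records per routed table; fails
  strictly above the 20% threshold. Severity *warning*: a failure here is
  the expected footprint of residual unmapped codes (the observation
  table, as the concept-0 sink, routinely exceeds the threshold even at
  ~90% overall coverage) and should be read against the coverage report.
* **conformance** — a nonzero standard concept's domain must match its
  table, and unit columns must hold Unit-domain concepts; any violation
  fails, severity *error* (these indicate mis-curated mappings). The
  observation table is exempt from the event-concept rule because it is
  the designated default sink.
* **plausibility** — gender-specific concepts on persons of the recorded
  other gender; severity *warning* and rows are kept, since such records
  come from the source data.

DQ runs are read-only (asserted by content hash). The pipeline exits
nonzero only on error-severity failures.

## Synthetic data

The generator's defaults define the study conditions: 1,000 participants;
COVID-19 prevalence 5%; per-vocabulary event-level mapped fractions
echoing real UK terminology coverage (SNOMED 0.97, CTV3 0.90, ICD-10
0.98, ICD-9 0.92, OPCS-4 0.89, OPCS-3 0.77, dm+d 0.99, bespoke
questionnaire 0.84, proprietary 0.20); special-value rate 1%;
missing-year-of-birth rate 0.1% (so one participant in 1,000 is
rejected); 1:many rate 10%; mean events per person 6 (GP), 4
(prescriptions), 1 (hospital), 0.3 (tests); 0.23% of cases evidenced only
by an unmappable CTV3 code. Every planted rate is realized *exactly*
where integer counts permit, via largest-remainder apportionment, and a
ground-truth JSON records the realized per-vocabulary term/event counts
using the same counting rules as the ETL's run log — so coverage reports
are checked by equality, not tolerance. The cross-maps plant one case of
every selection-rule shape (preferred/active filter, standard filter,
domain priority, tie-break, strict-filter fallback), and the custom map
ships the canonical hypertension entry (20002/1065 → 4214956 + 316866)
and the SARS-CoV-2 test concepts.

What the generator does *not* emulate: realistic disease co-occurrence,
demography, visit structure, or code-frequency distributions — it targets
structural fidelity (file shapes, coding pathologies, mapping edge
cases). Passing tests therefore demonstrate that the machinery is
correct, deterministic and conservation-safe on data with the right
*structure*; they say nothing about coverage levels achievable on any
real extract. Dates are uniform over 2006–2021 with COVID-era evidence
confined to 2020–2021 and death dates after a person's last event; one
integer seed drives an independent RNG stream per output file, so adding
a file never perturbs the others, and identical seeds yield byte-identical
bundles.

## Numerical and procedural choices

* Dates are ISO-8601 strings throughout; time-of-day is not modelled.
* Provenance (`*_type_concept_id`) is one fixed constant per source
  stream, configurable in `PipelineConfig`.
* Health-economics tables (payer_plan_period, cost) are created but never
  populated: schema-only by design.
* Completeness uses a strict `>` comparison at the threshold; an
  exactly-20% table passes.
* Test problem sizes: the unit suites run on a 60-participant bundle that
  concentrates every pathology (rejections, unmappable-only cases, a
  planted unit-domain defect); the acceptance properties additionally run
  on a default 1,000-participant bundle.

## Known limitations

* The tie-break and observation-period policies are explicit stand-ins
  for manual/unspecified steps in the original workflow.
* Drug eras group by drug concept, not ingredient.
* Phenotype definitions are structural fixtures, not validated clinical
  codelists; the COVID-19 definition mirrors the multi-source union logic
  but not any published code list.
* Cancer-registry (ICD-O) records are out of scope and ignored if
  present.
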