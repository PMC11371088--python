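# Methods

## Scope and shape

The toolkit models a four-stage migration: a tabular analytical EHR export
(the shape of an Epic Clarity extract), a rule-driven transformation into
mCODE FHIR R4 profiles, an entity–attribute–value (EAV) profile store with
FHIR-style search, and application-level cohort analytics. Each stage is an
independent library module with a thin CLI on top; everything downstream of
the generator consumes only the documented interfaces, so real extract CSVs
with the same schema can be substituted for synthetic ones.

## Profile model

Five profile kinds are implemented: CancerPatient (FHIR `Patient`),
GenomicsReport (`DiagnosticReport`), GenomicVariant and GenomicRegionStudied
(`Observation`), GenomicSpecimen (`Specimen`). The registry of kinds — FHIR
resource type, canonical profile URL, per-field value type, must-support
flag, code system and serialization slot — is a single machine-readable
table (`src/mcodekit/data/profile_fields.json`), so validation, EAV
flattening and JSON emission are all data-driven and a further kind (e.g. a
condition profile) can be added without touching code. Must-support sets
follow the mCODE STU implementation guide's genomics profiles; variant
attributes map to the standard LOINC component codes (48018-6 gene, 48004-6
c.HGVS, 48019-4 change type, 48002-0 genomic source class, 48005-3 p.HGVS,
81258-6 allelic frequency, 53037-8 clinical significance).

The must-support contract: every must-support field is either populated or
covered by exactly one `dataAbsentReason` (codes `unknown`, `masked`,
`not-performed`, `not-asked`; default `unknown` when a source cell is simply
empty). A field may never be both present and absent, and validation
enumerates every uncovered field as an error. Extensions never invalidate a
profile.

Source data with no home in these five kinds is carried as FHIR extensions
under a configurable namespace (default `urn:example:mcode-pilot:`).
Phecode diagnoses are the main case: each diagnosis becomes two extensions
on the patient profile (`diagnosis/<phecode>` with the coded value,
`diagnosis/<phecode>/onset` with the date). Extensions record the field
they relate to in an `anchor` sub-extension and are emitted at resource
level; anchoring the JSON element itself was rejected as it would make the
parser depend on every slot type's extension syntax for little analytical
gain.

Serialization is canonical JSON (UTF-8, sorted keys, minimal whitespace,
extensions sorted by URL, components in registry order), so structural
equality of profiles coincides with byte equality of their JSON, and
`from_fhir_json ∘ to_fhir_json` is the identity on valid profiles — both
are property-tested over randomized profiles.

## Synthetic extract generator

The generator emulates the content a genomics-enabled oncology EHR export
carries, not any proprietary schema: the CSV layout (five tables, fixed
columns, RFC-4180, empty cell = absent) is an explicit stand-in documented
here because the real export schema is unpublished. What it emulates:
demographics (sex/race/ethnicity codes with empirically plausible
frequencies), adult-oncology birth dates (1935–2005, so ages against the
default `as_of` 2021-01-01 are ~15–86), event dates in a fixed 2000–2020
window (never wall clock, keeping age computation reproducible), reports
with Poisson-distributed variant counts (`variant_rate`, default 2), HGVS-
like c. and p. strings consistent with the drawn change type, allelic
fractions in [0.02, 0.98], five-level clinical significance, an 80/20
somatic/germline split, panel regions as the variant genes plus two random
extras (10 % of reports carry no region data, so the region-profile count G
is a proper subset of R), and one specimen per report.

Missingness is Bernoulli per cell at a single configurable rate over the
nullable columns (race, ethnicity, change type, amino-acid change, allelic
frequency, clinical significance, specimen type); with rate *p* and *n*
cells the absent fraction is binomial, and tests check it within 3
standard errors.

Diagnoses use a two-part model. `diagnosis_model[gene][phecode] = w` means:
a patient carrying ≥ 1 variant of that gene receives that diagnosis with
probability exactly *w*; background diagnoses (Poisson count, default mean
0.9 per patient, matching roughly one cancer diagnosis per patient) are
drawn only from Phecodes *not* configured for the patient's carried genes.
Excluding enriched codes from the background keeps the configured value
identifiable as P(c | g) without deconvolution, which is what makes the
parameter-recovery test sharp. What the generator does **not** emulate:
correlated mutational signatures, linkage between variants, co-mutation
structure, longitudinal records, or realistic marginal diagnosis
prevalences — so passing tests demonstrate pipeline correctness, not
clinical realism of any derived statistic.

Determinism: one RNG stream per table, spawned from the single seed
(`numpy` `SeedSequence`), so identical (config, seed) gives byte-identical
CSVs and enlarging one table does not perturb the sampling order of others.

## ETL

The mapping table ships as a versioned data file (rules: source column →
kind.field; translations: source code → target code/display), because
reconciling source and mCODE naming conventions is inherently manual. A
load-time invariant requires every must-support field of every kind to be
the target of exactly one rule or an explicit no-source entry. Untranslatable
codes raise an error naming the value and column; row-level errors never
abort a cohort — they are collected with coordinates and clean rows proceed
(standard bulk-ETL practice, and it keeps the conservation audit total).

Resource ids are deterministic functions of source ids (`pat:<mrn>`,
`rep:<report>`, `var:<report>:<ordinal>`, `reg:<report>`, `spe:<specimen>`),
so re-running the ETL upserts rather than duplicates. The bundle size
identity P + R + V + G + S is property-tested over random configs.
Variants with every optional field blank are transformed with data-absent
reasons (structurally complete, contentually empty); specimens never
referenced by a report are transformed as orphans.

Every populated source cell is recorded in a provenance map to its
destination (field, extension, identifier/reference, or logged error). The
audit replays the map against the bundle — or the loaded store, proving
end-to-end recoverability — and fails on any unaccounted cell.

Loading is batched (`ceil(n / batch_size)` batches) across a thread pool.
The contract is order-independence of the final store state, not a specific
mechanism: upserts keyed by unique resource ids commute, so any
workers/batch-size combination yields identical contents (asserted by
whole-store set equality).

## Store and search

SQLite, one row per populated leaf: dotted, indexed attribute paths
(`gene.code`, `result_refs.0`), `absent.<field>` for data-absent reasons,
`ext|<url>|...` for extensions (the `|` separator avoids ambiguity with
dots inside URLs). `from_eav ∘ to_eav` is the identity (property-tested).
Validation happens at write time; rejected profiles leave the store
untouched.

Search predicates are conjunctive: kind, subject, gene (variant gene,
region membership, or — for patient/report/specimen resources — carriage by
the subject patient), Phecode (via the patient's diagnosis extensions),
sex/race/age-range (via the subject patient; ages computed against the
store's persisted `as_of` date), and genomic source class (variants only).
Ordering is lexicographic by (kind, resource_id) — deterministic ordering
is required for testable pagination; the page cap is 1,000 (a configurable
constant, defaulted to the limit of the hosted server this store stands in
for). Continuation tokens encode the last-returned key plus a fingerprint
of the query, so keyset pagination never duplicates results across
concurrent inserts and a token cannot be replayed against a different
query; pages partition the brute-force match set exactly.

## Analytics

Distribution tables tally variant rows per gene or diagnoses per Phecode;
entries are sorted by count descending (ties lexicographic), truncated to
top-N (default 30), with percentages always computed over all categories.
Summary tables emit one row per (patient, variant) pair with the six
variant attributes plus demographics; deidentification is surrogate keys in
stable patient order plus age in years — no source identifier or birth date
appears. The initial page is 10 rows and any request is clamped to 200.

Incidence is computed at patient level (a patient with two variants of a
gene counts once) and at gene granularity by default — matching the
calculator's gene-level interface — with an optional exact-HGVS restriction.
Patients with several mapped diagnoses contribute to each cancer type, so
probabilities across types can sum above 1; the sum-to-one check therefore
uses single-diagnosis cohorts. Counts are pure maximum-likelihood ratios
(no smoothing or pseudocounts). The 33 cancer-type abbreviations and the
Phecode-to-type map are data files. Analytics accept a store or an
in-memory bundle (the in-process analogue of precomputed statistics); both
paths are asserted equal.

## Problem sizes and numerical choices

The test and acceptance runs use cohorts of 25–2,000 patients: 500 for the
end-to-end audit, 2,500 profiles for the pagination partition, 50 small
random cohorts for the Bayes/oracle comparison (tolerance 1e-12, pure
counting arithmetic), and for parameter recovery a 10-gene panel (a
realistic targeted assay, which makes EGFR carriage common enough — about
18 % of patients at `variant_rate=2` — for a sharp 3-standard-error check
at n = 2,000) with 0.4 lung-cancer enrichment, plus 500-patient cohorts for
the ranked-first frequency. Ages use completed years; distribution ties
break lexicographically; fractions are validated to [0, 1]; degenerate
inputs (empty cohort, zero carriers, empty regions) return empty/flagged
results rather than errors.

## Known limitations

- FHIR coverage is exactly the five kinds; codes are checked for shape and
  registry-declared systems, not terminology membership.
- The store is not a FHIR REST server (no versioning, history, transaction
  bundles or authentication) — it reproduces the storage model and the
  search/pagination behaviour the analytics depend on.
- The synthetic cohort is statistically simple by design (independence
  across patients and variants); conclusions about real-data performance
  are limited to pipeline correctness.
- A sixth (condition) profile kind would let diagnoses live as first-class
  resources instead of patient extensions; the registry is ready for it.
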