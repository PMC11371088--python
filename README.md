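# mcodekit

A self-contained toolkit for exercising the full path from an oncology EHR
export to analysable [mCODE](https://hl7.org/fhir/us/mcode/) (Minimal Common
Oncology Data Elements) FHIR genomics profiles. It is aimed at clinical
informaticists who want to prototype or test an mCODE migration — mapping
rules, must-support validation, server loading, cohort queries — without
access to protected patient data or a hosted FHIR server.

The toolkit covers five stages:

1. **Synthetic source data** — a deterministic generator for Clarity-style
   tabular extracts: patients, Phecode-coded cancer diagnoses, genomic test
   reports, HGVS gene-variant observations and specimens, with configurable
   missingness and gene-conditional diagnosis enrichment.
2. **mCODE profiles** — five profile kinds (CancerPatient, GenomicsReport,
   GenomicVariant, GenomicRegionStudied, GenomicSpecimen) with must-support
   validation, FHIR `dataAbsentReason` placeholders for unfillable fields,
   extensions for source data with no mCODE home, and canonical FHIR R4 JSON
   serialization both ways.
3. **Three-step ETL** — extract rows, transform them through a versioned
   column-to-field mapping table with code-system translation, and bulk-load
   the result (NDJSON, batched, concurrency-safe) with validation on load.
   A cell-level provenance audit proves no source value is silently lost.
4. **EAV profile store** — an embedded SQLite stand-in for a managed FHIR
   server: profiles flattened to entity–attribute–value rows, idempotent
   upserts, and FHIR-style conjunctive search with deterministic keyset
   pagination capped at 1,000 profiles per page.
5. **Cohort analytics** — top-30 gene / Phecode distribution tables,
   deidentified per-variant summary tables (10-row initial page, 200-row
   request cap), and a conditional cancer-incidence calculator over the 33
   TCGA cancer types.

## The incidence calculator

For a gene variant *V* and cancer type *C* the calculator estimates, over
distinct patients, the conditional probability of diagnosis given carriage
by Bayes' theorem:

```
P(C | V) = P(V | C) · P(C) / P(V)
         ≈ (n(V∧C)/n(C)) · (n(C)/n) / (n(V)/n)  =  n(V∧C) / n(V)
```

Both the three-factor form and the direct ratio are computed from the same
counts and exposed in every result so the arithmetic is auditable. A
patient carries *V* if any of their variant profiles matches the gene (an
exact-HGVS mode is available); a gene with zero carriers yields an explicit
"not observed" outcome rather than a division error.

## Worked example

```
$ mcodekit generate --n-patients 200 --seed 42 --out extract
patients.csv: 200 rows
diagnoses.csv: 205 rows
reports.csv: 200 rows
variants.csv: 420 rows
specimens.csv: 200 rows

$ mcodekit transform --extract extract --out bundle.ndjson
wrote 1197 profiles to bundle.ndjson

$ mcodekit load --bundle bundle.ndjson --store store.db --batch-size 500 --workers 4
{
  "attempted": 1197,
  "loaded": 1197,
  "rejected": [],
  "batches": 3,
  "elapsed_seconds": 0.078
}
```

The 1,197 profiles are exactly P + R + V + G + S: 200 patients + 200
reports + 420 variant observations + 177 region-studied panels (reports
with region data) + 200 specimens. Every profile validated at load time;
none were rejected.

```
$ mcodekit stats --store store.db --axis gene --top-n 5
{
  "axis": "gene",
  "truncated_to": 5,
  "entries": [
    {"label": "ATM",  "count": 17, "percentage": 4.0476},
    {"label": "ESR1", "count": 14, "percentage": 3.3333},
    ...
  ]
}
```

Counts tally variant observations per gene; percentages are shares of *all*
420 variants, so a truncated table still reads against the whole cohort.

```
$ mcodekit risk --store store.db --gene EGFR | head -4
cancer_type,p_c_given_v,count_v_and_c,count_c,count_v,n_patients
CESC,0.111111,1,15,9,200
CHOL,0.111111,1,11,9,200
DLBC,0.111111,1,11,9,200
```

Reading the first row: 9 of 200 patients carry an EGFR variant, 1 of those
9 also has a cervical-cancer diagnosis, so P(CESC | EGFR) = 1/9 ≈ 0.11.

The same operations are available as library functions (`generate_cohort`,
`transform_cohort`, `load_bundle`, `distribution`, `summary_table`,
`incidence`) on either a store or an in-memory profile bundle.

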