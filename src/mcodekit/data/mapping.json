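{
  "_comment": "Versioned source-to-mCODE mapping table. Each rule maps one extract column onto one profile field; value translations reconcile source code systems with the target code systems declared in profile_fields.json. Phecode diagnoses have no field in the five implemented kinds and are carried as extensions on the CancerPatient profile (see the 'extensions' note). Must-support fields with no source column would be listed under 'no_source' and receive a data-absent reason unconditionally.",
  "version": "1.0",
  "rules": [
    {"source_table": "patients", "source_column": "birth_date", "kind": "CancerPatient", "field": "birth_date"},
    {"source_table": "patients", "source_column": "sex", "kind": "CancerPatient", "field": "sex"},
    {"source_table": "patients", "source_column": "race", "kind": "CancerPatient", "field": "race"},
    {"source_table": "patients", "source_column": "ethnicity", "kind": "CancerPatient", "field": "ethnicity"},
    {"source_table": "reports", "source_column": "test_date", "kind": "GenomicsReport", "field": "test_date"},
    {"source_table": "reports", "source_column": "specimen_id", "kind": "GenomicsReport", "field": "specimen_ref"},
    {"source_table": "reports", "source_column": "regions_studied", "kind": "GenomicRegionStudied", "field": "genes"},
    {"source_table": "variants", "source_column": "gene_symbol", "kind": "GenomicVariant", "field": "gene"},
    {"source_table": "variants", "source_column": "dna_change", "kind": "GenomicVariant", "field": "dna_change"},
    {"source_table": "variants", "source_column": "dna_change_type", "kind": "GenomicVariant", "field": "dna_change_type"},
    {"source_table": "variants", "source_column": "genomic_source_class", "kind": "GenomicVariant", "field": "genomic_source_class"},
    {"source_table": "variants", "source_column": "amino_acid_change", "kind": "GenomicVariant", "field": "amino_acid_change"},
    {"source_table": "variants", "source_column": "allelic_frequency", "kind": "GenomicVariant", "field": "allelic_frequency"},
    {"source_table": "variants", "source_column": "clinical_significance", "kind": "GenomicVariant", "field": "clinical_significance"},
    {"source_table": "specimens", "source_column": "specimen_type", "kind": "GenomicSpecimen", "field": "specimen_type"},
    {"source_table": "specimens", "source_column": "collected_date", "kind": "GenomicSpecimen", "field": "collected_date"}
  ],
  "no_source": [],
  "translations": {
    "patients.sex": {"F": "female", "M": "male", "O": "other", "U": "unknown"},
    "patients.race": {
      "W": "2106-3", "B": "2054-5", "A": "2028-9", "N": "1002-5", "P": "2076-8", "U": "UNK"
    },
    "patients.ethnicity": {"H": "2135-2", "N": "2186-5", "U": "UNK"},
    "variants.genomic_source_class": {
      "somatic": ["LA6684-0", "Somatic"],
      "germline": ["LA6683-2", "Germline"]
    },
    "variants.clinical_significance": {
      "Pathogenic": ["LA6668-3", "Pathogenic"],
      "Likely pathogenic": ["LA26332-9", "Likely pathogenic"],
      "Uncertain significance": ["LA26333-7", "Uncertain significance"],
      "Likely benign": ["LA26334-5", "Likely benign"],
      "Benign": ["LA6675-8", "Benign"]
    },
    "variants.dna_change_type": {
      "SNV": ["SO:0001483", "SNV"],
      "DEL": ["SO:0000159", "deletion"],
      "INS": ["SO:0000667", "insertion"],
      "DUP": ["SO:1000035", "duplication"],
      "DELINS": ["SO:1000032", "delins"]
    },
    "specimens.specimen_type": {
      "TUMOR": ["TUMOR", "Tumor tissue"],
      "BLOOD": ["BLD", "Whole blood"],
      "SALIVA": ["SAL", "Saliva"],
      "TISSUE": ["TISS", "Tissue"]
    }
  },
  "extensions": {
    "diagnoses": "Each diagnoses.csv row becomes two extensions on the patient's CancerPatient profile under the configured namespace: 'diagnosis/{phecode}' (coded: Phecode system, code, label) and 'diagnosis/{phecode}/onset' (date)."
  }
}
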