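{
  "_comment": "Machine-readable declaration of the five implemented mCODE profile kinds: FHIR resource type, canonical profile URL, and the per-kind field table (name, value type, must-support flag, FHIR serialization slot, code system for coded fields). Must-support sets follow the mCODE STU implementation guide for the genomics profiles; the registry is data-driven so further kinds can be added without code changes.",
  "kinds": {
    "CancerPatient": {
      "resource_type": "Patient",
      "profile_url": "http://hl7.org/fhir/us/mcode/StructureDefinition/mcode-cancer-patient",
      "has_subject": false,
      "fields": [
        {"name": "birth_date", "type": "date", "must_support": true,
         "slot": {"kind": "primitive", "element": "birthDate"}},
        {"name": "sex", "type": "code", "must_support": true,
         "slot": {"kind": "primitive", "element": "gender"}},
        {"name": "race", "type": "code", "must_support": true,
         "slot": {"kind": "extension_code", "url": "http://hl7.org/fhir/us/core/StructureDefinition/us-core-race"}},
        {"name": "ethnicity", "type": "code", "must_support": true,
         "slot": {"kind": "extension_code", "url": "http://hl7.org/fhir/us/core/StructureDefinition/us-core-ethnicity"}}
      ]
    },
    "GenomicsReport": {
      "resource_type": "DiagnosticReport",
      "profile_url": "http://hl7.org/fhir/us/mcode/StructureDefinition/mcode-cancer-genomics-report",
      "has_subject": true,
      "report_code": {"system": "http://loinc.org", "code": "81247-9", "display": "Master HL7 genetic variant reporting panel"},
      "fields": [
        {"name": "test_date", "type": "date", "must_support": true,
         "slot": {"kind": "primitive", "element": "effectiveDateTime"}},
        {"name": "specimen_ref", "type": "ref", "must_support": true,
         "slot": {"kind": "specimen_ref"}, "ref_type": "Specimen"},
        {"name": "result_refs", "type": "ref_list", "must_support": false,
         "slot": {"kind": "result_refs"}, "ref_type": "Observation"},
        {"name": "region_refs", "type": "ref_list", "must_support": false,
         "slot": {"kind": "extension_ref_list", "url": "http://hl7.org/fhir/us/mcode/StructureDefinition/mcode-region-studied-ref"},
         "ref_type": "Observation"}
      ]
    },
    "GenomicVariant": {
      "resource_type": "Observation",
      "profile_url": "http://hl7.org/fhir/us/mcode/StructureDefinition/mcode-genomic-variant",
      "has_subject": true,
      "observation_code": {"system": "http://loinc.org", "code": "69548-4", "display": "Genetic variant assessment"},
      "fields": [
        {"name": "gene", "type": "coded", "must_support": true, "system": "http://www.genenames.org",
         "slot": {"kind": "component", "loinc": "48018-6", "display": "Gene studied [ID]"}},
        {"name": "dna_change", "type": "coded", "must_support": true, "system": "http://varnomen.hgvs.org",
         "slot": {"kind": "component", "loinc": "48004-6", "display": "DNA change (c.HGVS)"}},
        {"name": "dna_change_type", "type": "coded", "must_support": true, "system": "http://sequenceontology.org",
         "slot": {"kind": "component", "loinc": "48019-4", "display": "DNA change type"}},
        {"name": "genomic_source_class", "type": "coded", "must_support": true, "system": "http://loinc.org",
         "slot": {"kind": "component", "loinc": "48002-0", "display": "Genomic source class"}},
        {"name": "amino_acid_change", "type": "coded", "must_support": true, "system": "http://varnomen.hgvs.org",
         "slot": {"kind": "component", "loinc": "48005-3", "display": "Amino acid change (p.HGVS)"}},
        {"name": "allelic_frequency", "type": "fraction", "must_support": true,
         "slot": {"kind": "component", "loinc": "81258-6", "display": "Sample variant allelic frequency"}},
        {"name": "clinical_significance", "type": "coded", "must_support": true, "system": "http://loinc.org",
         "slot": {"kind": "component", "loinc": "53037-8", "display": "Genetic variation clinical significance"}}
      ]
    },
    "GenomicRegionStudied": {
      "resource_type": "Observation",
      "profile_url": "http://hl7.org/fhir/us/mcode/StructureDefinition/mcode-genomic-region-studied",
      "has_subject": true,
      "observation_code": {"system": "http://loinc.org", "code": "53041-0", "display": "DNA region of interest panel"},
      "fields": [
        {"name": "genes", "type": "code_list", "must_support": true, "system": "http://www.genenames.org",
         "slot": {"kind": "component_list", "loinc": "48018-6", "display": "Gene studied [ID]"}}
      ]
    },
    "GenomicSpecimen": {
      "resource_type": "Specimen",
      "profile_url": "http://hl7.org/fhir/us/mcode/StructureDefinition/mcode-human-specimen",
      "has_subject": true,
      "fields": [
        {"name": "specimen_type", "type": "coded", "must_support": true,
         "system": "http://terminology.hl7.org/CodeSystem/v2-0487",
         "slot": {"kind": "specimen_type"}},
        {"name": "collected_date", "type": "date", "must_support": true,
         "slot": {"kind": "collected"}}
      ]
    }
  }
}
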