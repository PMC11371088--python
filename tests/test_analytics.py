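"""Analytics vs brute-force counting oracles over the raw extract."""

from __future__ import annotations

import math

import pytest

from conftest import (
    oracle_diagnosis_counts,
    oracle_gene_counts,
    oracle_incidence,
)
from mcodekit.analytics import (
    CohortFilter,
    CohortView,
    distribution,
    incidence,
    incidence_report,
    phecode_to_label,
    summary_table,
    tcga_labels,
)
from mcodekit.etl import load_bundle, transform_cohort
from mcodekit.store import EavStore
from mcodekit.synthetic import CohortConfig, default_genes, generate_cohort


@pytest.fixture(scope="module")
def cohort():
    extract = generate_cohort(
        CohortConfig(n_patients=60, seed=33, missingness=0.15, variant_rate=2,
                     background_diagnosis_rate=1.2)
    )
    result = transform_cohort(extract)
    store = EavStore()
    load_bundle(result.bundle, store)
    return extract, result.bundle, store


# ---------------------------------------------------------------------------
# distributions

def test_gene_distribution_matches_direct_tally(cohort):
    extract, _, store = cohort
    expected = oracle_gene_counts(extract)
    table = distribution(store, "gene", top_n=len(expected))
    assert {label: n for label, n, _ in table.entries} == dict(expected)


def test_phecode_distribution_matches_direct_tally(cohort):
    extract, _, store = cohort
    expected = oracle_diagnosis_counts(extract)
    table = distribution(store, "phecode", top_n=len(expected))
    assert {label: n for label, n, _ in table.entries} == dict(expected)


def test_truncation_to_top_n(cohort):
    _, _, store = cohort
    table = distribution(store, "gene", top_n=5)
    assert len(table.entries) == 5 and table.truncated_to == 5
    counts = [n for _, n, _ in table.entries]
    assert counts == sorted(counts, reverse=True)
    assert sum(pct for _, _, pct in table.entries) <= 100.0 + 1e-9


def test_small_store_percentages_sum_to_100(cohort):
    _, bundle, _ = cohort
    table = distribution(bundle, "gene", top_n=10_000)
    assert table.truncated_to is None
    assert math.isclose(sum(p for _, _, p in table.entries), 100.0)


def test_unknown_axis_rejected(cohort):
    with pytest.raises(ValueError, match="axis"):
        distribution(cohort[2], "specimen")


def test_bundle_and_store_sources_agree(cohort):
    _, bundle, store = cohort
    assert distribution(bundle, "gene").entries == distribution(store, "gene").entries


# ---------------------------------------------------------------------------
# summary table

def test_default_request_returns_ten_rows(cohort):
    _, _, store = cohort
    rows = summary_table(store)
    assert len(rows.rows) == 10 and rows.limit == 10 and rows.offset == 0


def test_limit_clamped_to_200(cohort):
    _, _, store = cohort
    rows = summary_table(store, limit=500)
    assert rows.limit == 200 and len(rows.rows) <= 200


def test_rows_are_deidentified(cohort):
    extract, _, store = cohort
    rows = summary_table(store, limit=200)
    source_ids = {p.patient_id for p in extract.patients}
    for row in rows.rows:
        assert row["case_id"].startswith("case-")
        assert set(row.values()) & source_ids == set()
        assert "birth_date" not in row and "patient_id" not in row


def test_filtered_rows_match_brute_force_join(cohort):
    extract, _, store = cohort
    rows = summary_table(
        store, CohortFilter(sex="F", gene_symbol="TP53"), limit=200
    )
    report_patient = {r.report_id: r.patient_id for r in extract.reports}
    females = {p.patient_id for p in extract.patients if p.sex == "F"}
    expected = [
        v for v in extract.variants
        if v.gene_symbol == "TP53" and report_patient[v.report_id] in females
    ]
    assert len(rows.rows) == len(expected)
    assert {r["dna_change"] for r in rows.rows} == {v.dna_change for v in expected}
    assert all(r["gene"] == "TP53" and r["sex"] == "female" for r in rows.rows)


def test_offset_pages_through_rows(cohort):
    _, _, store = cohort
    first = summary_table(store, limit=10)
    second = summary_table(store, offset=10, limit=10)
    assert first.rows != second.rows
    everything = summary_table(store, limit=200)
    assert first.rows + second.rows == everything.rows[:20]


def test_bad_summary_arguments_rejected(cohort):
    _, _, store = cohort
    with pytest.raises(ValueError):
        summary_table(store, offset=-1)
    with pytest.raises(Exception):
        CohortFilter(age_range=(90, 10))


# ---------------------------------------------------------------------------
# conditional incidence

def test_incidence_matches_counting_oracle_per_label(cohort):
    extract, _, store = cohort
    results = incidence_report(store, "TP53")
    assert len(results) == 33
    for r in results:
        vc, c, v, n, p = oracle_incidence(extract, "TP53", r.cancer_type)
        assert (r.count_v_and_c, r.count_c, r.count_v, r.n_patients) == (vc, c, v, n)
        if p is None:
            assert r.p_c_given_v is None
        else:
            assert abs(r.p_c_given_v - p) <= 1e-12


def test_bayes_form_equals_direct_ratio(cohort):
    _, _, store = cohort
    for r in incidence_report(store, "EGFR"):
        if r.p_c_given_v is not None and r.count_c > 0:
            assert abs(r.p_c_given_v - r.p_bayes) <= 1e-12


def test_results_ranked_descending(cohort):
    _, _, store = cohort
    ps = [r.p_c_given_v for r in incidence_report(store, "KRAS")]
    ps = [p if p is not None else -1 for p in ps]
    assert ps == sorted(ps, reverse=True)


def test_unobserved_variant_is_not_a_division_error(cohort):
    _, _, store = cohort
    results = incidence_report(store, "NOSUCHGENE")
    assert all(not r.variant_observed and r.p_c_given_v is None for r in results)


def test_hand_built_cohort_gives_exact_fraction():
    """10 carriers, 4 with the cancer: P(C|V) = 0.4 exactly."""
    from mcodekit.profiles import CodedValue, McodeProfile, ProfileBundle

    ns = "urn:example:mcode-pilot:"
    profiles = []
    for i in range(12):
        ext = []
        if i < 4 or i == 11:  # 4 carriers + 1 non-carrier have lung cancer
            ext = [__import__("mcodekit.profiles", fromlist=["ExtensionValue"])
                   .ExtensionValue(url=f"{ns}diagnosis/165.1",
                                   value=CodedValue("urn:example:phecode", "165.1",
                                                    "Lung"),
                                   anchor_path="resource")]
        profiles.append(McodeProfile(
            kind="CancerPatient", resource_id=f"pat:{i:02d}",
            fields={"birth_date": "1950-01-01", "sex": "female",
                    "race": "2106-3", "ethnicity": "2186-5"},
            extensions=ext,
        ))
    for i in range(10):  # first 10 patients carry an EGFR variant
        profiles.append(McodeProfile(
            kind="GenomicVariant", resource_id=f"var:{i:02d}",
            subject_ref=f"pat:{i:02d}",
            fields={"gene": CodedValue("http://www.genenames.org", "EGFR", "EGFR"),
                    "dna_change": CodedValue("http://varnomen.hgvs.org", "c.1A>G"),
                    "dna_change_type": CodedValue("http://sequenceontology.org",
                                                  "SO:0001483", "SNV"),
                    "genomic_source_class": CodedValue("http://loinc.org",
                                                       "LA6684-0", "Somatic"),
                    "amino_acid_change": CodedValue("http://varnomen.hgvs.org",
                                                    "p.Ala1Gly"),
                    "allelic_frequency": 0.5,
                    "clinical_significance": CodedValue("http://loinc.org",
                                                        "LA6668-3", "Pathogenic")},
        ))
    bundle = ProfileBundle(profiles)
    results = incidence(bundle, "EGFR", cancer_labels=["LUAD"])
    (r,) = results
    assert (r.count_v, r.count_v_and_c, r.count_c, r.n_patients) == (10, 4, 5, 12)
    assert r.p_c_given_v == 0.4
    assert abs(r.p_bayes - 0.4) <= 1e-12


def test_certainty_case_probability_one(cohort):
    """A variant carried only by patients with cancer C gives P(C|V)=1."""
    extract = generate_cohort(CohortConfig(
        n_patients=200, seed=77, missingness=0, variant_rate=1.5,
        genes=default_genes()[:6],
        diagnosis_model={"BRAF": {"172.11": 1.0}},
        background_diagnosis_rate=0.0,
    ))
    result = transform_cohort(extract)
    results = incidence(result.bundle, "BRAF", cancer_labels=["SKCM"])
    (r,) = results
    assert r.count_v > 0 and r.p_c_given_v == 1.0


def test_single_diagnosis_cohort_probabilities_sum_to_one():
    """When every carrier has exactly one mapped cancer, sum_c P(c|V) = 1."""
    extract = generate_cohort(CohortConfig(
        n_patients=400, seed=55, missingness=0, variant_rate=2,
        genes=default_genes()[:6], background_diagnosis_rate=0.0,
        diagnosis_model={g: {"165.1": 0.5, "174.1": 0.5}
                         for g in default_genes()[:6]},
    ))
    # keep only patients with exactly one diagnosis
    keep = {d.patient_id for d in extract.diagnoses}
    counts = {}
    for d in extract.diagnoses:
        counts[d.patient_id] = counts.get(d.patient_id, 0) + 1
    singles = {pid for pid, c in counts.items() if c == 1}
    extract.diagnoses = [d for d in extract.diagnoses if d.patient_id in singles]
    result = transform_cohort(extract)
    view = CohortView(result.bundle)
    carriers = view.carriers("EGFR")
    diagnosed_carriers = carriers & {
        f"pat:{pid}" for pid in singles
    }
    results = incidence(view, "EGFR")
    total = sum(r.p_c_given_v for r in results if r.p_c_given_v is not None)
    # carriers without any diagnosis dilute the sum; restrict expectation
    assert math.isclose(total, len(diagnosed_carriers) / len(carriers), rel_tol=1e-12)


def test_parameter_recovery_small_cohort():
    """Configured P(lung|EGFR)=0.4 recovered within 3 SE on a fresh cohort."""
    cfg = CohortConfig(
        n_patients=1000, seed=13, missingness=0.1, variant_rate=2,
        genes=default_genes()[:10],
        diagnosis_model={"EGFR": {"165.1": 0.4}},
    )
    result = transform_cohort(generate_cohort(cfg))
    view = CohortView(result.bundle)
    r = next(x for x in incidence(view, "EGFR") if x.cancer_type == "LUAD")
    se = math.sqrt(0.4 * 0.6 / r.count_v)
    assert abs(r.p_c_given_v - 0.4) <= 3 * se


def test_vocabulary_files_consistent():
    labels = tcga_labels()
    assert len(labels) == 33
    mapped = set(phecode_to_label().values())
    assert mapped == {a for a, _ in labels}
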