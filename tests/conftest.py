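"""Shared fixtures: profile builders and brute-force counting oracles.

The oracles work directly on the raw synthetic extract tables, bypassing the
profile/store machinery entirely, so they are independent checks of every
statistic the analytics layer produces.
"""

from __future__ import annotations

from collections import Counter

import pytest

from mcodekit.analytics import phecode_to_label
from mcodekit.profiles import CodedValue, McodeProfile
from mcodekit.registry import kind_registry, kind_spec
from mcodekit.synthetic import ClarityExtract, CohortConfig, generate_cohort

# ---------------------------------------------------------------------------
# profile builders

_SAMPLE_VALUES = {
    "date": "2015-06-01",
    "code": "female",
    "ref": "spe:SP1",
    "string": "x",
}


def make_profile(kind: str, resource_id: str = "r1",
                 subject_ref: str | None = None) -> McodeProfile:
    """A fully populated, valid profile of the given kind."""
    spec = kind_spec(kind)
    fields = {}
    for fs in spec.fields:
        if fs.type == "coded":
            fields[fs.name] = CodedValue(
                system=fs.system or "urn:test", code=f"{fs.name}-code",
                display=f"{fs.name} display",
            )
        elif fs.type == "fraction":
            fields[fs.name] = 0.25
        elif fs.type == "ref_list":
            fields[fs.name] = [f"var:GR1:{i}" for i in range(2)]
        elif fs.type == "code_list":
            fields[fs.name] = ["EGFR", "TP53"]
        else:
            fields[fs.name] = _SAMPLE_VALUES[fs.type]
    if spec.has_subject and subject_ref is None:
        subject_ref = "pat:MRN100000"
    return McodeProfile(kind=kind, resource_id=resource_id,
                        subject_ref=subject_ref, fields=fields)


def all_kinds() -> list[str]:
    return sorted(kind_registry())


@pytest.fixture
def variant_profile() -> McodeProfile:
    return make_profile("GenomicVariant", "var:GR1:0")


@pytest.fixture(scope="session")
def small_extract() -> ClarityExtract:
    return generate_cohort(
        CohortConfig(n_patients=25, seed=11, missingness=0.15, variant_rate=2.0)
    )


# ---------------------------------------------------------------------------
# brute-force oracles over the raw extract

def oracle_gene_counts(extract: ClarityExtract) -> Counter:
    return Counter(v.gene_symbol for v in extract.variants if v.gene_symbol)


def oracle_diagnosis_counts(extract: ClarityExtract) -> Counter:
    return Counter(d.label for d in extract.diagnoses)


def oracle_carriers(extract: ClarityExtract, gene: str) -> set[str]:
    """Patients with >= 1 variant of ``gene``, joined through reports."""
    report_patient = {r.report_id: r.patient_id for r in extract.reports}
    return {
        report_patient[v.report_id]
        for v in extract.variants
        if v.gene_symbol == gene
    }


def oracle_patients_with_label(extract: ClarityExtract, label: str) -> set[str]:
    code_map = phecode_to_label()
    return {
        d.patient_id for d in extract.diagnoses
        if code_map.get(d.phecode) == label
    }


def oracle_incidence(extract: ClarityExtract, gene: str, label: str):
    """(count_v_and_c, count_c, count_v, n, p) counted from raw tables."""
    carriers = oracle_carriers(extract, gene)
    with_c = oracle_patients_with_label(extract, label)
    n = len(extract.patients)
    v = len(carriers)
    vc = len(carriers & with_c)
    return vc, len(with_c), v, n, (vc / v if v else None)
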