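"""Cohort analytics over stored mCODE profiles.

Reproduces the application-side computations: top-N distribution tables of
genes and Phecode diagnoses (top 30 by default, percentages over *all*
categories so a truncated table's shares still refer to the whole cohort),
filtered deidentified summary tables with the 10-row initial page and the
200-row request cap, and the conditional cancer-incidence calculator.

The incidence calculator estimates, over distinct patients, the probability
of carrying a diagnosis of cancer type ``c`` given at least one variant of
gene ``g``::

    P(C | V) = P(V | C) P(C) / P(V)

estimated by counts as ``n(V∧C)/n(C) · n(C)/n / (n(V)/n)``, which is
identically ``n(V∧C)/n(V)`` — both forms are exposed so the arithmetic is
auditable.  Cancer types are the 33 TCGA study abbreviations shipped as a
data file, reached from Phecodes through a packaged Phecode-to-type map.

Every function accepts either an :class:`~mcodekit.store.EavStore` or an
in-memory :class:`~mcodekit.profiles.ProfileBundle` as its source; the
bundle-backed path is the in-process analogue of serving charts from
precalculated statistics rather than live server queries.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Union

from pydantic import BaseModel, model_validator

from .profiles import CodedValue, McodeProfile, ProfileBundle
from .store import EavStore, age_in_years

__all__ = [
    "DistributionTable",
    "CohortFilter",
    "SummaryRows",
    "IncidenceResult",
    "CohortView",
    "distribution",
    "summary_table",
    "incidence",
    "incidence_report",
    "tcga_labels",
    "phecode_to_label",
    "DEFAULT_TOP_N",
    "SUMMARY_INITIAL_LIMIT",
    "SUMMARY_MAX_LIMIT",
]

#: Only the top 30 categories are shown by default, for concise visualization.
DEFAULT_TOP_N = 30
#: The summary view first presents 10 rows ...
SUMMARY_INITIAL_LIMIT = 10
#: ... and a single request is capped at 200 rows to prevent delays.
SUMMARY_MAX_LIMIT = 200

_SEX_ALIASES = {"f": "female", "m": "male", "o": "other", "u": "unknown"}

Source = Union[EavStore, ProfileBundle]


def tcga_labels() -> list[tuple[str, str]]:
    """The 33 (abbreviation, name) TCGA-style cancer types."""
    text = resources.files("mcodekit.data").joinpath("tcga_cancer_types.tsv").read_text()
    rows = [ln.split("\t") for ln in text.strip().splitlines()[1:]]
    return [(r[0], r[1]) for r in rows]


def phecode_to_label() -> dict[str, str]:
    """Packaged Phecode -> TCGA cancer-type abbreviation map."""
    text = resources.files("mcodekit.data").joinpath("neoplasm_phecodes.tsv").read_text()
    rows = [ln.split("\t") for ln in text.strip().splitlines()[1:]]
    return {r[0]: r[2] for r in rows}


# ---------------------------------------------------------------------------
# source adapter

class CohortView:
    """Read-only view of a profile source for analytics.

    Materializes patients, variants and per-patient diagnoses once, in
    deterministic (kind, resource_id) order.
    """

    def __init__(self, source: Source, as_of: Optional[str] = None):
        if isinstance(source, EavStore):
            profiles = list(source.iter_profiles())
            self.as_of = as_of or source.as_of
        else:
            profiles = sorted(source, key=lambda p: (p.kind, p.resource_id))
            self.as_of = as_of or "2021-01-01"
        self.patients = [p for p in profiles if p.kind == "CancerPatient"]
        self.variants = [p for p in profiles if p.kind == "GenomicVariant"]
        self._patient_by_id = {p.resource_id: p for p in self.patients}

    def patient_of(self, profile: McodeProfile) -> Optional[McodeProfile]:
        return self._patient_by_id.get(profile.subject_ref or "")

    @staticmethod
    def diagnoses_of(patient: McodeProfile) -> list[CodedValue]:
        """Phecode diagnoses carried as extensions on a patient profile."""
        out = []
        for e in patient.extensions:
            if "diagnosis/" in e.url and not e.url.endswith("/onset") \
                    and isinstance(e.value, CodedValue):
                out.append(e.value)
        return out

    def carriers(self, gene: str, hgvs: Optional[str] = None) -> set[str]:
        """Patient resource_ids with >= 1 matching variant (patient-level)."""
        out = set()
        for v in self.variants:
            g = v.fields.get("gene")
            if g is None or g.code != gene:
                continue
            if hgvs is not None:
                dc = v.fields.get("dna_change")
                if dc is None or dc.code != hgvs:
                    continue
            if v.subject_ref:
                out.add(v.subject_ref)
        return out


def _view(source: Source, as_of: Optional[str] = None) -> CohortView:
    return source if isinstance(source, CohortView) else CohortView(source, as_of)


# ---------------------------------------------------------------------------
# distributions

@dataclass
class DistributionTable:
    """Top-N category counts; percentages are shares of all categories."""

    axis: str
    entries: list[tuple[str, int, float]]  # (label, count, percentage)
    truncated_to: Optional[int] = None


def distribution(source: Source, axis: str, top_n: int = DEFAULT_TOP_N) -> DistributionTable:
    """Tally the ``gene`` axis over variant profiles or the ``phecode`` axis
    over patients' diagnosis extensions; entries sorted by count descending,
    ties broken lexicographically."""
    if axis not in ("gene", "phecode"):
        raise ValueError(f"unknown distribution axis {axis!r}; use 'gene' or 'phecode'")
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    view = _view(source)
    counts: Counter[str] = Counter()
    if axis == "gene":
        for v in view.variants:
            g = v.fields.get("gene")
            if g is not None:
                counts[g.display or g.code] += 1
    else:
        for p in view.patients:
            for d in view.diagnoses_of(p):
                counts[d.display or d.code] += 1
    total = sum(counts.values())
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    truncated = top_n if len(ordered) > top_n else None
    entries = [
        (label, n, 100.0 * n / total) for label, n in ordered[:top_n]
    ]
    return DistributionTable(axis=axis, entries=entries, truncated_to=truncated)


# ---------------------------------------------------------------------------
# summary table

class CohortFilter(BaseModel):
    """Conjunctive demographic and genomic filters for the summary table."""

    race: Optional[str] = None
    sex: Optional[str] = None
    age_range: Optional[tuple[float, float]] = None
    gene_symbol: Optional[str] = None

    @model_validator(mode="after")
    def _ordered(self):
        if self.age_range is not None and self.age_range[0] > self.age_range[1]:
            raise ValueError(f"age_range lo > hi: {self.age_range}")
        return self


@dataclass
class SummaryRows:
    """One deidentified row per (patient, variant) pair.

    Patients are identified only by a surrogate key and age in years as of
    the store's reference date; the six variant attributes mirror the
    summary view of the source application.
    """

    rows: list[dict]
    offset: int
    limit: int
    total: int


_ROW_COLUMNS = (
    "case_id", "age", "sex", "race", "ethnicity", "gene", "dna_change",
    "dna_change_type", "genomic_source_class", "amino_acid_change",
    "allelic_frequency", "clinical_significance",
)


def _display(value) -> Optional[str]:
    if isinstance(value, CodedValue):
        return value.display or value.code
    return value


def summary_table(
    source: Source,
    cohort_filter: Optional[CohortFilter] = None,
    offset: int = 0,
    limit: int = SUMMARY_INITIAL_LIMIT,
) -> SummaryRows:
    """Deterministic, filtered, paginated deidentified summary rows.

    ``limit`` defaults to the 10-row initial page and is clamped to the
    200-row request cap; ``offset`` pages through the remainder.
    """
    if offset < 0:
        raise ValueError("offset must be >= 0")
    if limit < 1:
        raise ValueError("limit must be >= 1")
    limit = min(limit, SUMMARY_MAX_LIMIT)
    f = cohort_filter or CohortFilter()
    view = _view(source)

    # surrogate keys in stable patient order: no source identifier leaks
    surrogate = {
        p.resource_id: f"case-{i + 1:05d}" for i, p in enumerate(view.patients)
    }
    rows: list[dict] = []
    variants_by_subject: dict[str, list[McodeProfile]] = {}
    for v in view.variants:
        if v.subject_ref:
            variants_by_subject.setdefault(v.subject_ref, []).append(v)

    for p in view.patients:
        bd = p.fields.get("birth_date")
        age = age_in_years(bd, view.as_of) if bd else None
        if f.sex is not None:
            wanted = _SEX_ALIASES.get(f.sex.lower(), f.sex.lower())
            if p.fields.get("sex", "").lower() != wanted:
                continue
        if f.race is not None and p.fields.get("race") != f.race:
            continue
        if f.age_range is not None:
            if age is None or not f.age_range[0] <= age <= f.age_range[1]:
                continue
        for v in sorted(
            variants_by_subject.get(p.resource_id, []), key=lambda x: x.resource_id
        ):
            g = v.fields.get("gene")
            if f.gene_symbol is not None and (g is None or g.code != f.gene_symbol):
                continue
            rows.append({
                "case_id": surrogate[p.resource_id],
                "age": age,
                "sex": p.fields.get("sex"),
                "race": p.fields.get("race"),
                "ethnicity": p.fields.get("ethnicity"),
                "gene": _display(g),
                "dna_change": _display(v.fields.get("dna_change")),
                "dna_change_type": _display(v.fields.get("dna_change_type")),
                "genomic_source_class": _display(v.fields.get("genomic_source_class")),
                "amino_acid_change": _display(v.fields.get("amino_acid_change")),
                "allelic_frequency": v.fields.get("allelic_frequency"),
                "clinical_significance": _display(v.fields.get("clinical_significance")),
            })
    total = len(rows)
    return SummaryRows(
        rows=rows[offset : offset + limit], offset=offset, limit=limit, total=total
    )


# ---------------------------------------------------------------------------
# conditional incidence

@dataclass(frozen=True)
class IncidenceResult:
    """Conditional incidence of one cancer type given a gene variant.

    ``p_c_given_v`` is the direct count estimator n(V∧C)/n(V); ``p_bayes``
    recomputes it through the three-factor Bayes form
    P(V|C)·P(C)/P(V) — the two agree identically (up to float arithmetic)
    and both are exposed so results are auditable from the counts.
    """

    cancer_type: str
    count_v_and_c: int
    count_c: int
    count_v: int
    n_patients: int
    variant_observed: bool

    @property
    def p_c_given_v(self) -> Optional[float]:
        if not self.variant_observed or self.count_v == 0:
            return None
        return self.count_v_and_c / self.count_v

    @property
    def p_bayes(self) -> Optional[float]:
        # (n(V∧C)/n(C)) * (n(C)/n) / (n(V)/n)
        if not self.variant_observed or self.count_v == 0 or self.n_patients == 0:
            return None
        if self.count_c == 0:
            return 0.0
        p_v_given_c = self.count_v_and_c / self.count_c
        p_c = self.count_c / self.n_patients
        p_v = self.count_v / self.n_patients
        return p_v_given_c * p_c / p_v


def incidence(
    source: Source,
    gene_variant: str,
    cancer_labels: Optional[list[str]] = None,
    hgvs: Optional[str] = None,
) -> list[IncidenceResult]:
    """Per-cancer-type conditional probability given a gene variant.

    Probabilities are computed over distinct patients: a patient with two
    variants of the same gene counts once, and a patient contributes to every
    cancer type they carry a mapped diagnosis for.  ``gene_variant`` is a
    gene symbol (the calculator's granularity); pass ``hgvs`` to restrict to
    one exact DNA change.  A gene with zero carriers yields not-observed
    results, never a division error.
    """
    labels = cancer_labels if cancer_labels is not None else [a for a, _ in tcga_labels()]
    if not labels:
        raise ValueError("cancer_labels must be non-empty")
    view = _view(source)
    code_to_label = phecode_to_label()
    n = len(view.patients)
    carriers = view.carriers(gene_variant, hgvs)
    observed = len(carriers) > 0

    patients_by_label: dict[str, set[str]] = {}
    for p in view.patients:
        for d in view.diagnoses_of(p):
            label = code_to_label.get(d.code)
            if label is not None:
                patients_by_label.setdefault(label, set()).add(p.resource_id)

    results = []
    for label in labels:
        with_c = patients_by_label.get(label, set())
        results.append(
            IncidenceResult(
                cancer_type=label,
                count_v_and_c=len(carriers & with_c),
                count_c=len(with_c),
                count_v=len(carriers),
                n_patients=n,
                variant_observed=observed,
            )
        )
    results.sort(key=lambda r: (-(r.p_c_given_v or 0.0), r.cancer_type))
    return results


def incidence_report(source: Source, gene: str) -> list[IncidenceResult]:
    """Ranked conditional incidence of all 33 cancer types for one gene."""
    return incidence(source, gene, cancer_labels=[a for a, _ in tcga_labels()])
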