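"""Synthetic Clarity-style oncology EHR extracts.

Generates the five related tables an analytical EHR export would contain —
patients, Phecode-coded cancer diagnoses, genomic test reports, gene-variant
observations and specimens — with the statistical structure the downstream
pipeline and analytics assume:

* referential integrity across all foreign keys;
* per-field missingness at a configurable Bernoulli rate;
* diagnosis frequencies conditional on carried genes: for a patient carrying
  gene *g*, a diagnosis with Phecode *c* configured in ``diagnosis_model[g]``
  is drawn with exactly that conditional probability, and background
  diagnoses never reuse Phecodes configured for the patient's carried genes,
  so the configured value is recoverable as P(c | g);
* byte-identical output for identical (config, seed): one RNG stream per
  table, all derived from the single seed, so enlarging the cohort does not
  perturb the sampling order of other tables.

The CSV schema is a documented stand-in for a proprietary Clarity export:
fixed UTF-8 comma-separated columns, RFC-4180 quoting, empty cells for
absent values (distinct from the literal string ``"unknown"``).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field as dc_field, fields as dc_fields
from datetime import date, timedelta
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, field_validator

__all__ = [
    "CohortConfig",
    "PatientRow",
    "DiagnosisRow",
    "GenomicTestRow",
    "VariantRow",
    "SpecimenRow",
    "ClarityExtract",
    "ExtractError",
    "generate_cohort",
    "write_extract",
    "read_extract",
    "validate_extract",
    "default_genes",
    "default_phecodes",
]

EVENT_WINDOW = (date(2000, 1, 1), date(2020, 12, 31))
BIRTH_WINDOW = (date(1935, 1, 1), date(2005, 12, 31))

SEX_CODES = ["F", "M", "O", "U"]
SEX_P = [0.52, 0.46, 0.01, 0.01]
RACE_CODES = ["W", "B", "A", "N", "P", "U"]
RACE_P = [0.70, 0.15, 0.06, 0.01, 0.01, 0.07]
ETHNICITY_CODES = ["N", "H", "U"]
ETHNICITY_P = [0.85, 0.10, 0.05]
SPECIMEN_TYPES = ["TUMOR", "BLOOD", "SALIVA", "TISSUE"]
SPECIMEN_P = [0.60, 0.25, 0.05, 0.10]
CHANGE_TYPES = ["SNV", "DEL", "INS", "DUP", "DELINS"]
CHANGE_P = [0.70, 0.12, 0.08, 0.05, 0.05]
SIGNIFICANCE = [
    "Pathogenic", "Likely pathogenic", "Uncertain significance",
    "Likely benign", "Benign",
]
SIGNIFICANCE_P = [0.25, 0.15, 0.35, 0.15, 0.10]
SOURCE_CLASSES = ["somatic", "germline"]
SOURCE_P = [0.8, 0.2]

#: columns whose cells may be blanked by the missingness process
MASKABLE = {
    "patients": ("race", "ethnicity"),
    "variants": (
        "dna_change_type", "amino_acid_change",
        "allelic_frequency", "clinical_significance",
    ),
    "specimens": ("specimen_type",),
}

_AA3 = [
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
]


def default_genes() -> list[str]:
    """Packaged list of cancer gene symbols used by the generator."""
    text = resources.files("mcodekit.data").joinpath("cancer_genes.txt").read_text()
    return [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]


def default_phecodes() -> list[tuple[str, str]]:
    """Packaged (phecode, label) pairs for neoplasm diagnoses."""
    text = resources.files("mcodekit.data").joinpath("neoplasm_phecodes.tsv").read_text()
    rows = [ln.split("\t") for ln in text.strip().splitlines()[1:]]
    return [(r[0], r[1]) for r in rows]


class ExtractError(ValueError):
    """Schema or referential-integrity problem in an extract."""


class CohortConfig(BaseModel):
    """Parameters of one synthetic cohort.

    Same seed + config produces byte-identical CSV output.  The ``as_of``
    date anchors age computation downstream so results never depend on the
    wall clock.
    """

    n_patients: int = Field(ge=0)
    genes: list[str] = Field(default_factory=default_genes, min_length=1)
    cancer_phecodes: list[tuple[str, str]] = Field(
        default_factory=default_phecodes, min_length=1
    )
    variant_rate: float = Field(default=2.0, ge=0)
    reports_per_patient: int = Field(default=1, ge=1)
    diagnosis_model: dict[str, dict[str, float]] = Field(default_factory=dict)
    background_diagnosis_rate: float = Field(default=0.9, ge=0)
    missingness: float = Field(default=0.1, ge=0.0, le=1.0)
    seed: int = 0
    as_of: str = "2021-01-01"

    @field_validator("diagnosis_model")
    @classmethod
    def _weights_are_probabilities(cls, v):
        for gene, per_cancer in v.items():
            for phecode, w in per_cancer.items():
                if not 0.0 <= w <= 1.0:
                    raise ValueError(
                        f"diagnosis_model[{gene!r}][{phecode!r}] = {w} "
                        "is not a probability in [0,1]"
                    )
        return v

    @field_validator("as_of")
    @classmethod
    def _as_of_is_date(cls, v):
        date.fromisoformat(v)
        return v


@dataclass(frozen=True)
class PatientRow:
    patient_id: str
    birth_date: str
    sex: str
    race: Optional[str]
    ethnicity: Optional[str]


@dataclass(frozen=True)
class DiagnosisRow:
    patient_id: str
    phecode: str
    label: str
    onset_date: str


@dataclass(frozen=True)
class GenomicTestRow:
    report_id: str
    patient_id: str
    specimen_id: str
    test_date: str
    regions_studied: tuple[str, ...]


@dataclass(frozen=True)
class VariantRow:
    report_id: str
    gene_symbol: str
    dna_change: str
    dna_change_type: Optional[str]
    genomic_source_class: str
    amino_acid_change: Optional[str]
    allelic_frequency: Optional[float]
    clinical_significance: Optional[str]


@dataclass(frozen=True)
class SpecimenRow:
    specimen_id: str
    patient_id: str
    specimen_type: Optional[str]
    collected_date: str


@dataclass
class ClarityExtract:
    """The five related tables of one Clarity-style export."""

    patients: list[PatientRow] = dc_field(default_factory=list)
    diagnoses: list[DiagnosisRow] = dc_field(default_factory=list)
    reports: list[GenomicTestRow] = dc_field(default_factory=list)
    variants: list[VariantRow] = dc_field(default_factory=list)
    specimens: list[SpecimenRow] = dc_field(default_factory=list)

    def table(self, name: str) -> list:
        return getattr(self, name)


TABLE_COLUMNS = {
    "patients": ("patient_id", "birth_date", "sex", "race", "ethnicity"),
    "diagnoses": ("patient_id", "phecode", "label", "onset_date"),
    "reports": ("report_id", "patient_id", "specimen_id", "test_date", "regions_studied"),
    "variants": (
        "report_id", "gene_symbol", "dna_change", "dna_change_type",
        "genomic_source_class", "amino_acid_change", "allelic_frequency",
        "clinical_significance",
    ),
    "specimens": ("specimen_id", "patient_id", "specimen_type", "collected_date"),
}
_ROW_TYPES = {
    "patients": PatientRow, "diagnoses": DiagnosisRow, "reports": GenomicTestRow,
    "variants": VariantRow, "specimens": SpecimenRow,
}


# ---------------------------------------------------------------------------
# generation

def _rand_date(rng: np.random.Generator, window: tuple[date, date]) -> str:
    lo, hi = window
    span = (hi - lo).days
    return (lo + timedelta(days=int(rng.integers(0, span + 1)))).isoformat()


def _hgvs_c(rng: np.random.Generator, change_type: str) -> str:
    pos = int(rng.integers(1, 5001))
    bases = "ACGT"
    if change_type == "SNV":
        ref, alt = rng.choice(list(bases), size=2, replace=False)
        return f"c.{pos}{ref}>{alt}"
    if change_type == "DEL":
        return f"c.{pos}_{pos + int(rng.integers(1, 10))}del"
    if change_type == "INS":
        ins = "".join(rng.choice(list(bases), size=int(rng.integers(1, 6))))
        return f"c.{pos}_{pos + 1}ins{ins}"
    if change_type == "DUP":
        return f"c.{pos}_{pos + int(rng.integers(1, 6))}dup"
    ins = "".join(rng.choice(list(bases), size=int(rng.integers(1, 4))))
    return f"c.{pos}_{pos + int(rng.integers(1, 6))}delins{ins}"


def _hgvs_p(rng: np.random.Generator) -> str:
    a, b = rng.choice(len(_AA3), size=2, replace=False)
    return f"p.{_AA3[a]}{int(rng.integers(1, 1200))}{_AA3[b]}"


def generate_cohort(config: CohortConfig) -> ClarityExtract:
    """Generate a referentially closed synthetic extract from ``config``.

    Deterministic: the single seed spawns one child RNG stream per table
    (patients, reports+variants, diagnoses, missingness), so two runs with
    the same config are identical row for row.
    """
    ss = np.random.SeedSequence(config.seed)
    s_pat, s_rep, s_var, s_dx, s_miss = [np.random.default_rng(c) for c in ss.spawn(5)]

    extract = ClarityExtract()
    carried: dict[str, set[str]] = {}

    for i in range(config.n_patients):
        pid = f"MRN{100000 + i}"
        extract.patients.append(
            PatientRow(
                patient_id=pid,
                birth_date=_rand_date(s_pat, BIRTH_WINDOW),
                sex=str(s_pat.choice(SEX_CODES, p=SEX_P)),
                race=str(s_pat.choice(RACE_CODES, p=RACE_P)),
                ethnicity=str(s_pat.choice(ETHNICITY_CODES, p=ETHNICITY_P)),
            )
        )
        carried[pid] = set()

    # reports, specimens (1:1 with reports) and variants
    k = 0
    for i in range(config.n_patients):
        pid = f"MRN{100000 + i}"
        for _ in range(config.reports_per_patient):
            rid, sid = f"GR{1000000 + k}", f"SP{1000000 + k}"
            k += 1
            n_var = int(s_var.poisson(config.variant_rate))
            var_genes = []
            for ordinal in range(n_var):
                gene = str(s_var.choice(config.genes))
                var_genes.append(gene)
                carried[pid].add(gene)
                ct = str(s_var.choice(CHANGE_TYPES, p=CHANGE_P))
                extract.variants.append(
                    VariantRow(
                        report_id=rid,
                        gene_symbol=gene,
                        dna_change=_hgvs_c(s_var, ct),
                        dna_change_type=ct,
                        genomic_source_class=str(s_var.choice(SOURCE_CLASSES, p=SOURCE_P)),
                        amino_acid_change=_hgvs_p(s_var),
                        allelic_frequency=round(float(s_var.uniform(0.02, 0.98)), 4),
                        clinical_significance=str(
                            s_var.choice(SIGNIFICANCE, p=SIGNIFICANCE_P)
                        ),
                    )
                )
            # panel regions: the variant genes plus a couple of extras;
            # ~10% of reports carry no region information at all
            if s_rep.random() < 0.10:
                regions: tuple[str, ...] = ()
            else:
                extras = {
                    str(g) for g in s_rep.choice(config.genes, size=2, replace=False)
                } if len(config.genes) >= 2 else set()
                regions = tuple(sorted(set(var_genes) | extras))
            extract.reports.append(
                GenomicTestRow(
                    report_id=rid, patient_id=pid, specimen_id=sid,
                    test_date=_rand_date(s_rep, EVENT_WINDOW),
                    regions_studied=regions,
                )
            )
            extract.specimens.append(
                SpecimenRow(
                    specimen_id=sid, patient_id=pid,
                    specimen_type=str(s_rep.choice(SPECIMEN_TYPES, p=SPECIMEN_P)),
                    collected_date=_rand_date(s_rep, EVENT_WINDOW),
                )
            )

    # diagnoses: gene-conditional draws first, then background draws over the
    # remaining Phecodes (so configured P(c|g) is exact, not inflated)
    all_codes = {c: lbl for c, lbl in config.cancer_phecodes}
    for i in range(config.n_patients):
        pid = f"MRN{100000 + i}"
        assigned: set[str] = set()
        excluded: set[str] = set()
        for gene in sorted(carried[pid] & set(config.diagnosis_model)):
            for phecode in sorted(config.diagnosis_model[gene]):
                w = config.diagnosis_model[gene][phecode]
                excluded.add(phecode)
                if phecode not in assigned and s_dx.random() < w:
                    assigned.add(phecode)
        pool = [c for c in all_codes if c not in excluded]
        n_bg = int(s_dx.poisson(config.background_diagnosis_rate))
        if n_bg > 0 and pool:
            picks = s_dx.choice(len(pool), size=min(n_bg, len(pool)), replace=False)
            assigned.update(pool[int(j)] for j in picks)
        for phecode in sorted(assigned):
            extract.diagnoses.append(
                DiagnosisRow(
                    patient_id=pid, phecode=phecode,
                    label=all_codes.get(phecode, phecode),
                    onset_date=_rand_date(s_dx, EVENT_WINDOW),
                )
            )

    _apply_missingness(extract, config.missingness, s_miss)
    validate_extract(extract)
    return extract


def _apply_missingness(
    extract: ClarityExtract, p: float, rng: np.random.Generator
) -> None:
    if p <= 0:
        return
    for table, columns in MASKABLE.items():
        rows = extract.table(table)
        if not rows:
            continue
        mask = rng.random(size=(len(rows), len(columns))) < p
        for i, row in enumerate(rows):
            blanks = {c: None for j, c in enumerate(columns) if mask[i, j]}
            if blanks:
                rows[i] = _replace_frozen(row, blanks)


def _replace_frozen(row, updates):
    values = {f.name: getattr(row, f.name) for f in dc_fields(row)}
    values.update(updates)
    return type(row)(**values)


# ---------------------------------------------------------------------------
# validation and CSV I/O

def validate_extract(extract: ClarityExtract) -> None:
    """Check uniqueness and referential closure; raises :class:`ExtractError`."""
    pids = [r.patient_id for r in extract.patients]
    if len(pids) != len(set(pids)):
        dup = sorted({p for p in pids if pids.count(p) > 1})[0]
        raise ExtractError(f"duplicate patient_id {dup!r} in patients")
    pid_set = set(pids)
    rids = [r.report_id for r in extract.reports]
    if len(rids) != len(set(rids)):
        dup = sorted({r for r in rids if rids.count(r) > 1})[0]
        raise ExtractError(f"duplicate report_id {dup!r} in reports")
    sids = [s.specimen_id for s in extract.specimens]
    if len(sids) != len(set(sids)):
        dup = sorted({s for s in sids if sids.count(s) > 1})[0]
        raise ExtractError(f"duplicate specimen_id {dup!r} in specimens")
    sid_set, rid_set = set(sids), set(rids)

    for d in extract.diagnoses:
        if d.patient_id not in pid_set:
            raise ExtractError(
                f"diagnoses row references unknown patient_id {d.patient_id!r}"
            )
    for r in extract.reports:
        if r.patient_id not in pid_set:
            raise ExtractError(
                f"reports row {r.report_id!r} references unknown patient_id "
                f"{r.patient_id!r}"
            )
        if r.specimen_id not in sid_set:
            raise ExtractError(
                f"reports row {r.report_id!r} references unknown specimen_id "
                f"{r.specimen_id!r}"
            )
    for v in extract.variants:
        if v.report_id not in rid_set:
            raise ExtractError(
                f"variants row references unknown report_id {v.report_id!r}"
            )
        if v.allelic_frequency is not None and not 0 <= v.allelic_frequency <= 1:
            raise ExtractError(
                f"variants row in {v.report_id!r}: allelic_frequency "
                f"{v.allelic_frequency} outside [0,1]"
            )
    for s in extract.specimens:
        if s.patient_id not in pid_set:
            raise ExtractError(
                f"specimens row {s.specimen_id!r} references unknown patient_id "
                f"{s.patient_id!r}"
            )


def _cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, tuple):
        return "|".join(value)
    return str(value)


def write_extract(extract: ClarityExtract, directory) -> dict[str, int]:
    """Write the five CSV files; returns a manifest {filename: data rows}."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, int] = {}
    for table, columns in TABLE_COLUMNS.items():
        path = directory / f"{table}.csv"
        try:
            with open(path, "w", encoding="utf-8", newline="") as fh:
                writer = csv.writer(fh, lineterminator="\n")
                writer.writerow(columns)
                n = 0
                for row in extract.table(table):
                    writer.writerow([_cell(getattr(row, c)) for c in columns])
                    n += 1
        except OSError as exc:
            raise ExtractError(f"cannot write {path}: {exc}") from exc
        manifest[f"{table}.csv"] = n
    return manifest


def _parse_cell(table: str, column: str, raw: str):
    if raw == "":
        return () if column == "regions_studied" else None
    if column == "regions_studied":
        return tuple(raw.split("|"))
    if column == "allelic_frequency":
        return float(raw)
    return raw


def read_extract(directory) -> ClarityExtract:
    """Read and validate an extract directory written by :func:`write_extract`.

    Strict schema: a missing file, an unknown or missing column, or a dangling
    foreign key is an error naming the offender.  Empty cells become absent
    values.
    """
    directory = Path(directory)
    extract = ClarityExtract()
    for table, columns in TABLE_COLUMNS.items():
        path = directory / f"{table}.csv"
        if not path.exists():
            raise ExtractError(f"missing extract file: {path}")
        with open(path, encoding="utf-8", newline="") as fh:
            reader = csv.reader(fh)
            try:
                header = tuple(next(reader))
            except StopIteration:
                raise ExtractError(f"{path} is empty (expected a header row)") from None
            unknown = [c for c in header if c not in columns]
            if unknown:
                raise ExtractError(
                    f"{table}.csv: unrecognized column {unknown[0]!r}"
                )
            missing = [c for c in columns if c not in header]
            if missing:
                raise ExtractError(f"{table}.csv: missing column {missing[0]!r}")
            if header != columns:
                raise ExtractError(
                    f"{table}.csv: columns out of order; expected {list(columns)}"
                )
            rowtype = _ROW_TYPES[table]
            for lineno, raw in enumerate(reader, 2):
                if len(raw) != len(columns):
                    raise ExtractError(
                        f"{table}.csv line {lineno}: expected {len(columns)} cells, "
                        f"got {len(raw)}"
                    )
                values = {
                    c: _parse_cell(table, c, cell) for c, cell in zip(columns, raw)
                }
                extract.table(table).append(rowtype(**values))
    validate_extract(extract)
    return extract
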