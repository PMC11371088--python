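"""Three-step ETL: extract rows, transform to mCODE profiles, load the store.

Transformation is rule-driven: a versioned mapping table (shipped as a data
file, because reconciling source and mCODE naming conventions is inherently
manual work) maps each extract column onto one profile field and translates
source code values into the target code systems.  Must-support fields with an
empty source cell receive a dataAbsentReason placeholder; source data with no
mCODE home (Phecode diagnoses) is attached as extensions of the related
profile.  Row-level errors never abort a cohort: they are collected with row
coordinates and clean rows are transformed (partial-failure contract).

Every populated source cell is tracked in a provenance map, so the
field-level audit can prove there is no silent data loss, and loading is
batched and concurrency-safe: the final store state is independent of the
number of workers and of the batch size.
"""

from __future__ import annotations

import json
import math
import time
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field as dc_field
from importlib import resources
from pathlib import Path
from typing import Any, Optional, Sequence

from .profiles import (
    CodedValue,
    DataAbsentReason,
    McodeProfile,
    ProfileBundle,
    ValidationReport,
)
from .registry import (
    DEFAULT_ABSENT_REASON,
    DEFAULT_EXTENSION_NAMESPACE,
    PHECODE_SYSTEM,
    kind_registry,
    kind_spec,
)
from .store import EavStore
from .synthetic import (
    ClarityExtract,
    DiagnosisRow,
    GenomicTestRow,
    PatientRow,
    SpecimenRow,
    VariantRow,
    validate_extract,
)

__all__ = [
    "MappingTable",
    "TransformError",
    "TransformResult",
    "RowError",
    "LoadReport",
    "AuditReport",
    "transform_patient",
    "transform_report_group",
    "transform_cohort",
    "load_bundle",
    "audit_transform",
    "patient_resource_id",
    "report_resource_id",
    "variant_resource_id",
    "region_resource_id",
    "specimen_resource_id",
]


class TransformError(ValueError):
    """A source value that cannot be translated or a row that is inconsistent."""


# deterministic resource ids derived from source ids: re-runs are idempotent
# upserts, never duplicates
def patient_resource_id(patient_id: str) -> str:
    return f"pat:{patient_id}"

def report_resource_id(report_id: str) -> str:
    return f"rep:{report_id}"

def variant_resource_id(report_id: str, ordinal: int) -> str:
    return f"var:{report_id}:{ordinal}"

def region_resource_id(report_id: str) -> str:
    return f"reg:{report_id}"

def specimen_resource_id(specimen_id: str) -> str:
    return f"spe:{specimen_id}"


class MappingTable:
    """Ordered column-to-field rules plus per-column value translations.

    Invariant (checked on load): every must-support field of every kind is
    the target of exactly one rule, or listed in the explicit no-source list
    (in which case it always receives a dataAbsentReason).
    """

    def __init__(self, spec: dict[str, Any]):
        self.version: str = spec.get("version", "0")
        self.rules: list[dict[str, str]] = list(spec["rules"])
        self.translations: dict[str, dict[str, Any]] = dict(spec.get("translations", {}))
        self.no_source: list[str] = list(spec.get("no_source", []))
        self._check_coverage()

    @classmethod
    def default(cls) -> "MappingTable":
        raw = json.loads(
            resources.files("mcodekit.data").joinpath("mapping.json").read_text()
        )
        return cls(raw)

    @classmethod
    def from_file(cls, path: str | Path) -> "MappingTable":
        return cls(json.loads(Path(path).read_text()))

    def _check_coverage(self) -> None:
        targets: dict[tuple[str, str], int] = {}
        for rule in self.rules:
            key = (rule["kind"], rule["field"])
            kind_spec(rule["kind"]).field(rule["field"])  # raises on unknown
            targets[key] = targets.get(key, 0) + 1
        for kind, kspec in kind_registry().items():
            for name in kspec.must_support_fields:
                n = targets.get((kind, name), 0)
                listed = f"{kind}.{name}" in self.no_source
                if n == 0 and not listed:
                    raise ValueError(
                        f"mapping table covers no source for must-support field "
                        f"{kind}.{name} and it is not in the no-source list"
                    )
                if n > 1:
                    raise ValueError(
                        f"mapping table maps {kind}.{name} from {n} rules; expected one"
                    )

    def translate(self, table: str, column: str, value: str) -> Any:
        """Translate one source value; raises naming value and column."""
        tmap = self.translations.get(f"{table}.{column}")
        if tmap is None:
            return value
        if value not in tmap:
            raise TransformError(
                f"untranslatable value {value!r} in column {table}.{column}"
            )
        return tmap[value]


def _coded(mapping: MappingTable, table: str, column: str, kind: str,
           field_name: str, raw: str) -> CodedValue:
    system = kind_spec(kind).field(field_name).system
    translated = mapping.translate(table, column, raw)
    if isinstance(translated, list):
        code, display = translated
        return CodedValue(system=system, code=code, display=display)
    return CodedValue(system=system, code=translated, display=translated)


# ---------------------------------------------------------------------------
# per-row transforms

def transform_patient(
    row: PatientRow,
    mapping: Optional[MappingTable] = None,
    diagnoses: Sequence[DiagnosisRow] = (),
    namespace: str = DEFAULT_EXTENSION_NAMESPACE,
) -> McodeProfile:
    """One patient row (plus their Phecode diagnoses) to a CancerPatient profile.

    Populated cells are translated through the mapping; empty must-support
    cells get a dataAbsentReason.  Diagnoses, which have no field in the five
    implemented kinds, are attached as namespaced extensions (code and onset
    date per diagnosis); duplicated Phecodes are rejected upstream.
    """
    mapping = mapping or MappingTable.default()
    fields: dict[str, Any] = {}
    absent: list[DataAbsentReason] = []

    if row.birth_date:
        fields["birth_date"] = row.birth_date
    else:
        absent.append(DataAbsentReason("birth_date", DEFAULT_ABSENT_REASON))
    for col, fname in (("sex", "sex"), ("race", "race"), ("ethnicity", "ethnicity")):
        raw = getattr(row, col)
        if raw:
            fields[fname] = mapping.translate("patients", col, raw)
        else:
            absent.append(DataAbsentReason(fname, DEFAULT_ABSENT_REASON))

    profile = McodeProfile(
        kind="CancerPatient",
        resource_id=patient_resource_id(row.patient_id),
        fields=fields,
        absent_reasons=absent,
    )
    seen: set[str] = set()
    for d in diagnoses:
        if d.phecode in seen:
            raise TransformError(
                f"duplicate diagnosis phecode {d.phecode!r} for patient "
                f"{row.patient_id!r}"
            )
        seen.add(d.phecode)
        profile.extensions.append(
            _diagnosis_extension(d, namespace)
        )
        if d.onset_date:
            profile.extensions.append(
                _onset_extension(d, namespace)
            )
    profile.extensions.sort(key=lambda e: e.url)
    return profile


def _diagnosis_extension(d: DiagnosisRow, namespace: str):
    from .profiles import ExtensionValue

    return ExtensionValue(
        url=f"{namespace}diagnosis/{d.phecode}",
        value=CodedValue(system=PHECODE_SYSTEM, code=d.phecode, display=d.label),
        anchor_path="resource",
    )


def _onset_extension(d: DiagnosisRow, namespace: str):
    from .profiles import ExtensionValue

    return ExtensionValue(
        url=f"{namespace}diagnosis/{d.phecode}/onset",
        value=d.onset_date,
        anchor_path="resource",
    )


def _transform_variant(
    v: VariantRow, ordinal: int, subject: str, mapping: MappingTable
) -> McodeProfile:
    fields: dict[str, Any] = {}
    absent: list[DataAbsentReason] = []

    def coded_or_absent(column: str, fname: str, raw: Optional[str]) -> None:
        if raw:
            fields[fname] = _coded(mapping, "variants", column, "GenomicVariant", fname, raw)
        else:
            absent.append(DataAbsentReason(fname, DEFAULT_ABSENT_REASON))

    coded_or_absent("gene_symbol", "gene", v.gene_symbol)
    coded_or_absent("dna_change", "dna_change", v.dna_change)
    coded_or_absent("dna_change_type", "dna_change_type", v.dna_change_type)
    coded_or_absent("genomic_source_class", "genomic_source_class", v.genomic_source_class)
    coded_or_absent("amino_acid_change", "amino_acid_change", v.amino_acid_change)
    coded_or_absent("clinical_significance", "clinical_significance", v.clinical_significance)
    if v.allelic_frequency is not None:
        fields["allelic_frequency"] = float(v.allelic_frequency)
    else:
        absent.append(DataAbsentReason("allelic_frequency", DEFAULT_ABSENT_REASON))

    return McodeProfile(
        kind="GenomicVariant",
        resource_id=variant_resource_id(v.report_id, ordinal),
        subject_ref=subject,
        fields=fields,
        absent_reasons=absent,
    )


def transform_report_group(
    report: GenomicTestRow,
    variants: Sequence[VariantRow],
    specimen: SpecimenRow,
    mapping: Optional[MappingTable] = None,
) -> ProfileBundle:
    """One genomic test and its satellite rows to a bundle fragment.

    Produces exactly 1 GenomicsReport + |variants| GenomicVariant +
    1 GenomicRegionStudied (when regions_studied is non-empty) +
    1 GenomicSpecimen; the report's result_refs list every variant id.
    """
    mapping = mapping or MappingTable.default()
    for v in variants:
        if v.report_id != report.report_id:
            raise TransformError(
                f"variant for report {v.report_id!r} grouped under report "
                f"{report.report_id!r}"
            )
    if specimen.specimen_id != report.specimen_id:
        raise TransformError(
            f"specimen {specimen.specimen_id!r} does not match report "
            f"{report.report_id!r} (expects {report.specimen_id!r})"
        )
    if specimen.patient_id != report.patient_id:
        raise TransformError(
            f"specimen {specimen.specimen_id!r} belongs to patient "
            f"{specimen.patient_id!r}, report to {report.patient_id!r}"
        )
    subject = patient_resource_id(report.patient_id)

    bundle = ProfileBundle()
    variant_profiles = [
        _transform_variant(v, i, subject, mapping) for i, v in enumerate(variants)
    ]

    rep_fields: dict[str, Any] = {}
    rep_absent: list[DataAbsentReason] = []
    if report.test_date:
        rep_fields["test_date"] = report.test_date
    else:
        rep_absent.append(DataAbsentReason("test_date", DEFAULT_ABSENT_REASON))
    rep_fields["specimen_ref"] = specimen_resource_id(report.specimen_id)
    if variant_profiles:
        rep_fields["result_refs"] = [p.resource_id for p in variant_profiles]
    if report.regions_studied:
        rep_fields["region_refs"] = [region_resource_id(report.report_id)]
    bundle.append(
        McodeProfile(
            kind="GenomicsReport",
            resource_id=report_resource_id(report.report_id),
            subject_ref=subject,
            fields=rep_fields,
            absent_reasons=rep_absent,
        )
    )
    bundle.extend(variant_profiles)
    if report.regions_studied:
        bundle.append(
            McodeProfile(
                kind="GenomicRegionStudied",
                resource_id=region_resource_id(report.report_id),
                subject_ref=subject,
                fields={"genes": list(report.regions_studied)},
            )
        )
    bundle.append(_transform_specimen(specimen, mapping))
    bundle.validate(complete=False)
    return bundle


def _transform_specimen(specimen: SpecimenRow, mapping: MappingTable) -> McodeProfile:
    fields: dict[str, Any] = {}
    absent: list[DataAbsentReason] = []
    if specimen.specimen_type:
        fields["specimen_type"] = _coded(
            mapping, "specimens", "specimen_type", "GenomicSpecimen",
            "specimen_type", specimen.specimen_type,
        )
    else:
        absent.append(DataAbsentReason("specimen_type", DEFAULT_ABSENT_REASON))
    if specimen.collected_date:
        fields["collected_date"] = specimen.collected_date
    else:
        absent.append(DataAbsentReason("collected_date", DEFAULT_ABSENT_REASON))
    return McodeProfile(
        kind="GenomicSpecimen",
        resource_id=specimen_resource_id(specimen.specimen_id),
        subject_ref=patient_resource_id(specimen.patient_id),
        fields=fields,
        absent_reasons=absent,
    )


# ---------------------------------------------------------------------------
# cohort transform with provenance

@dataclass(frozen=True)
class RowError:
    table: str
    row_index: int
    row_key: str
    message: str


@dataclass
class TransformResult:
    """Bundle plus collected row errors and cell-level provenance.

    ``provenance`` maps (table, row_index, column) of every populated source
    cell to its destination: ``("field", resource_id, field_name)``,
    ``("extension", resource_id, url)``, ``("id", resource_id)`` for cells
    consumed as identifiers/references, or ``("error", message)`` for cells
    of rows whose transformation failed (a logged, never silent, drop).
    """

    bundle: ProfileBundle
    errors: list[RowError] = dc_field(default_factory=list)
    provenance: dict[tuple[str, int, str], tuple] = dc_field(default_factory=dict)


def transform_cohort(
    extract: ClarityExtract,
    mapping: Optional[MappingTable] = None,
    namespace: str = DEFAULT_EXTENSION_NAMESPACE,
) -> TransformResult:
    """Transform a whole extract; pure function of (extract, mapping).

    Bundle size is P + R + V + G + S (patients, reports, variant rows,
    reports with non-empty regions, specimens) minus any rows that failed
    with a collected error.  Specimens never referenced by a report are
    transformed as orphans.
    """
    mapping = mapping or MappingTable.default()
    validate_extract(extract)
    result = TransformResult(bundle=ProfileBundle())
    prov = result.provenance

    dx_by_patient: dict[str, list[tuple[int, DiagnosisRow]]] = {}
    for i, d in enumerate(extract.diagnoses):
        dx_by_patient.setdefault(d.patient_id, []).append((i, d))
    var_by_report: dict[str, list[tuple[int, VariantRow]]] = {}
    for i, v in enumerate(extract.variants):
        var_by_report.setdefault(v.report_id, []).append((i, v))
    spec_by_id = {s.specimen_id: (i, s) for i, s in enumerate(extract.specimens)}

    def mark_row_error(table: str, idx: int, row, key: str, msg: str) -> None:
        result.errors.append(RowError(table, idx, key, msg))
        for col in _populated_columns(table, row):
            prov[(table, idx, col)] = ("error", msg)

    # patients (and their diagnoses)
    for i, row in enumerate(extract.patients):
        diags = dx_by_patient.get(row.patient_id, [])
        try:
            profile = transform_patient(
                row, mapping, [d for _, d in diags], namespace
            )
        except TransformError as exc:
            mark_row_error("patients", i, row, row.patient_id, str(exc))
            for j, d in diags:
                for col in _populated_columns("diagnoses", d):
                    prov[("diagnoses", j, col)] = ("error", str(exc))
            continue
        result.bundle.append(profile)
        rid = profile.resource_id
        prov[("patients", i, "patient_id")] = ("id", rid)
        for col, fname in (("birth_date", "birth_date"), ("sex", "sex"),
                           ("race", "race"), ("ethnicity", "ethnicity")):
            if getattr(row, col):
                prov[("patients", i, col)] = ("field", rid, fname)
        for j, d in diags:
            url = f"{namespace}diagnosis/{d.phecode}"
            prov[("diagnoses", j, "patient_id")] = ("id", rid)
            prov[("diagnoses", j, "phecode")] = ("extension", rid, url)
            prov[("diagnoses", j, "label")] = ("extension", rid, url)
            if d.onset_date:
                prov[("diagnoses", j, "onset_date")] = ("extension", rid, f"{url}/onset")

    # reports with their variants, regions and specimens
    consumed_specimens: set[str] = set()
    for i, report in enumerate(extract.reports):
        vars_here = var_by_report.get(report.report_id, [])
        si, specimen = spec_by_id[report.specimen_id]
        try:
            fragment = transform_report_group(
                report, [v for _, v in vars_here], specimen, mapping
            )
        except TransformError as exc:
            mark_row_error("reports", i, report, report.report_id, str(exc))
            for j, v in vars_here:
                for col in _populated_columns("variants", v):
                    prov[("variants", j, col)] = ("error", str(exc))
            continue
        consumed_specimens.add(report.specimen_id)
        result.bundle.extend(fragment.profiles)
        rep_rid = report_resource_id(report.report_id)
        prov[("reports", i, "report_id")] = ("id", rep_rid)
        prov[("reports", i, "patient_id")] = ("id", rep_rid)
        prov[("reports", i, "specimen_id")] = ("field", rep_rid, "specimen_ref")
        if report.test_date:
            prov[("reports", i, "test_date")] = ("field", rep_rid, "test_date")
        if report.regions_studied:
            prov[("reports", i, "regions_studied")] = (
                "field", region_resource_id(report.report_id), "genes"
            )
        for ordinal, (j, v) in enumerate(vars_here):
            var_rid = variant_resource_id(report.report_id, ordinal)
            prov[("variants", j, "report_id")] = ("id", var_rid)
            for col, fname in (
                ("gene_symbol", "gene"), ("dna_change", "dna_change"),
                ("dna_change_type", "dna_change_type"),
                ("genomic_source_class", "genomic_source_class"),
                ("amino_acid_change", "amino_acid_change"),
                ("allelic_frequency", "allelic_frequency"),
                ("clinical_significance", "clinical_significance"),
            ):
                if getattr(v, col) is not None and getattr(v, col) != "":
                    prov[("variants", j, col)] = ("field", var_rid, fname)
        spe_rid = specimen_resource_id(specimen.specimen_id)
        prov[("specimens", si, "specimen_id")] = ("id", spe_rid)
        prov[("specimens", si, "patient_id")] = ("id", spe_rid)
        if specimen.specimen_type:
            prov[("specimens", si, "specimen_type")] = ("field", spe_rid, "specimen_type")
        if specimen.collected_date:
            prov[("specimens", si, "collected_date")] = ("field", spe_rid, "collected_date")

    # orphan specimens (no report references them)
    for si, specimen in enumerate(extract.specimens):
        if specimen.specimen_id in consumed_specimens:
            continue
        try:
            profile = _transform_specimen(specimen, mapping)
        except TransformError as exc:
            mark_row_error("specimens", si, specimen, specimen.specimen_id, str(exc))
            continue
        result.bundle.append(profile)
        spe_rid = profile.resource_id
        prov[("specimens", si, "specimen_id")] = ("id", spe_rid)
        prov[("specimens", si, "patient_id")] = ("id", spe_rid)
        if specimen.specimen_type:
            prov[("specimens", si, "specimen_type")] = ("field", spe_rid, "specimen_type")
        if specimen.collected_date:
            prov[("specimens", si, "collected_date")] = ("field", spe_rid, "collected_date")

    if not result.errors:
        result.bundle.validate(complete=True)
    return result


def _populated_columns(table: str, row) -> list[str]:
    from .synthetic import TABLE_COLUMNS

    out = []
    for col in TABLE_COLUMNS[table]:
        v = getattr(row, col)
        if v is not None and v != "" and v != ():
            out.append(col)
    return out


# ---------------------------------------------------------------------------
# audit: no silent data loss

@dataclass
class AuditReport:
    """Cell-level conservation check over one transform.

    Every populated source cell must appear in exactly one profile field, one
    extension, one identifier/reference, or one logged drop; anything else is
    an unaccounted (silent) loss and fails the audit.
    """

    total_cells: int
    accounted: int
    logged_drops: int
    unaccounted: list[tuple[str, int, str]]

    @property
    def clean(self) -> bool:
        return not self.unaccounted


def audit_transform(
    extract: ClarityExtract,
    result: TransformResult,
    store: Optional[EavStore] = None,
) -> AuditReport:
    """Verify every populated source cell is recoverable from the transform.

    When ``store`` is given the destinations are additionally resolved
    against the loaded store, proving end-to-end recoverability after the
    load step as well.
    """
    by_id = result.bundle.by_id()

    def resolve(rid: str) -> Optional[McodeProfile]:
        if store is not None:
            return store.get(rid)
        return by_id.get(rid)

    total = accounted = drops = 0
    unaccounted: list[tuple[str, int, str]] = []
    from .synthetic import TABLE_COLUMNS

    for table in TABLE_COLUMNS:
        for idx, row in enumerate(result_rows(extract, table)):
            for col in _populated_columns(table, row):
                total += 1
                dest = result.provenance.get((table, idx, col))
                ok = False
                if dest is None:
                    pass
                elif dest[0] == "error":
                    drops += 1
                    ok = True
                elif dest[0] == "id":
                    ok = resolve(dest[1]) is not None
                elif dest[0] == "field":
                    p = resolve(dest[1])
                    ok = p is not None and dest[2] in p.fields
                elif dest[0] == "extension":
                    p = resolve(dest[1])
                    ok = p is not None and any(e.url == dest[2] for e in p.extensions)
                if ok:
                    accounted += 1
                else:
                    unaccounted.append((table, idx, col))
    return AuditReport(
        total_cells=total, accounted=accounted, logged_drops=drops,
        unaccounted=unaccounted,
    )


def result_rows(extract: ClarityExtract, table: str) -> list:
    return extract.table(table)


# ---------------------------------------------------------------------------
# load

@dataclass
class LoadReport:
    """Outcome of one bulk load; attempted = loaded + len(rejected)."""

    attempted: int
    loaded: int
    rejected: list[tuple[str, ValidationReport]]
    batches: int
    elapsed: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "attempted": self.attempted,
                "loaded": self.loaded,
                "rejected": [
                    {"resource_id": rid,
                     "findings": [list(f) for f in report.findings]}
                    for rid, report in self.rejected
                ],
                "batches": self.batches,
                "elapsed_seconds": round(self.elapsed, 3),
            },
            indent=2,
        )


def load_bundle(
    bundle: ProfileBundle,
    store: EavStore,
    batch_size: int = 500,
    workers: int = 1,
) -> LoadReport:
    """Validated, batched, concurrent bulk load into the store.

    Profiles are posted in ceil(n / batch_size) batches across ``workers``
    concurrent workers; because the store upserts by resource_id, the final
    store contents are identical for any workers/batch_size combination.
    Invalid profiles are rejected with their ValidationReport, never loaded.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    if workers < 1:
        raise ValueError("workers must be >= 1")
    profiles = list(bundle)
    n = len(profiles)
    batches = [profiles[i : i + batch_size] for i in range(0, n, batch_size)]
    assert len(batches) == (math.ceil(n / batch_size) if n else 0)
    t0 = time.perf_counter()
    loaded = 0
    rejected: list[tuple[str, ValidationReport]] = []

    def post(batch: list[McodeProfile]) -> tuple[int, list]:
        ok, bad = store.put_many(batch)
        return len(ok), bad

    if workers == 1 or len(batches) <= 1:
        results = [post(b) for b in batches]
    else:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            results = list(pool.map(post, batches))
    for ok, bad in results:
        loaded += ok
        rejected.extend(bad)
    return LoadReport(
        attempted=n, loaded=loaded, rejected=rejected,
        batches=len(batches), elapsed=time.perf_counter() - t0,
    )
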