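"""Data-driven registry of the implemented mCODE profile kinds.

The five kinds (CancerPatient, GenomicsReport, GenomicVariant,
GenomicRegionStudied, GenomicSpecimen), their must-support field sets, value
types, code systems and FHIR serialization slots are declared in
``data/profile_fields.json`` and loaded here once at import.  Validation,
EAV flattening and FHIR JSON emission are all driven off this table, so a
further kind can be added by editing the data file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Any, Optional

DATA_ABSENT_REASON_URL = "http://hl7.org/fhir/StructureDefinition/data-absent-reason"
DATA_ABSENT_REASON_SYSTEM = "http://terminology.hl7.org/CodeSystem/data-absent-reason"
#: Valid dataAbsentReason codes accepted on must-support fields.
ABSENT_REASON_CODES = frozenset({"unknown", "masked", "not-performed", "not-asked"})
#: Default reason when a source cell is simply empty.
DEFAULT_ABSENT_REASON = "unknown"

#: Base namespace for locally defined extensions (configurable per call site).
DEFAULT_EXTENSION_NAMESPACE = "urn:example:mcode-pilot:"

#: Code system URI used for Phecode diagnosis codes carried as extensions.
PHECODE_SYSTEM = "urn:example:phecode"

VALUE_TYPES = frozenset(
    {"date", "code", "coded", "fraction", "string", "ref", "ref_list", "code_list"}
)


@dataclass(frozen=True)
class FieldSpec:
    """One declared field of a profile kind."""

    name: str
    type: str
    must_support: bool
    slot: dict[str, Any]
    system: Optional[str] = None
    ref_type: Optional[str] = None


@dataclass(frozen=True)
class KindSpec:
    """One profile kind: FHIR resource type, canonical URL and field table."""

    kind: str
    resource_type: str
    profile_url: str
    has_subject: bool
    fields: tuple[FieldSpec, ...]
    fixed_code: Optional[dict[str, str]] = None  # Observation/DiagnosticReport code

    def field(self, name: str) -> FieldSpec:
        for f in self.fields:
            if f.name == name:
                return f
        raise KeyError(name)

    @property
    def field_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.fields)

    @property
    def must_support_fields(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.fields if f.must_support)


def _load() -> dict[str, KindSpec]:
    raw = json.loads(
        resources.files("mcodekit.data").joinpath("profile_fields.json").read_text()
    )
    kinds: dict[str, KindSpec] = {}
    for kind, spec in raw["kinds"].items():
        fields = []
        for f in spec["fields"]:
            if f["type"] not in VALUE_TYPES:
                raise ValueError(f"unknown value type {f['type']!r} for {kind}.{f['name']}")
            fields.append(
                FieldSpec(
                    name=f["name"],
                    type=f["type"],
                    must_support=bool(f["must_support"]),
                    slot=f["slot"],
                    system=f.get("system"),
                    ref_type=f.get("ref_type"),
                )
            )
        kinds[kind] = KindSpec(
            kind=kind,
            resource_type=spec["resource_type"],
            profile_url=spec["profile_url"],
            has_subject=bool(spec["has_subject"]),
            fields=tuple(fields),
            fixed_code=spec.get("observation_code") or spec.get("report_code"),
        )
    return kinds


@lru_cache(maxsize=1)
def kind_registry() -> dict[str, KindSpec]:
    """The registry of implemented profile kinds, keyed by kind name."""
    return _load()


def kind_spec(kind: str) -> KindSpec:
    try:
        return kind_registry()[kind]
    except KeyError:
        raise KeyError(f"unknown profile kind: {kind!r}") from None


def profile_url_to_kind(url: str) -> Optional[str]:
    for kind, spec in kind_registry().items():
        if spec.profile_url == url:
            return kind
    return None
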