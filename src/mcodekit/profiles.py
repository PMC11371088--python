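"""mCODE profile domain model, validation and FHIR R4 JSON serialization.

Implements the five profile kinds used by the pipeline — CancerPatient
(FHIR ``Patient``), GenomicsReport (``DiagnosticReport``), GenomicVariant and
GenomicRegionStudied (``Observation``), GenomicSpecimen (``Specimen``) — with
the mCODE must-support contract: every must-support field is either populated
or covered by exactly one dataAbsentReason placeholder.  Source data with no
mCODE home is carried as FHIR extensions anchored to a related field.

Serialization is canonical (UTF-8, sorted keys, no insignificant whitespace),
so structurally equal profiles produce byte-identical JSON, and
``from_fhir_json(to_fhir_json(p)) == p`` for every valid profile.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, replace
from datetime import date
from typing import Any, Iterable, Iterator, Optional, Union

from .registry import (
    ABSENT_REASON_CODES,
    DATA_ABSENT_REASON_SYSTEM,
    DATA_ABSENT_REASON_URL,
    DEFAULT_EXTENSION_NAMESPACE,
    FieldSpec,
    KindSpec,
    kind_registry,
    kind_spec,
    profile_url_to_kind,
)

__all__ = [
    "CodedValue",
    "DataAbsentReason",
    "ExtensionValue",
    "McodeProfile",
    "ProfileBundle",
    "ValidationReport",
    "Finding",
    "McodeError",
    "ProfileValidationError",
    "ProfileJSONError",
    "MalformedJsonError",
    "MissingProfileUrlError",
    "UnknownKindError",
    "BundleError",
    "validate_profile",
    "apply_data_absent_reason",
    "attach_extension",
    "to_fhir_json",
    "from_fhir_json",
    "write_bundle_ndjson",
    "read_bundle_ndjson",
]


# ---------------------------------------------------------------------------
# errors

class McodeError(Exception):
    """Base class for profile-layer errors."""


class ProfileValidationError(McodeError):
    """Raised when an operation requires a valid profile but validation failed."""

    def __init__(self, report: "ValidationReport", message: str = "profile is invalid"):
        self.report = report
        details = "; ".join(f"{f.field_path}: {f.message}" for f in report.errors())
        super().__init__(f"{message}: {details}" if details else message)


class ProfileJSONError(McodeError):
    """Base class for FHIR JSON parsing problems."""


class MalformedJsonError(ProfileJSONError):
    pass


class MissingProfileUrlError(ProfileJSONError):
    pass


class UnknownKindError(ProfileJSONError):
    pass


class BundleError(McodeError):
    pass


# ---------------------------------------------------------------------------
# value types

@dataclass(frozen=True)
class CodedValue:
    """A coded value: code-system URI, code, optional display text."""

    system: str
    code: str
    display: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.system or not self.code:
            raise ValueError("CodedValue requires non-empty system and code")


@dataclass(frozen=True)
class DataAbsentReason:
    """Placeholder explaining why a must-support field is unpopulated."""

    field_path: str
    reason_code: str = "unknown"


PrimitiveOrCoded = Union[str, int, float, bool, CodedValue]


@dataclass(frozen=True)
class ExtensionValue:
    """Extra source data carried as a FHIR extension on a related field.

    ``anchor_path`` names the declared profile field the extension relates to,
    or ``"resource"`` when it relates to the resource as a whole.
    """

    url: str
    value: PrimitiveOrCoded
    anchor_path: str = "resource"


Finding = tuple  # (severity, field_path, message)


@dataclass
class ValidationReport:
    """Outcome of must-support validation; ``valid`` iff no error findings."""

    findings: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not any(sev == "error" for sev, _, _ in self.findings)

    def errors(self) -> list["_F"]:
        return [_F(*f) for f in self.findings if f[0] == "error"]

    def add(self, severity: str, field_path: str, message: str) -> None:
        self.findings.append((severity, field_path, message))


@dataclass(frozen=True)
class _F:
    severity: str
    field_path: str
    message: str


# ---------------------------------------------------------------------------
# the profile

@dataclass
class McodeProfile:
    """One mCODE profile instance of any of the five implemented kinds.

    ``fields`` maps declared field names to values whose Python type follows
    the registry: ISO date strings, plain code strings, :class:`CodedValue`,
    floats for fractions, resource-id strings for references, and lists for
    reference/code lists.  Unpopulated fields are simply missing from the
    mapping (never ``None``).
    """

    kind: str
    resource_id: str
    subject_ref: Optional[str] = None
    fields: dict[str, Any] = field(default_factory=dict)
    absent_reasons: list[DataAbsentReason] = field(default_factory=list)
    extensions: list[ExtensionValue] = field(default_factory=list)

    def __post_init__(self) -> None:
        kind_spec(self.kind)  # raises on unknown kind
        # normalize: drop empty values, keep deterministic list order
        self.fields = {
            k: v for k, v in self.fields.items()
            if v is not None and v != "" and v != []
        }
        self.absent_reasons = sorted(self.absent_reasons, key=lambda a: a.field_path)
        self.extensions = sorted(self.extensions, key=lambda e: e.url)

    @property
    def spec(self) -> KindSpec:
        return kind_spec(self.kind)

    def clone(self) -> "McodeProfile":
        return McodeProfile(
            kind=self.kind,
            resource_id=self.resource_id,
            subject_ref=self.subject_ref,
            fields=copy.deepcopy(self.fields),
            absent_reasons=list(self.absent_reasons),
            extensions=list(self.extensions),
        )

    def absent_for(self, field_path: str) -> list[DataAbsentReason]:
        return [a for a in self.absent_reasons if a.field_path == field_path]


@dataclass
class ProfileBundle:
    """An ordered collection of profiles with unique, mutually resolvable ids."""

    profiles: list[McodeProfile] = field(default_factory=list)

    def __iter__(self) -> Iterator[McodeProfile]:
        return iter(self.profiles)

    def __len__(self) -> int:
        return len(self.profiles)

    def append(self, profile: McodeProfile) -> None:
        self.profiles.append(profile)

    def extend(self, profiles: Iterable[McodeProfile]) -> None:
        self.profiles.extend(profiles)

    def by_id(self) -> dict[str, McodeProfile]:
        return {p.resource_id: p for p in self.profiles}

    def validate(self, complete: bool = True) -> None:
        """Check id uniqueness and, when ``complete``, reference resolution.

        ``complete=False`` is used for bundle fragments (e.g. one report group)
        whose subject patient lives elsewhere.
        """
        seen: dict[str, str] = {}
        for p in self.profiles:
            if p.resource_id in seen:
                raise BundleError(f"duplicate resource_id in bundle: {p.resource_id!r}")
            seen[p.resource_id] = p.kind
        if not complete:
            return
        for p in self.profiles:
            for ref, what in _outgoing_refs(p):
                if ref not in seen:
                    raise BundleError(
                        f"{p.resource_id}: {what} reference {ref!r} does not resolve"
                    )
                if what == "result_refs" and seen[ref] != "GenomicVariant":
                    raise BundleError(
                        f"{p.resource_id}: result_refs must reference GenomicVariant "
                        f"profiles, got {seen[ref]} for {ref!r}"
                    )


def _outgoing_refs(p: McodeProfile) -> list[tuple[str, str]]:
    out = []
    if p.subject_ref is not None:
        out.append((p.subject_ref, "subject"))
    for fs in p.spec.fields:
        v = p.fields.get(fs.name)
        if v is None:
            continue
        if fs.type == "ref":
            out.append((v, fs.name))
        elif fs.type == "ref_list":
            out.extend((r, fs.name) for r in v)
    return out


# ---------------------------------------------------------------------------
# validation

def _is_iso_date(v: Any) -> bool:
    if not isinstance(v, str):
        return False
    try:
        date.fromisoformat(v)
        return True
    except ValueError:
        return False


def _check_value(fs: FieldSpec, v: Any, report: ValidationReport) -> None:
    t = fs.type
    if t == "date" and not _is_iso_date(v):
        report.add("error", fs.name, f"expected ISO date, got {v!r}")
    elif t in ("code", "string", "ref") and not (isinstance(v, str) and v):
        report.add("error", fs.name, f"expected non-empty string, got {v!r}")
    elif t == "coded" and not isinstance(v, CodedValue):
        report.add("error", fs.name, f"expected CodedValue, got {type(v).__name__}")
    elif t == "fraction":
        if not isinstance(v, (int, float)) or isinstance(v, bool):
            report.add("error", fs.name, f"expected number, got {type(v).__name__}")
        elif not 0.0 <= float(v) <= 1.0:
            report.add("error", fs.name, f"fraction out of range [0,1]: {v!r}")
    elif t == "ref_list" and not (
        isinstance(v, list) and all(isinstance(r, str) and r for r in v)
    ):
        report.add("error", fs.name, "expected list of resource-id strings")
    elif t == "code_list" and not (
        isinstance(v, list) and all(isinstance(c, str) and c for c in v)
    ):
        report.add("error", fs.name, "expected list of code strings")


def validate_profile(profile: McodeProfile) -> ValidationReport:
    """Validate the must-support contract of one profile.

    Every must-support field must be populated or covered by exactly one
    dataAbsentReason; populated values are shape-checked against the registry
    (codes are not checked for terminology membership).  Extensions never
    cause findings.  The check is pure: the profile is not modified.
    """
    report = ValidationReport()
    spec = profile.spec
    declared = set(spec.field_names)

    for name in profile.fields:
        if name not in declared:
            report.add("error", name, f"unknown field for kind {profile.kind}")
    for fs in spec.fields:
        if fs.name in profile.fields:
            _check_value(fs, profile.fields[fs.name], report)

    # data-absent reasons: declared must-support path, known code, no overlap
    seen_paths: set[str] = set()
    for a in profile.absent_reasons:
        if a.field_path not in declared:
            report.add("error", a.field_path, "data-absent reason names an undeclared field")
            continue
        if not spec.field(a.field_path).must_support:
            report.add(
                "error", a.field_path,
                "data-absent reason only applies to must-support fields",
            )
        if a.reason_code not in ABSENT_REASON_CODES:
            report.add(
                "error", a.field_path,
                f"unknown data-absent reason code {a.reason_code!r}",
            )
        if a.field_path in seen_paths:
            report.add("error", a.field_path, "more than one data-absent reason for field")
        seen_paths.add(a.field_path)
        if a.field_path in profile.fields:
            report.add(
                "error", a.field_path,
                "field is populated and also carries a data-absent reason",
            )

    for name in spec.must_support_fields:
        if name not in profile.fields and name not in seen_paths:
            report.add(
                "error", name,
                "must-support field is not populated and has no data-absent reason",
            )

    if spec.has_subject and not profile.subject_ref:
        report.add("error", "subject_ref", f"{profile.kind} requires a subject reference")
    if not spec.has_subject and profile.subject_ref:
        report.add("error", "subject_ref", f"{profile.kind} must not carry a subject reference")
    if not profile.resource_id:
        report.add("error", "resource_id", "resource_id must be non-empty")
    return report


def apply_data_absent_reason(
    profile: McodeProfile, field_path: str, reason_code: str = "unknown"
) -> McodeProfile:
    """Return a copy of ``profile`` with a dataAbsentReason on ``field_path``.

    Rejects unknown field paths, populated fields (a field cannot be both
    present and absent), already-covered fields and unknown reason codes.
    The input profile is not modified.
    """
    spec = profile.spec
    if field_path not in spec.field_names:
        raise ValueError(f"unknown field path {field_path!r} for kind {profile.kind}")
    if not spec.field(field_path).must_support:
        raise ValueError(f"{field_path!r} is not a must-support field of {profile.kind}")
    if field_path in profile.fields:
        raise ValueError(f"field {field_path!r} is populated; cannot mark it absent")
    if profile.absent_for(field_path):
        raise ValueError(f"field {field_path!r} already carries a data-absent reason")
    if reason_code not in ABSENT_REASON_CODES:
        raise ValueError(
            f"unknown data-absent reason code {reason_code!r}; "
            f"expected one of {sorted(ABSENT_REASON_CODES)}"
        )
    out = profile.clone()
    out.absent_reasons = sorted(
        out.absent_reasons + [DataAbsentReason(field_path, reason_code)],
        key=lambda a: a.field_path,
    )
    return out


def attach_extension(
    profile: McodeProfile,
    anchor_path: str,
    url: str,
    value: PrimitiveOrCoded,
    namespace: str = DEFAULT_EXTENSION_NAMESPACE,
) -> McodeProfile:
    """Return a copy of ``profile`` with an extension attached.

    ``url`` must fall under the configured ``namespace``; ``anchor_path`` must
    be a declared field of the profile kind or the literal ``"resource"``.
    Duplicate urls within one profile are rejected.
    """
    if not url.startswith(namespace):
        raise ValueError(f"extension url {url!r} is not under namespace {namespace!r}")
    if anchor_path != "resource" and anchor_path not in profile.spec.field_names:
        raise ValueError(
            f"unknown anchor path {anchor_path!r} for kind {profile.kind}"
        )
    if any(e.url == url for e in profile.extensions):
        raise ValueError(f"duplicate extension url {url!r}")
    if not isinstance(value, (str, int, float, bool, CodedValue)):
        raise ValueError(f"unsupported extension value type {type(value).__name__}")
    out = profile.clone()
    out.extensions = sorted(
        out.extensions + [ExtensionValue(url=url, value=value, anchor_path=anchor_path)],
        key=lambda e: e.url,
    )
    return out


# ---------------------------------------------------------------------------
# FHIR JSON emission

def _codeable(cv: CodedValue) -> dict[str, Any]:
    coding: dict[str, Any] = {"system": cv.system, "code": cv.code}
    if cv.display is not None:
        coding["display"] = cv.display
    return {"coding": [coding]}

def _parse_codeable(obj: dict[str, Any]) -> CodedValue:
    coding = obj.get("coding") or []
    if not coding:
        raise MalformedJsonError(f"CodeableConcept without coding: {obj!r}")
    c = coding[0]
    return CodedValue(system=c["system"], code=c["code"], display=c.get("display"))

def _dar_ext(reason: str) -> dict[str, str]:
    return {"url": DATA_ABSENT_REASON_URL, "valueCode": reason}

def _dar_concept(reason: str) -> dict[str, Any]:
    return {"coding": [{"system": DATA_ABSENT_REASON_SYSTEM, "code": reason}]}

def _ref(ref_type: str, rid: str) -> dict[str, str]:
    return {"reference": f"{ref_type}/{rid}"}

def _parse_ref(obj: dict[str, Any]) -> str:
    ref = obj.get("reference", "")
    return ref.split("/", 1)[1] if "/" in ref else ref

_VALUE_KEYS = {
    str: "valueString",
    bool: "valueBoolean",
    int: "valueInteger",
    float: "valueDecimal",
}


def _emit_extension_value(ev: ExtensionValue) -> dict[str, Any]:
    sub: dict[str, Any] = {"url": "value"}
    if isinstance(ev.value, CodedValue):
        sub["valueCodeableConcept"] = _codeable(ev.value)
    else:
        sub[_VALUE_KEYS[type(ev.value)]] = ev.value
    return {
        "url": ev.url,
        "extension": [{"url": "anchor", "valueString": ev.anchor_path}, sub],
    }


def _parse_extension_value(obj: dict[str, Any]) -> ExtensionValue:
    anchor = "resource"
    value: Any = None
    for sub in obj.get("extension", []):
        if sub.get("url") == "anchor":
            anchor = sub.get("valueString", "resource")
        elif sub.get("url") == "value":
            if "valueCodeableConcept" in sub:
                value = _parse_codeable(sub["valueCodeableConcept"])
            else:
                for key in ("valueString", "valueBoolean", "valueInteger", "valueDecimal"):
                    if key in sub:
                        value = sub[key]
                        break
    if value is None:
        raise MalformedJsonError(f"extension {obj.get('url')!r} carries no value")
    return ExtensionValue(url=obj["url"], value=value, anchor_path=anchor)


def _emit_component(fs: FieldSpec, value: Any) -> dict[str, Any]:
    comp: dict[str, Any] = {
        "code": {"coding": [{"system": "http://loinc.org",
                             "code": fs.slot["loinc"],
                             "display": fs.slot.get("display", "")}]}
    }
    if fs.type == "coded":
        comp["valueCodeableConcept"] = _codeable(value)
    elif fs.type == "fraction":
        comp["valueQuantity"] = {
            "value": value, "system": "http://unitsofmeasure.org", "code": "1"
        }
    else:
        comp["valueString"] = value
    return comp


def to_fhir_dict(profile: McodeProfile) -> dict[str, Any]:
    """Emit one profile as a FHIR R4 resource dict; rejects invalid profiles."""
    report = validate_profile(profile)
    if not report.valid:
        raise ProfileValidationError(report, "cannot serialize invalid profile")
    spec = profile.spec
    res: dict[str, Any] = {
        "resourceType": spec.resource_type,
        "id": profile.resource_id,
        "meta": {"profile": [spec.profile_url]},
    }
    if spec.resource_type in ("Observation", "DiagnosticReport"):
        res["status"] = "final"
    if spec.fixed_code:
        res["code"] = {"coding": [dict(spec.fixed_code)]}
    if spec.has_subject:
        res["subject"] = _ref("Patient", profile.subject_ref)

    ext_out: list[dict[str, Any]] = []
    components: list[dict[str, Any]] = []
    absent = {a.field_path: a.reason_code for a in profile.absent_reasons}

    for fs in spec.fields:
        value = profile.fields.get(fs.name)
        reason = absent.get(fs.name)
        k = fs.slot["kind"]
        if value is None and reason is None:
            continue
        if k == "primitive":
            el = fs.slot["element"]
            if value is not None:
                res[el] = value
            else:
                res["_" + el] = {"extension": [_dar_ext(reason)]}
        elif k == "extension_code":
            if value is not None:
                ext_out.append({"url": fs.slot["url"], "valueCode": value})
            else:
                ext_out.append({"url": fs.slot["url"], "extension": [_dar_ext(reason)]})
        elif k == "extension_ref_list":
            for rid in value or []:
                ext_out.append(
                    {"url": fs.slot["url"], "valueReference": _ref(fs.ref_type, rid)}
                )
        elif k == "specimen_ref":
            if value is not None:
                res["specimen"] = [_ref("Specimen", value)]
            else:
                res["specimen"] = [{"extension": [_dar_ext(reason)]}]
        elif k == "result_refs":
            res["result"] = [_ref("Observation", rid) for rid in value or []]
        elif k == "component":
            if value is not None:
                components.append(_emit_component(fs, value))
            else:
                components.append({
                    "code": {"coding": [{"system": "http://loinc.org",
                                         "code": fs.slot["loinc"],
                                         "display": fs.slot.get("display", "")}]},
                    "dataAbsentReason": _dar_concept(reason),
                })
        elif k == "component_list":
            if value is not None:
                for code in value:
                    cv = CodedValue(system=fs.system, code=code)
                    components.append(
                        _emit_component(replace(fs, type="coded"), cv)
                    )
            else:
                components.append({
                    "code": {"coding": [{"system": "http://loinc.org",
                                         "code": fs.slot["loinc"],
                                         "display": fs.slot.get("display", "")}]},
                    "dataAbsentReason": _dar_concept(reason),
                })
        elif k == "specimen_type":
            if value is not None:
                res["type"] = _codeable(value)
            else:
                res["type"] = {"extension": [_dar_ext(reason)]}
        elif k == "collected":
            coll = res.setdefault("collection", {})
            if value is not None:
                coll["collectedDateTime"] = value
            else:
                coll["_collectedDateTime"] = {"extension": [_dar_ext(reason)]}
        else:  # pragma: no cover - registry is validated at load
            raise ValueError(f"unknown slot kind {k!r}")

    for ev in profile.extensions:
        ext_out.append(_emit_extension_value(ev))
    if components:
        res["component"] = components
    if ext_out:
        res["extension"] = sorted(
            ext_out, key=lambda e: (e["url"], json.dumps(e, sort_keys=True))
        )
    return res


def to_fhir_json(profile: McodeProfile) -> str:
    """Canonical FHIR R4 JSON text (sorted keys, minimal whitespace)."""
    return json.dumps(
        to_fhir_dict(profile), sort_keys=True, separators=(",", ":"), ensure_ascii=False
    )


# ---------------------------------------------------------------------------
# FHIR JSON parsing

def _slot_extension_urls(spec: KindSpec) -> dict[str, FieldSpec]:
    out = {}
    for fs in spec.fields:
        if fs.slot["kind"] in ("extension_code", "extension_ref_list"):
            out[fs.slot["url"]] = fs
    return out


def from_fhir_dict(res: dict[str, Any]) -> McodeProfile:
    """Reconstruct a profile from a FHIR R4 resource dict."""
    if not isinstance(res, dict) or "resourceType" not in res:
        raise MalformedJsonError("document has no resourceType")
    rt = res["resourceType"]
    urls = (res.get("meta") or {}).get("profile") or []
    if not urls:
        raise MissingProfileUrlError(f"resource {rt} carries no meta.profile")
    kind = next((k for u in urls if (k := profile_url_to_kind(u))), None)
    if kind is None:
        raise UnknownKindError(
            f"no implemented profile kind for resourceType {rt!r} "
            f"with profiles {urls!r}"
        )
    spec = kind_spec(kind)
    if spec.resource_type != rt:
        raise UnknownKindError(
            f"resourceType {rt!r} does not match kind {kind} ({spec.resource_type})"
        )

    fields: dict[str, Any] = {}
    absent: list[DataAbsentReason] = []
    extensions: list[ExtensionValue] = []

    def read_dar(container: dict[str, Any]) -> Optional[str]:
        for e in container.get("extension", []):
            if e.get("url") == DATA_ABSENT_REASON_URL:
                return e.get("valueCode", "unknown")
        return None

    # components, indexed by LOINC code
    comps_by_code: dict[str, list[dict[str, Any]]] = {}
    for comp in res.get("component", []):
        code = (comp.get("code", {}).get("coding") or [{}])[0].get("code", "")
        comps_by_code.setdefault(code, []).append(comp)

    slot_ext = _slot_extension_urls(spec)
    ref_list_acc: dict[str, list[str]] = {}
    for e in res.get("extension", []):
        fs = slot_ext.get(e.get("url", ""))
        if fs is not None:
            if fs.slot["kind"] == "extension_code":
                reason = read_dar(e)
                if reason is not None:
                    absent.append(DataAbsentReason(fs.name, reason))
                elif "valueCode" in e:
                    fields[fs.name] = e["valueCode"]
            else:  # extension_ref_list
                ref_list_acc.setdefault(fs.name, []).append(
                    _parse_ref(e["valueReference"])
                )
        else:
            extensions.append(_parse_extension_value(e))
    fields.update(ref_list_acc)

    for fs in spec.fields:
        k = fs.slot["kind"]
        if k == "primitive":
            el = fs.slot["element"]
            if el in res:
                fields[fs.name] = res[el]
            elif "_" + el in res:
                reason = read_dar(res["_" + el])
                if reason is not None:
                    absent.append(DataAbsentReason(fs.name, reason))
        elif k == "specimen_ref":
            spc = res.get("specimen") or []
            if spc:
                reason = read_dar(spc[0])
                if reason is not None:
                    absent.append(DataAbsentReason(fs.name, reason))
                else:
                    fields[fs.name] = _parse_ref(spc[0])
        elif k == "result_refs":
            if res.get("result"):
                fields[fs.name] = [_parse_ref(r) for r in res["result"]]
        elif k == "component":
            comps = comps_by_code.get(fs.slot["loinc"], [])
            if comps:
                comp = comps[0]
                if "dataAbsentReason" in comp:
                    coding = comp["dataAbsentReason"].get("coding", [{}])
                    absent.append(
                        DataAbsentReason(fs.name, coding[0].get("code", "unknown"))
                    )
                elif "valueCodeableConcept" in comp:
                    fields[fs.name] = _parse_codeable(comp["valueCodeableConcept"])
                elif "valueQuantity" in comp:
                    fields[fs.name] = comp["valueQuantity"]["value"]
                elif "valueString" in comp:
                    fields[fs.name] = comp["valueString"]
        elif k == "component_list":
            comps = comps_by_code.get(fs.slot["loinc"], [])
            if comps:
                if "dataAbsentReason" in comps[0]:
                    coding = comps[0]["dataAbsentReason"].get("coding", [{}])
                    absent.append(
                        DataAbsentReason(fs.name, coding[0].get("code", "unknown"))
                    )
                else:
                    fields[fs.name] = [
                        _parse_codeable(c["valueCodeableConcept"]).code for c in comps
                    ]
        elif k == "specimen_type":
            t = res.get("type")
            if t is not None:
                reason = read_dar(t)
                if reason is not None:
                    absent.append(DataAbsentReason(fs.name, reason))
                else:
                    fields[fs.name] = _parse_codeable(t)
        elif k == "collected":
            coll = res.get("collection") or {}
            if "collectedDateTime" in coll:
                fields[fs.name] = coll["collectedDateTime"]
            elif "_collectedDateTime" in coll:
                reason = read_dar(coll["_collectedDateTime"])
                if reason is not None:
                    absent.append(DataAbsentReason(fs.name, reason))

    subject_ref = _parse_ref(res["subject"]) if "subject" in res else None
    return McodeProfile(
        kind=kind,
        resource_id=res.get("id", ""),
        subject_ref=subject_ref,
        fields=fields,
        absent_reasons=absent,
        extensions=extensions,
    )


def from_fhir_json(text: str) -> McodeProfile:
    """Parse canonical (or any) FHIR R4 JSON text into a profile."""
    try:
        res = json.loads(text)
    except json.JSONDecodeError as exc:
        raise MalformedJsonError(f"malformed JSON: {exc}") from exc
    return from_fhir_dict(res)


# ---------------------------------------------------------------------------
# NDJSON bundles (bulk-import convention: one resource per line)

def write_bundle_ndjson(bundle: ProfileBundle, path) -> int:
    """Write a bundle as NDJSON; returns the number of lines written."""
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for p in bundle:
            fh.write(to_fhir_json(p))
            fh.write("\n")
            n += 1
    return n


def read_bundle_ndjson(path) -> ProfileBundle:
    bundle = ProfileBundle()
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                bundle.append(from_fhir_json(line))
            except ProfileJSONError as exc:
                raise type(exc)(f"line {i}: {exc}") from exc
    return bundle
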