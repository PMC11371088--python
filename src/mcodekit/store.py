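"""Entity-attribute-value profile store with FHIR-style paginated search.

In-process stand-in for a managed FHIR server backed by an EAV-model SQL
database: every stored profile is flattened into (resource_id, resource_type,
attribute_path, value) rows in a single-file embedded SQLite database, each
profile is validated at the time of being loaded, and search returns
deterministic keyset-paginated pages capped at 1,000 profiles — the page
limit the hosted server this emulates imposes, which forces multiple calls
for comprehensive data.

Attribute paths are dotted and indexed (``gene.code``, ``result_refs.0``);
data-absent reasons are stored under ``absent.<field>`` and extensions under
``ext|<url>|...`` (the ``|`` separator keeps URLs, which contain dots,
unambiguous).
"""

from __future__ import annotations

import base64
import hashlib
import json
import sqlite3
import threading
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Any, Iterator, Optional

from pydantic import BaseModel, model_validator

from .profiles import (
    CodedValue,
    DataAbsentReason,
    ExtensionValue,
    McodeProfile,
    ProfileValidationError,
    validate_profile,
)
from .registry import kind_spec

__all__ = [
    "EavRow",
    "EavStore",
    "SearchQuery",
    "SearchResultPage",
    "StoreError",
    "to_eav",
    "from_eav",
    "DEFAULT_PAGE_LIMIT",
]

#: Search page cap, matching the hosted FHIR server's 1,000-profile limit.
DEFAULT_PAGE_LIMIT = 1000

_SEX_ALIASES = {"f": "female", "m": "male", "o": "other", "u": "unknown"}


class StoreError(Exception):
    pass


@dataclass(frozen=True)
class EavRow:
    resource_id: str
    resource_type: str
    attribute_path: str
    value: str
    value_type: str


# ---------------------------------------------------------------------------
# flatten / reconstruct

def _encode(value: Any) -> tuple[str, str]:
    if isinstance(value, bool):
        return ("true" if value else "false", "boolean")
    if isinstance(value, int):
        return (str(value), "integer")
    if isinstance(value, float):
        return (repr(value), "decimal")
    return (str(value), "string")


def _decode(value: str, value_type: str) -> Any:
    if value_type == "decimal":
        return float(value)
    if value_type == "integer":
        return int(value)
    if value_type == "boolean":
        return value == "true"
    return value


def to_eav(profile: McodeProfile) -> list[EavRow]:
    """Flatten a valid profile into EAV rows, one per populated leaf."""
    report = validate_profile(profile)
    if not report.valid:
        raise ProfileValidationError(report, "cannot store invalid profile")
    spec = profile.spec
    rows: list[tuple[str, str, str]] = []  # (path, value, type)

    if profile.subject_ref is not None:
        rows.append(("subject_ref", profile.subject_ref, "ref"))
    for fs in spec.fields:
        v = profile.fields.get(fs.name)
        if v is None:
            continue
        if fs.type == "coded":
            rows.append((f"{fs.name}.system", v.system, "string"))
            rows.append((f"{fs.name}.code", v.code, "string"))
            if v.display is not None:
                rows.append((f"{fs.name}.display", v.display, "string"))
        elif fs.type in ("ref_list", "code_list"):
            for i, item in enumerate(v):
                rows.append((f"{fs.name}.{i}", item, "ref" if fs.type == "ref_list" else "string"))
        elif fs.type == "fraction":
            rows.append((fs.name, repr(float(v)), "decimal"))
        else:
            rows.append((fs.name, str(v), "ref" if fs.type == "ref" else "string"))
    for a in profile.absent_reasons:
        rows.append((f"absent.{a.field_path}", a.reason_code, "dar"))
    for e in profile.extensions:
        rows.append((f"ext|{e.url}|anchor", e.anchor_path, "string"))
        if isinstance(e.value, CodedValue):
            rows.append((f"ext|{e.url}|value.system", e.value.system, "string"))
            rows.append((f"ext|{e.url}|value.code", e.value.code, "string"))
            if e.value.display is not None:
                rows.append((f"ext|{e.url}|value.display", e.value.display, "string"))
        else:
            val, vt = _encode(e.value)
            rows.append((f"ext|{e.url}|value", val, vt))
    return [
        EavRow(profile.resource_id, profile.kind, path, value, vt)
        for path, value, vt in rows
    ]


def from_eav(rows: list[EavRow]) -> McodeProfile:
    """Reconstruct one profile from its EAV rows."""
    if not rows:
        raise StoreError("no EAV rows to reconstruct from")
    rids = {r.resource_id for r in rows}
    if len(rids) > 1:
        raise StoreError(f"rows for mixed resource_ids: {sorted(rids)}")
    kinds = {r.resource_type for r in rows if r.resource_type}
    if not kinds:
        raise StoreError("rows are missing resource_type")
    if len(kinds) > 1:
        raise StoreError(f"rows with mixed resource_type: {sorted(kinds)}")
    kind = kinds.pop()
    spec = kind_spec(kind)

    subject_ref: Optional[str] = None
    fields: dict[str, Any] = {}
    absent: list[DataAbsentReason] = []
    ext_acc: dict[str, dict[str, Any]] = {}
    coded_acc: dict[str, dict[str, str]] = {}
    list_acc: dict[str, dict[int, str]] = {}

    for r in rows:
        p = r.attribute_path
        if p == "subject_ref":
            subject_ref = r.value
        elif p.startswith("absent."):
            absent.append(DataAbsentReason(p[len("absent."):], r.value))
        elif p.startswith("ext|"):
            _, url, rest = p.split("|", 2)
            ext_acc.setdefault(url, {})[rest] = _decode(r.value, r.value_type)
        else:
            name, _, sub = p.partition(".")
            try:
                fs = spec.field(name)
            except KeyError:
                raise StoreError(f"unknown attribute_path {p!r} for kind {kind}") from None
            if fs.type == "coded":
                coded_acc.setdefault(name, {})[sub] = r.value
            elif fs.type in ("ref_list", "code_list"):
                list_acc.setdefault(name, {})[int(sub)] = r.value
            else:
                fields[name] = _decode(r.value, r.value_type)

    for name, parts in coded_acc.items():
        fields[name] = CodedValue(
            system=parts["system"], code=parts["code"], display=parts.get("display")
        )
    for name, parts in list_acc.items():
        fields[name] = [parts[i] for i in sorted(parts)]

    extensions = []
    for url, parts in ext_acc.items():
        anchor = parts.get("anchor", "resource")
        if "value.system" in parts:
            value: Any = CodedValue(
                system=parts["value.system"], code=parts["value.code"],
                display=parts.get("value.display"),
            )
        else:
            value = parts["value"]
        extensions.append(ExtensionValue(url=url, value=value, anchor_path=anchor))

    return McodeProfile(
        kind=kind, resource_id=rows[0].resource_id, subject_ref=subject_ref,
        fields=fields, absent_reasons=absent, extensions=extensions,
    )


# ---------------------------------------------------------------------------
# search query / result types

class SearchQuery(BaseModel):
    """Conjunctive FHIR-style search predicates plus a continuation token."""

    resource_type: Optional[str] = None  # profile kind name
    subject: Optional[str] = None
    gene: Optional[str] = None
    phecode: Optional[str] = None
    sex: Optional[str] = None
    race: Optional[str] = None
    age_range: Optional[tuple[float, float]] = None
    genomic_source_class: Optional[str] = None
    page_token: Optional[str] = None

    @model_validator(mode="after")
    def _age_range_ordered(self):
        if self.age_range is not None and self.age_range[0] > self.age_range[1]:
            raise ValueError(f"age_range lo > hi: {self.age_range}")
        return self

    def fingerprint(self) -> str:
        payload = self.model_dump(exclude={"page_token"})
        payload["age_range"] = list(payload["age_range"]) if payload["age_range"] else None
        return hashlib.sha1(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class SearchResultPage:
    profiles: list[McodeProfile]
    total: int
    next_token: Optional[str] = None


def _encode_token(key: tuple[str, str], fingerprint: str) -> str:
    raw = json.dumps({"k": list(key), "f": fingerprint}).encode()
    return base64.urlsafe_b64encode(raw).decode()


def _decode_token(token: str, fingerprint: str) -> tuple[str, str]:
    try:
        obj = json.loads(base64.urlsafe_b64decode(token.encode()))
        key = obj["k"]
        if not (isinstance(key, list) and len(key) == 2):
            raise ValueError("bad key")
    except Exception as exc:
        raise StoreError(f"malformed page token: {token!r}") from exc
    if obj.get("f") != fingerprint:
        raise StoreError("page token does not belong to this query")
    return (key[0], key[1])


def age_in_years(birth_date: str, as_of: str) -> int:
    b, a = date.fromisoformat(birth_date), date.fromisoformat(as_of)
    return a.year - b.year - ((a.month, a.day) < (b.month, b.day))


# ---------------------------------------------------------------------------
# the store

class EavStore:
    """Single-file (or in-memory) EAV profile store.

    Profiles are validated on ``put`` (invalid ones are rejected with their
    ValidationReport and the store is unchanged) and upserted by resource_id,
    so repeated loads are idempotent.  ``as_of`` anchors age-range search
    predicates; it is persisted in the store file so reopening preserves it.
    """

    def __init__(
        self,
        path: str | Path = ":memory:",
        page_limit: int = DEFAULT_PAGE_LIMIT,
        as_of: str = "2021-01-01",
    ):
        self.path = str(path)
        self._conn = sqlite3.connect(self.path, check_same_thread=False)
        self._lock = threading.Lock()
        with self._lock:
            cur = self._conn.cursor()
            cur.execute(
                "CREATE TABLE IF NOT EXISTS eav ("
                " resource_id TEXT NOT NULL,"
                " resource_type TEXT NOT NULL,"
                " attribute_path TEXT NOT NULL,"
                " value TEXT NOT NULL,"
                " value_type TEXT NOT NULL,"
                " PRIMARY KEY (resource_id, attribute_path))"
            )
            cur.execute(
                "CREATE INDEX IF NOT EXISTS ix_eav_type ON eav (resource_type)"
            )
            cur.execute(
                "CREATE TABLE IF NOT EXISTS store_config (key TEXT PRIMARY KEY, value TEXT)"
            )
            stored = dict(cur.execute("SELECT key, value FROM store_config"))
            if stored:
                self.page_limit = int(stored["page_limit"])
                self.as_of = stored["as_of"]
            else:
                self.page_limit = int(page_limit)
                self.as_of = as_of
                cur.executemany(
                    "INSERT INTO store_config VALUES (?, ?)",
                    [("page_limit", str(self.page_limit)), ("as_of", self.as_of)],
                )
            self._conn.commit()

    def close(self) -> None:
        self._conn.close()

    # -- write path --------------------------------------------------------

    def put(self, profile: McodeProfile) -> str:
        """Validate and upsert one profile; returns its resource_id."""
        rows = to_eav(profile)  # raises ProfileValidationError when invalid
        with self._lock:
            cur = self._conn.cursor()
            cur.execute("DELETE FROM eav WHERE resource_id = ?", (profile.resource_id,))
            cur.executemany(
                "INSERT INTO eav VALUES (?, ?, ?, ?, ?)",
                [
                    (r.resource_id, r.resource_type, r.attribute_path, r.value, r.value_type)
                    for r in rows
                ],
            )
            self._conn.commit()
        return profile.resource_id

    def put_many(
        self, profiles: list[McodeProfile]
    ) -> tuple[list[str], list[tuple[str, Any]]]:
        """Upsert a batch in one transaction; returns (loaded ids, rejections).

        Each rejection is (resource_id, ValidationReport); rejected profiles
        leave the store untouched.
        """
        staged: list[tuple[str, list[EavRow]]] = []
        loaded: list[str] = []
        rejected: list[tuple[str, Any]] = []
        for p in profiles:
            try:
                staged.append((p.resource_id, to_eav(p)))
                loaded.append(p.resource_id)
            except ProfileValidationError as exc:
                rejected.append((p.resource_id, exc.report))
        with self._lock:
            cur = self._conn.cursor()
            for rid, rows in staged:
                cur.execute("DELETE FROM eav WHERE resource_id = ?", (rid,))
                cur.executemany(
                    "INSERT INTO eav VALUES (?, ?, ?, ?, ?)",
                    [
                        (r.resource_id, r.resource_type, r.attribute_path,
                         r.value, r.value_type)
                        for r in rows
                    ],
                )
            self._conn.commit()
        return loaded, rejected

    def snapshot(self) -> frozenset[tuple[str, str, str, str, str]]:
        """All EAV rows as a frozenset, for order-independence assertions."""
        cur = self._conn.execute(
            "SELECT resource_id, resource_type, attribute_path, value, value_type FROM eav"
        )
        return frozenset(tuple(r) for r in cur.fetchall())

    # -- read path ---------------------------------------------------------

    def get(self, resource_id: str) -> Optional[McodeProfile]:
        cur = self._conn.execute(
            "SELECT resource_id, resource_type, attribute_path, value, value_type"
            " FROM eav WHERE resource_id = ?",
            (resource_id,),
        )
        rows = [EavRow(*r) for r in cur.fetchall()]
        return from_eav(rows) if rows else None

    def count(self) -> int:
        (n,) = self._conn.execute(
            "SELECT COUNT(DISTINCT resource_id) FROM eav"
        ).fetchone()
        return n

    def iter_profiles(self, resource_type: Optional[str] = None) -> Iterator[McodeProfile]:
        """Profiles in (resource_type, resource_id) order."""
        if resource_type is None:
            cur = self._conn.execute(
                "SELECT resource_id, resource_type, attribute_path, value, value_type"
                " FROM eav ORDER BY resource_type, resource_id"
            )
        else:
            cur = self._conn.execute(
                "SELECT resource_id, resource_type, attribute_path, value, value_type"
                " FROM eav WHERE resource_type = ? ORDER BY resource_type, resource_id",
                (resource_type,),
            )
        current: list[EavRow] = []
        for raw in cur:
            row = EavRow(*raw)
            if current and current[0].resource_id != row.resource_id:
                yield from_eav(current)
                current = []
            current.append(row)
        if current:
            yield from_eav(current)

    # -- search ------------------------------------------------------------

    def search(self, query: SearchQuery) -> SearchResultPage:
        """Evaluate conjunctive predicates; return one deterministic page.

        Ordering is lexicographic by (resource_type, resource_id); the
        continuation token encodes the last-returned key (keyset pagination),
        so inserts between page requests never duplicate results.
        """
        matches = self._match(query)
        fp = query.fingerprint()
        start = 0
        if query.page_token is not None:
            last = _decode_token(query.page_token, fp)
            keys = [(p.kind, p.resource_id) for p in matches]
            # first strictly-greater key
            start = next((i for i, k in enumerate(keys) if k > last), len(keys))
        page = matches[start : start + self.page_limit]
        next_token = None
        if start + self.page_limit < len(matches) and page:
            next_token = _encode_token((page[-1].kind, page[-1].resource_id), fp)
        return SearchResultPage(profiles=page, total=len(matches), next_token=next_token)

    def _match(self, query: SearchQuery) -> list[McodeProfile]:
        profiles = list(self.iter_profiles(query.resource_type))
        needs_patients = any(
            v is not None
            for v in (query.sex, query.race, query.age_range, query.phecode)
        )
        patients: dict[str, McodeProfile] = {}
        if needs_patients:
            patients = {
                p.resource_id: p for p in self.iter_profiles("CancerPatient")
            }
        gene_carriers: Optional[set[str]] = None
        if query.gene is not None:
            gene_carriers = set()
            for v in self.iter_profiles("GenomicVariant"):
                g = v.fields.get("gene")
                if g is not None and g.code == query.gene and v.subject_ref:
                    gene_carriers.add(v.subject_ref)

        out = []
        for p in profiles:
            if self._matches(p, query, patients, gene_carriers):
                out.append(p)
        out.sort(key=lambda p: (p.kind, p.resource_id))
        return out

    def _patient_of(
        self, p: McodeProfile, patients: dict[str, McodeProfile]
    ) -> Optional[McodeProfile]:
        if p.kind == "CancerPatient":
            return p
        if p.subject_ref is not None:
            return patients.get(p.subject_ref)
        return None

    def _matches(
        self,
        p: McodeProfile,
        q: SearchQuery,
        patients: dict[str, McodeProfile],
        gene_carriers: Optional[set[str]],
    ) -> bool:
        if q.subject is not None:
            owner = p.resource_id if p.kind == "CancerPatient" else p.subject_ref
            if owner != q.subject:
                return False
        if q.gene is not None:
            if p.kind == "GenomicVariant":
                g = p.fields.get("gene")
                if g is None or g.code != q.gene:
                    return False
            elif p.kind == "GenomicRegionStudied":
                if q.gene not in p.fields.get("genes", []):
                    return False
            else:
                owner = p.resource_id if p.kind == "CancerPatient" else p.subject_ref
                if gene_carriers is None or owner not in gene_carriers:
                    return False
        if q.genomic_source_class is not None:
            if p.kind != "GenomicVariant":
                return False
            sc = p.fields.get("genomic_source_class")
            if sc is None:
                return False
            wanted = q.genomic_source_class.lower()
            if wanted not in (sc.code.lower(), (sc.display or "").lower()):
                return False
        if q.sex is not None or q.race is not None or q.age_range is not None \
                or q.phecode is not None:
            pat = self._patient_of(p, patients)
            if pat is None:
                return False
            if q.sex is not None:
                wanted = _SEX_ALIASES.get(q.sex.lower(), q.sex.lower())
                if pat.fields.get("sex", "").lower() != wanted:
                    return False
            if q.race is not None and pat.fields.get("race") != q.race:
                return False
            if q.age_range is not None:
                bd = pat.fields.get("birth_date")
                if bd is None:
                    return False
                age = age_in_years(bd, self.as_of)
                lo, hi = q.age_range
                if not lo <= age <= hi:
                    return False
            if q.phecode is not None:
                if not any(
                    isinstance(e.value, CodedValue) and e.value.code == q.phecode
                    and not e.url.endswith("/onset")
                    for e in pat.extensions
                ):
                    return False
        return True
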