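"""Profile model: must-support validation, absent reasons, extensions, FHIR JSON."""

from __future__ import annotations

import json
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import all_kinds, make_profile
from mcodekit.profiles import (
    CodedValue,
    DataAbsentReason,
    MalformedJsonError,
    McodeProfile,
    MissingProfileUrlError,
    ProfileBundle,
    ProfileValidationError,
    UnknownKindError,
    apply_data_absent_reason,
    attach_extension,
    from_fhir_json,
    read_bundle_ndjson,
    to_fhir_json,
    validate_profile,
    write_bundle_ndjson,
)
from mcodekit.registry import kind_spec

NS = "urn:example:mcode-pilot:"


# ---------------------------------------------------------------------------
# validation

def test_fully_populated_variant_is_valid(variant_profile):
    report = validate_profile(variant_profile)
    assert report.valid and report.findings == []


def test_missing_gene_without_reason_is_an_error(variant_profile):
    del variant_profile.fields["gene"]
    report = validate_profile(variant_profile)
    assert not report.valid
    assert any(f.field_path == "gene" for f in report.errors())


def test_absent_reason_restores_validity(variant_profile):
    del variant_profile.fields["gene"]
    fixed = apply_data_absent_reason(variant_profile, "gene", "unknown")
    assert validate_profile(fixed).valid
    # original is untouched (pure function)
    assert not validate_profile(variant_profile).valid
    assert variant_profile.absent_reasons == []


def test_reason_on_populated_field_rejected(variant_profile):
    with pytest.raises(ValueError, match="populated"):
        apply_data_absent_reason(variant_profile, "gene")


def test_reason_applied_twice_rejected(variant_profile):
    del variant_profile.fields["gene"]
    once = apply_data_absent_reason(variant_profile, "gene")
    with pytest.raises(ValueError, match="already"):
        apply_data_absent_reason(once, "gene")


def test_unknown_field_path_rejected(variant_profile):
    with pytest.raises(ValueError, match="no_such_field"):
        apply_data_absent_reason(variant_profile, "no_such_field")


def test_unknown_reason_code_rejected(variant_profile):
    del variant_profile.fields["gene"]
    with pytest.raises(ValueError, match="refused"):
        apply_data_absent_reason(variant_profile, "gene", "refused")


def test_hand_built_unknown_reason_code_is_a_finding(variant_profile):
    del variant_profile.fields["gene"]
    variant_profile.absent_reasons.append(DataAbsentReason("gene", "bogus"))
    report = validate_profile(variant_profile)
    assert any("bogus" in f.message for f in report.errors())


def test_allelic_frequency_out_of_range_is_an_error(variant_profile):
    variant_profile.fields["allelic_frequency"] = 1.2
    report = validate_profile(variant_profile)
    assert any(f.field_path == "allelic_frequency" for f in report.errors())


def test_validation_is_pure_and_idempotent(variant_profile):
    before = variant_profile.clone()
    r1 = validate_profile(variant_profile)
    r2 = validate_profile(variant_profile)
    assert r1.findings == r2.findings
    assert variant_profile == before


def test_subject_required_except_for_patient():
    p = make_profile("GenomicSpecimen", "spe:1")
    p.subject_ref = None
    assert not validate_profile(p).valid
    pat = make_profile("CancerPatient", "pat:1")
    pat.subject_ref = "pat:2"
    assert not validate_profile(pat).valid


# ---------------------------------------------------------------------------
# extensions

def test_extension_roundtrips_through_json():
    p = make_profile("GenomicsReport", "rep:GR1")
    p = attach_extension(p, "test_date", NS + "lab-run-id", "RUN-42")
    again = from_fhir_json(to_fhir_json(p))
    assert again == p
    assert again.extensions[0].value == "RUN-42"
    assert again.extensions[0].anchor_path == "test_date"


def test_duplicate_extension_url_rejected():
    p = make_profile("CancerPatient", "pat:1")
    p = attach_extension(p, "resource", NS + "flag", True)
    with pytest.raises(ValueError, match="duplicate"):
        attach_extension(p, "resource", NS + "flag", False)


def test_extension_unknown_anchor_rejected():
    p = make_profile("CancerPatient", "pat:1")
    with pytest.raises(ValueError, match="nope"):
        attach_extension(p, "nope", NS + "x", 1)


def test_extension_outside_namespace_rejected():
    p = make_profile("CancerPatient", "pat:1")
    with pytest.raises(ValueError, match="namespace"):
        attach_extension(p, "resource", "http://elsewhere/x", 1)


def test_extensions_never_invalidate(variant_profile):
    p = attach_extension(variant_profile, "gene", NS + "note", "checked")
    assert validate_profile(p).valid


# ---------------------------------------------------------------------------
# FHIR JSON serialization

EXPECTED_RESOURCE_TYPES = {
    "CancerPatient": "Patient",
    "GenomicsReport": "DiagnosticReport",
    "GenomicVariant": "Observation",
    "GenomicRegionStudied": "Observation",
    "GenomicSpecimen": "Specimen",
}


@pytest.mark.parametrize("kind", all_kinds())
def test_resource_type_and_profile_url(kind):
    doc = json.loads(to_fhir_json(make_profile(kind)))
    assert doc["resourceType"] == EXPECTED_RESOURCE_TYPES[kind]
    assert doc["meta"]["profile"] == [kind_spec(kind).profile_url]


def test_equal_profiles_serialize_to_identical_bytes():
    a = make_profile("GenomicVariant", "var:1")
    b = make_profile("GenomicVariant", "var:1")
    b.fields = dict(reversed(list(b.fields.items())))  # different dict order
    assert a == b
    assert to_fhir_json(a) == to_fhir_json(b)


def test_invalid_profile_refuses_to_serialize(variant_profile):
    del variant_profile.fields["gene"]
    with pytest.raises(ProfileValidationError) as err:
        to_fhir_json(variant_profile)
    assert any(f.field_path == "gene" for f in err.value.report.errors())


def _random_valid_profile(rng: random.Random) -> McodeProfile:
    kind = rng.choice(all_kinds())
    p = make_profile(kind, f"{kind.lower()}:{rng.randrange(10**6)}")
    # knock out a random subset of must-support fields, cover with reasons
    for name in kind_spec(kind).must_support_fields:
        if rng.random() < 0.4:
            del p.fields[name]
            p = apply_data_absent_reason(
                p, name, rng.choice(["unknown", "masked", "not-performed", "not-asked"])
            )
    if rng.random() < 0.5:
        p = attach_extension(p, "resource", NS + "note", rng.choice(
            ["free text", 3, 2.5, True,
             CodedValue(system="urn:test", code="c1", display="C One")]
        ))
    return p


@pytest.mark.parametrize("seed", range(25))
def test_fhir_json_round_trip_identity(seed):
    """from_fhir_json(to_fhir_json(p)) == p over randomized valid profiles."""
    p = _random_valid_profile(random.Random(seed))
    text = to_fhir_json(p)
    again = from_fhir_json(text)
    assert again == p
    assert to_fhir_json(again) == text


@settings(derandomize=True, max_examples=40, deadline=None)
@given(st.integers(min_value=0, max_value=10**9))
def test_fhir_json_round_trip_property(entropy):
    """Serialization is a bijection on valid profiles (property form)."""
    p = _random_valid_profile(random.Random(entropy))
    assert from_fhir_json(to_fhir_json(p)) == p


def test_data_absent_reason_emitted_as_fhir_extension(variant_profile):
    del variant_profile.fields["gene"]
    p = apply_data_absent_reason(variant_profile, "gene", "masked")
    doc = json.loads(to_fhir_json(p))
    gene_comp = [
        c for c in doc["component"]
        if c["code"]["coding"][0]["code"] == "48018-6"
    ]
    assert gene_comp and gene_comp[0]["dataAbsentReason"]["coding"][0]["code"] == "masked"


def test_unknown_resource_type_rejected():
    text = json.dumps({
        "resourceType": "Medication", "id": "m1",
        "meta": {"profile": ["http://example.org/not-ours"]},
    })
    with pytest.raises(UnknownKindError):
        from_fhir_json(text)


def test_missing_meta_profile_rejected():
    with pytest.raises(MissingProfileUrlError):
        from_fhir_json(json.dumps({"resourceType": "Patient", "id": "p"}))


def test_truncated_json_rejected(variant_profile):
    with pytest.raises(MalformedJsonError):
        from_fhir_json(to_fhir_json(variant_profile)[:-10])


# ---------------------------------------------------------------------------
# bundles and NDJSON

def test_bundle_rejects_duplicate_ids():
    bundle = ProfileBundle([make_profile("CancerPatient", "pat:1"),
                            make_profile("CancerPatient", "pat:1")])
    with pytest.raises(Exception, match="duplicate"):
        bundle.validate()


def test_bundle_result_refs_must_point_at_variants():
    rep = make_profile("GenomicsReport", "rep:1", subject_ref="pat:1")
    rep.fields["result_refs"] = ["spe:1"]
    rep.fields["region_refs"] = ["reg:1"]
    bundle = ProfileBundle([
        make_profile("CancerPatient", "pat:1"),
        rep,
        make_profile("GenomicSpecimen", "spe:1", subject_ref="pat:1"),
        make_profile("GenomicRegionStudied", "reg:1", subject_ref="pat:1"),
    ])
    # specimen_ref from make_profile points at spe:SP1 which is absent; fix it
    rep.fields["specimen_ref"] = "spe:1"
    with pytest.raises(Exception, match="result_refs"):
        bundle.validate()


def test_ndjson_round_trip(tmp_path):
    bundle = ProfileBundle([
        make_profile("CancerPatient", "pat:1"),
        make_profile("GenomicVariant", "var:1", subject_ref="pat:1"),
    ])
    path = tmp_path / "bundle.ndjson"
    assert write_bundle_ndjson(bundle, path) == 2
    again = read_bundle_ndjson(path)
    assert again.profiles == bundle.profiles
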