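from datetime import datetime, timedelta, timezone

import pytest

from strokeaudit.model import (
    ArchetypeSchema, ElementDef, Entry, PatientCase, SchemaError,
    SchemaRegistry, get_value, set_element, validate_case,
)
from strokeaudit.values import CodedText, DateTime, Quantity
from strokeaudit.knowledge import criteria as C

UTC = timezone.utc
T0 = datetime(2014, 3, 1, 12, 0, tzinfo=UTC)


def _glucose_entry(magnitude=2.9, unit="mmol/l", path=C.GLUCOSE_VALUE):
    return Entry(C.GLUCOSE_OBS, "OBSERVATION", T0,
                 {path: Quantity(magnitude, unit)})


def test_shipped_registry_has_sixteen_schemas(registry):
    assert len(registry) == 16


def test_duplicate_registration_is_an_error():
    reg = SchemaRegistry()
    schema = ArchetypeSchema("a.b", "OBSERVATION")
    reg.register_schema(schema)
    with pytest.raises(SchemaError):
        reg.register_schema(schema)


def test_empty_schema_accepts_entry_of_matching_type():
    reg = SchemaRegistry()
    reg.register_schema(ArchetypeSchema("a.empty", "OBSERVATION"))
    ok = Entry("a.empty", "OBSERVATION", T0, {})
    assert reg.validate_entry(ok) == []
    wrong = Entry("a.empty", "ACTION", T0, {})
    assert [v.kind for v in reg.validate_entry(wrong)] == ["entry_type"]


def test_malformed_path_rejected():
    with pytest.raises(SchemaError):
        ElementDef("data[at0001]", "count")


def test_validate_entry_accepts_glucose_in_expected_unit(registry):
    assert registry.validate_entry(_glucose_entry(2.9, "mmol/l")) == []


def test_validate_entry_flags_unit_mismatch(registry):
    violations = registry.validate_entry(_glucose_entry(52.0, "mg/dl"))
    assert [v.kind for v in violations] == ["unit"]


def test_validate_entry_flags_unknown_path(registry):
    violations = registry.validate_entry(
        _glucose_entry(path="/data[at0001]/items[at9999]"))
    assert [v.kind for v in violations] == ["path"]


def test_validate_entry_rejects_item_tree_instantiation(registry):
    e = Entry("openEHR-EHR-ITEM_TREE.imaging", "ITEM_TREE", T0, {})
    assert [v.kind for v in registry.validate_entry(e)] == ["entry_type"]


def test_slot_flattening_exposes_prefixed_paths(registry):
    defs = registry.element_defs(C.PROCEDURE)
    assert C.GAS_DELIVERY in defs
    assert defs[C.GAS_DELIVERY].codes["at0006"] == "Nasal canula"


def test_get_value_multiplicity_and_event_time_order():
    e1 = Entry(C.DIAGNOSIS, "EVALUATION", T0,
               {C.DIAG_CODE: CodedText("ICD10", "I64")})
    e2 = Entry(C.DIAGNOSIS, "EVALUATION", T0 - timedelta(days=1),
               {C.DIAG_CODE: CodedText("SNOMED-CT", "230690007")})
    case = PatientCase("x", T0, (e1, e2))
    values = get_value(case, C.DIAGNOSIS, C.DIAG_CODE)
    assert values == [CodedText("SNOMED-CT", "230690007"), CodedText("ICD10", "I64")]


def test_get_value_missing_archetype_yields_empty_list():
    case = PatientCase("x", T0, ())
    assert get_value(case, C.IMAGING, C.IMG_FINDINGS) == []


def test_get_value_reads_imaging_findings_coded_text():
    e = Entry(C.IMAGING, "INSTRUCTION", T0, {
        C.IMG_FINDINGS: CodedText("SNOMED-CT", "50960005", "Haemorrhage"),
        C.IMG_SITE: CodedText("SNOMED-CT", "12738006", "Brain"),
    })
    case = PatientCase("x", T0, (e,))
    assert get_value(case, C.IMAGING, C.IMG_FINDINGS) == \
        [CodedText("SNOMED-CT", "50960005")]


def test_set_element_replaces_value_in_matching_entries():
    case = PatientCase("x", T0, (_glucose_entry(5.0),))
    updated = set_element(case, C.GLUCOSE_OBS, C.GLUCOSE_VALUE,
                          Quantity(2.5, "mmol/l"))
    assert get_value(updated, C.GLUCOSE_OBS, C.GLUCOSE_VALUE) == \
        [Quantity(2.5, "mmol/l")]
    with pytest.raises(SchemaError):
        set_element(case, C.NIHSS_OBS, C.NIHSS_TOTAL, Quantity(1, "x"))


def test_validate_case_flags_mixed_timezone_discipline(registry):
    naive = Entry(C.DIAGNOSIS, "EVALUATION", datetime(2014, 3, 1, 10, 0),
                  {C.DIAG_ONSET: DateTime(datetime(2014, 3, 1, 9, 0))})
    case = PatientCase("x", T0, (naive,))
    assert any(v.kind == "timezone" for v in validate_case(case, registry))


def test_validate_case_warns_on_entry_after_reference_time(registry):
    late = Entry(C.GLUCOSE_OBS, "OBSERVATION", T0 + timedelta(hours=1),
                 {C.GLUCOSE_VALUE: Quantity(5.0, "mmol/l")})
    case = PatientCase("x", T0, (late,))
    assert any(v.kind == "reference_time" for v in validate_case(case, registry))
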