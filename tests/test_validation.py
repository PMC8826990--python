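"""Edit checks: typed coercion, record-level validation, double entry."""

import pytest
from hypothesis import given, settings, strategies as st

from ecrfkit import (
    MISSING,
    UNANSWERED,
    FieldDefinition,
    LengthSpec,
    RangeSpec,
    RecordPayload,
    compare_double_entry,
    validate_record,
    validate_value,
)
from conftest import GOOD_PAYLOAD, demo_fields, make_revision, mls, yn_choices


def field_by_name(name):
    return next(f for f in demo_fields() if f.field_name == name)


def rule_ids(findings):
    return [f.rule_id for f in findings]


class TestValidateValue:
    @pytest.mark.parametrize(
        "name,raw,expected",
        [
            ("AGE", "42", 42.0),
            ("SEX", "2", "2"),
            ("VISIT_DATE", "2021-03-04", "2021-03-04"),
            ("ONSET", "2020-05", "2020-05"),  # partial date on lenient picker
            ("ONSET", "2020", "2020"),
            ("WAKE", "23:59", "23:59"),
            ("WEIGHT", "72.5", 72.5),
            ("NOTES", "short", "short"),
        ],
    )
    def test_clean_values(self, name, raw, expected):
        value, findings = validate_value(field_by_name(name), raw)
        assert findings == []
        assert value == expected

    @pytest.mark.parametrize(
        "name,raw,rule",
        [
            ("AGE", "150", "RANGE"),
            ("AGE", "abc", "TYPE"),
            ("AGE", "1234", "LENGTH"),
            ("WEIGHT", "72.55", "LENGTH"),   # decimals limit 1
            ("WEIGHT", "72.34", "LENGTH"),
            ("SEX", "9", "CHOICE"),
            ("VISIT_DATE", "2021-13-01", "DATE_FORMAT"),
            ("VISIT_DATE", "2021-02-30", "DATE_FORMAT"),
            ("ONSET", "2020-13", "DATE_FORMAT"),
            ("WAKE", "24:00", "TIME_FORMAT"),
            ("WAKE", "9:00", "TIME_FORMAT"),
            ("NOTES", "12345678901", "LENGTH"),
        ],
    )
    def test_single_rule_violations(self, name, raw, rule):
        value, findings = validate_value(field_by_name(name), raw)
        assert rule_ids(findings) == [rule]
        assert value is UNANSWERED

    def test_step_divisibility(self):
        age = field_by_name("AGE")  # step 1
        assert rule_ids(validate_value(age, "41.5")[1]) == ["RANGE"]
        weight = field_by_name("WEIGHT")  # step 0.1
        assert validate_value(weight, "72.4")[1] == []

    def test_multicheckbox_accepts_set_of_keys(self):
        f = FieldDefinition("MC", mls("Pick"), 1, "multiCheckbox", "T",
                            choices=yn_choices("a", "b", "c"))
        assert validate_value(f, "a,c")[0] == ("a", "c")
        assert rule_ids(validate_value(f, "a,zz")[1]) == ["CHOICE"]

    def test_pin_requires_digits(self):
        f = FieldDefinition("PIN", mls("Pin"), 1, "pin", "T", length=LengthSpec(4))
        assert validate_value(f, "1234")[0] == "1234"
        assert rule_ids(validate_value(f, "12a4")[1]) == ["TYPE"]

    def test_missing_flag(self):
        weight = field_by_name("WEIGHT")  # allow_missing
        assert validate_value(weight, "", missing_flag=True)[0] is MISSING
        # value and missing flag together conflict
        assert rule_ids(validate_value(weight, "70", missing_flag=True)[1]) == [
            "MISSING_CONFLICT"
        ]
        age = field_by_name("AGE")  # missing not allowed
        assert rule_ids(validate_value(age, "", missing_flag=True)[1]) == [
            "MISSING_CONFLICT"
        ]


class TestValidateRecord:
    def test_finding_free_payload(self, revision):
        clean, findings = validate_record(revision, RecordPayload(values=dict(GOOD_PAYLOAD)))
        assert findings == []
        assert clean.values["AGE"] == 42.0
        assert clean.values["PREGNANT"] is UNANSWERED  # hidden for SEX=1

    def test_required_visible_field_missing(self, revision):
        payload = RecordPayload(values={k: v for k, v in GOOD_PAYLOAD.items() if k != "AGE"})
        _, findings = validate_record(revision, payload)
        assert [(f.field_name, f.rule_id) for f in findings] == [("AGE", "REQUIRED")]

    def test_required_hidden_field_not_enforced(self, revision):
        # PREGNANT is required but hidden when SEX=1
        _, findings = validate_record(revision, RecordPayload(values=dict(GOOD_PAYLOAD)))
        assert all(f.field_name != "PREGNANT" for f in findings)

    def test_missing_flag_satisfies_required(self, revision):
        values = {k: v for k, v in GOOD_PAYLOAD.items() if k != "WEIGHT"}
        clean, findings = validate_record(
            revision, RecordPayload(values=values, missing={"WEIGHT"})
        )
        assert findings == []
        assert clean.values["WEIGHT"] is MISSING

    def test_hidden_value_flagged_and_cleared(self, revision):
        payload = RecordPayload(values={**GOOD_PAYLOAD, "PREGNANT": "1"})  # SEX=1
        clean, findings = validate_record(revision, payload)
        assert ("PREGNANT", "HIDDEN_VALUE") in [(f.field_name, f.rule_id) for f in findings]
        assert clean.values["PREGNANT"] is UNANSWERED

    def test_unknown_field_finding(self, revision):
        payload = RecordPayload(values={**GOOD_PAYLOAD, "NOPE": "1"})
        _, findings = validate_record(revision, payload)
        assert ("NOPE", "UNKNOWN_FIELD") in [(f.field_name, f.rule_id) for f in findings]

    def test_default_fills_untouched_field_only(self):
        fields = (
            FieldDefinition("A", mls("A"), 1, "input", "N", default_value="5",
                            value_range=RangeSpec(0, 10, 1)),
            FieldDefinition("B", mls("B"), 2, "input", "T", subquestion="A = 5"),
        )
        rev = make_revision(fields)
        clean, findings = validate_record(rev, RecordPayload())
        assert findings == []
        assert clean.values["A"] == 5.0
        assert clean.visibility["B"] is True  # default drives skip logic
        clean, _ = validate_record(rev, RecordPayload(values={"A": "7"}))
        assert clean.values["A"] == 7.0
        assert clean.visibility["B"] is False

    def test_fixed_point_revalidation(self, revision):
        payload = RecordPayload(
            values={"SEX": "2", "AGE": "30", "PREGNANT": "1", "PREG_WEEKS": "12",
                    "VISIT_DATE": "2021-06-01"},
            missing={"WEIGHT"},
        )
        clean, findings = validate_record(revision, payload)
        assert findings == []
        values, missing = clean.serialized_values()
        clean2, findings2 = validate_record(
            revision, RecordPayload(values=values, missing=missing)
        )
        assert findings2 == []
        assert clean2.values == clean.values

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        payload=st.dictionaries(
            st.sampled_from([f.field_name for f in demo_fields()] + ["JUNK"]),
            st.text(max_size=12),
            max_size=8,
        ),
        missing=st.sets(st.sampled_from(["WEIGHT", "AGE", "JUNK"]), max_size=3),
    )
    def test_never_raises_on_arbitrary_text(self, payload, missing):
        rev = make_revision()
        clean, findings = validate_record(
            rev, RecordPayload(values=payload, missing=missing)
        )
        assert set(clean.values) == set(rev.field_names())
        for f in findings:
            assert f.severity in ("error", "warning")


class TestDoubleEntry:
    def _payload(self, ssn="123-45-6789", age="42"):
        return RecordPayload(values={**GOOD_PAYLOAD, "AGE": age, "SSN": ssn})

    def test_identical_entries_no_discrepancy(self, revision):
        assert compare_double_entry(self._payload(), self._payload(), revision) == []

    def test_double_entry_field_difference_reported(self, revision):
        out = compare_double_entry(
            self._payload(ssn="123-45-6789"), self._payload(ssn="999-99-9999"), revision
        )
        assert len(out) == 1
        assert out[0].field_name == "SSN"
        assert (out[0].first, out[0].second) == ("123-45-6789", "999-99-9999")

    def test_non_double_entry_difference_ignored(self, revision):
        out = compare_double_entry(
            self._payload(age="42"), self._payload(age="43"), revision
        )
        assert out == []
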