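"""Shared fixtures: a small handcrafted demographics-style form and a
deterministic clock, plus generator-backed study configurations."""

from __future__ import annotations

from datetime import datetime, timedelta, timezone

import pytest

from ecrfkit import (
    CRFDefinition,
    CRFRevision,
    CRFVersion,
    Choice,
    FieldDefinition,
    Fieldset,
    LengthSpec,
    MLSText,
    RangeSpec,
    Study,
    StudyConfig,
    StudyEventDef,
)

T0 = datetime(2021, 1, 1, tzinfo=timezone.utc)


def mls(text: str, **tr: str) -> MLSText:
    return MLSText.of(text, **tr)


class TickingClock:
    """Deterministic clock advancing one second per call."""

    def __init__(self, start: datetime = T0):
        self.now = start

    def __call__(self) -> datetime:
        self.now += timedelta(seconds=1)
        return self.now


def yn_choices(*keys: str) -> tuple[Choice, ...]:
    return tuple(Choice(key=k, label=mls(f"Option {k}")) for k in keys)


def demo_fields() -> tuple[FieldDefinition, ...]:
    return (
        FieldDefinition("SEX", mls("Sex"), 1, "radio", "T", required=True,
                        choices=yn_choices("1", "2")),
        FieldDefinition("AGE", mls("Age"), 2, "input", "N", required=True,
                        value_range=RangeSpec(0, 100, 1), length=LengthSpec(3),
                        units=mls("years")),
        FieldDefinition("PREGNANT", mls("Pregnant?"), 3, "radio", "T", required=True,
                        choices=yn_choices("1", "2"), subquestion="SEX = 2"),
        FieldDefinition("PREG_WEEKS", mls("Gestation weeks"), 4, "input", "N",
                        value_range=RangeSpec(1, 45, 1), subquestion="PREGNANT = 1",
                        indent=1),
        FieldDefinition("VISIT_DATE", mls("Visit date"), 5, "datepickerStrict", "D",
                        required=True),
        FieldDefinition("ONSET", mls("Symptom onset"), 6, "datepicker", "D"),
        FieldDefinition("WAKE", mls("Wake time"), 7, "timepicker24", "T"),
        FieldDefinition("WEIGHT", mls("Weight"), 8, "input", "N", required=True,
                        allow_missing=True, value_range=RangeSpec(30, 200, 0.1),
                        length=LengthSpec(5, 1), units=mls("kg")),
        FieldDefinition("NOTES", mls("Notes"), 9, "textarea", "T",
                        length=LengthSpec(10)),
        FieldDefinition("SSN", mls("National id"), 10, "input", "T", phi=True,
                        double_entry=True),
    )


def make_revision(fields=None, revision_no: int = 1,
                  activated_at: datetime = T0) -> CRFRevision:
    return CRFRevision(
        revision_no=revision_no,
        activated_at=activated_at,
        fieldsets=(
            Fieldset(
                title=mls("Demographics"),
                fields=tuple(demo_fields() if fields is None else fields),
            ),
        ),
    )


def make_config(revisions=None, crf_kwargs=None, extra_crfs=()) -> StudyConfig:
    crf = CRFDefinition(
        crf_name="DEMOG",
        crf_label="Demographics",
        versions=(CRFVersion("v1", tuple(revisions or (make_revision(),))),),
        **(crf_kwargs or {}),
    )
    crfs = (crf, *extra_crfs)
    return StudyConfig(
        study_id="TEST01",
        study_label="Test study",
        events=(
            StudyEventDef("BL", "Baseline", 1, required_crfs=("DEMOG",)),
            StudyEventDef("M06", "Month 6", 2, required_crfs=("DEMOG",)),
        ),
        crfs=crfs,
        sites=("S01", "S02"),
        languages=("en",),
    )


GOOD_PAYLOAD = {
    "SEX": "1",
    "AGE": "42",
    "VISIT_DATE": "2021-03-04",
    "WEIGHT": "72.5",
}


@pytest.fixture
def revision():
    return make_revision()


@pytest.fixture
def config():
    return make_config()


@pytest.fixture
def clock():
    return TickingClock()


@pytest.fixture
def study(config, clock):
    return Study(config, b"test-secret", clock=clock)
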