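"""Study configuration domain model.

An electronic case report form (eCRF) is described entirely by metadata:
which fields it carries, how each is typed, constrained, and rendered,
and which conditional visibility (skip-pattern) rules apply.  A study
configuration bundles the schedule of events, the eCRF definitions with
their version/revision history, the trial sites and the supported
languages.  Every other part of the package is driven by these objects.

Numeric range constraints use the ``<min>…<max>[:<step>]`` template and
field length constraints the ``<total>[,<decimals>]`` template.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Optional, Sequence

from .errors import ConfigParseError, EdcError, NotFoundError
from .mls import MLSText

#: Recognised field input widgets.
WIDGETS = (
    "select",
    "multiCheckbox",
    "input",
    "textarea",
    "radio",
    "radioHorizontal",
    "pin",
    "datepickerStrict",
    "datepicker",
    "timepicker24",
)

#: Widgets whose admissible values come from a key/label choice list.
CHOICE_WIDGETS = frozenset({"select", "multiCheckbox", "radio", "radioHorizontal"})

#: Field data types: (T)ext, (N)umeric, (D)ate.
DTYPES = ("T", "N", "D")

#: Relative tolerance when testing (value - min) divisibility by step.
STEP_RTOL = 1e-9


@dataclass(frozen=True)
class RangeSpec:
    """Admissible range for a numeric field: min ≤ v ≤ max, optionally on a
    step grid anchored at min."""

    min: float
    max: float
    step: Optional[float] = None

    def __post_init__(self):
        object.__setattr__(self, "min", float(self.min))
        object.__setattr__(self, "max", float(self.max))
        if self.step is not None:
            object.__setattr__(self, "step", float(self.step))
        if self.min > self.max:
            raise ConfigParseError(f"range min {self.min} > max {self.max}")
        if self.step is not None and self.step <= 0:
            raise ConfigParseError(f"range step must be positive, got {self.step}")

    def admits(self, value: float) -> bool:
        if not (self.min <= value <= self.max):
            return False
        if self.step is None:
            return True
        k = (value - self.min) / self.step
        scale = max(abs(value), abs(self.min), abs(self.step), 1.0)
        return abs(k - round(k)) * self.step <= STEP_RTOL * scale

    def as_text(self) -> str:
        def fmt(x: float) -> str:
            return str(int(x)) if float(x).is_integer() else repr(x)

        text = f"{fmt(self.min)}…{fmt(self.max)}"
        if self.step is not None:
            text += f":{fmt(self.step)}"
        return text


@dataclass(frozen=True)
class LengthSpec:
    """Maximum field length: total significant characters, and for numeric
    fields an optional maximum number of decimal places."""

    total: int
    decimals: Optional[int] = None

    def __post_init__(self):
        if self.total <= 0:
            raise ConfigParseError(f"length total must be positive, got {self.total}")
        if self.decimals is not None:
            if self.decimals < 0:
                raise ConfigParseError("length decimals must be non-negative")
            if self.decimals >= self.total:
                raise ConfigParseError(
                    f"length decimals {self.decimals} must be < total {self.total}"
                )

    def as_text(self) -> str:
        if self.decimals is None:
            return str(self.total)
        return f"{self.total},{self.decimals}"


_RANGE_RE = re.compile(
    r"^\s*(?P<min>[^…]*?)\s*(?:…|\.\.\.)\s*(?P<max>[^:]*?)\s*(?::\s*(?P<step>.*?)\s*)?$"
)


def parse_range_spec(text: str) -> RangeSpec:
    """Parse a numeric range written ``<min>…<max>`` or ``<min>…<max>:<step>``.

    ``...`` is accepted as a synonym of the ellipsis character.  Without a
    step, any value in [min, max] is admissible.
    """
    if "…" not in text and "..." not in text:
        raise ConfigParseError(f"range {text!r}: missing '…' separator")
    m = _RANGE_RE.match(text)
    if m is None:
        raise ConfigParseError(f"range {text!r}: malformed")
    parts = {}
    for name in ("min", "max", "step"):
        token = m.group(name)
        if name == "step" and token is None:
            parts[name] = None
            continue
        try:
            parts[name] = float(token)
        except (TypeError, ValueError):
            raise ConfigParseError(f"range {text!r}: non-numeric {name} {token!r}")
    return RangeSpec(min=parts["min"], max=parts["max"], step=parts["step"])


def parse_length_spec(text: str, dtype: str) -> LengthSpec:
    """Parse a length constraint: ``N,D`` for numeric fields, ``N`` otherwise.

    Date fields carry no length constraint; supplying one is an error.
    """
    if dtype == "D":
        raise ConfigParseError(f"length {text!r}: date fields take no length spec")
    parts = [p.strip() for p in text.split(",")]
    if dtype != "N" and len(parts) > 1:
        raise ConfigParseError(f"length {text!r}: decimals only valid for numeric fields")
    if len(parts) > 2:
        raise ConfigParseError(f"length {text!r}: too many components")
    try:
        total = int(parts[0])
        decimals = int(parts[1]) if len(parts) == 2 else None
    except ValueError:
        raise ConfigParseError(f"length {text!r}: non-integer component")
    return LengthSpec(total=total, decimals=decimals)


@dataclass(frozen=True)
class Choice:
    key: str
    label: MLSText


@dataclass(frozen=True)
class FieldDefinition:
    field_name: str
    question: MLSText
    order: int
    widget: str
    dtype: str
    units: Optional[MLSText] = None
    notes: Optional[MLSText] = None
    value_range: Optional[RangeSpec] = None
    required: bool = False
    allow_missing: bool = False
    length: Optional[LengthSpec] = None
    phi: bool = False
    indent: int = 0
    subquestion: Optional[str] = None
    default_value: Optional[str] = None
    double_entry: bool = False
    choices: tuple[Choice, ...] = ()

    def __post_init__(self):
        if self.widget not in WIDGETS:
            raise ConfigParseError(f"unknown widget {self.widget!r}")
        if self.dtype not in DTYPES:
            raise ConfigParseError(f"unknown field type {self.dtype!r}")
        if self.indent < 0:
            raise ConfigParseError("indent must be non-negative")
        object.__setattr__(self, "choices", tuple(self.choices))

    @property
    def has_choices(self) -> bool:
        return self.widget in CHOICE_WIDGETS

    def choice_keys(self) -> tuple[str, ...]:
        return tuple(c.key for c in self.choices)


@dataclass(frozen=True)
class Fieldset:
    title: MLSText
    fields: tuple[FieldDefinition, ...]
    description: Optional[MLSText] = None

    def __post_init__(self):
        ordered = sorted(
            enumerate(self.fields), key=lambda pair: (pair[1].order, pair[0])
        )
        object.__setattr__(self, "fields", tuple(f for _, f in ordered))


@dataclass(frozen=True)
class FileAttachmentDefinition:
    name: str
    label: MLSText
    restrictions: tuple[str, ...] = ()  # permitted extensions; empty = any


@dataclass(frozen=True)
class CRFRevision:
    revision_no: int
    fieldsets: tuple[Fieldset, ...]
    activated_at: datetime
    form_subtitle: Optional[MLSText] = None
    form_instruction: Optional[MLSText] = None
    attachments: tuple[FileAttachmentDefinition, ...] = ()

    def __post_init__(self):
        ts = self.activated_at
        if ts.tzinfo is None:
            object.__setattr__(self, "activated_at", ts.replace(tzinfo=timezone.utc))
        object.__setattr__(self, "fieldsets", tuple(self.fieldsets))

    def iter_fields(self):
        for fs in self.fieldsets:
            yield from fs.fields

    @property
    def fields(self) -> tuple[FieldDefinition, ...]:
        return tuple(self.iter_fields())

    def field_names(self) -> tuple[str, ...]:
        return tuple(f.field_name for f in self.iter_fields())

    def field(self, name: str) -> FieldDefinition:
        for f in self.iter_fields():
            if f.field_name == name:
                return f
        raise NotFoundError(f"field {name!r} not in revision {self.revision_no}")


@dataclass(frozen=True)
class CRFVersion:
    v_version: str
    revisions: tuple[CRFRevision, ...]

    def __post_init__(self):
        object.__setattr__(
            self, "revisions", tuple(sorted(self.revisions, key=lambda r: r.revision_no))
        )

    def active_revision(self, at: datetime) -> Optional[CRFRevision]:
        """Latest revision activated at or before ``at``, if any."""
        live = [r for r in self.revisions if r.activated_at <= at]
        return live[-1] if live else None


@dataclass(frozen=True)
class CRFDefinition:
    crf_name: str
    crf_label: str
    versions: tuple[CRFVersion, ...]
    allow_multiple_entry: bool = False
    is_cross_events: bool = False
    allow_change_version: bool = False
    log_menu_fields: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "versions", tuple(self.versions))
        object.__setattr__(self, "log_menu_fields", tuple(self.log_menu_fields))

    def version(self, name: str) -> CRFVersion:
        for v in self.versions:
            if v.v_version == name:
                return v
        raise NotFoundError(f"version {name!r} not in CRF {self.crf_name}")


@dataclass(frozen=True)
class StudyEventDef:
    event_code: str
    label: str
    order: int
    required_crfs: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "required_crfs", tuple(self.required_crfs))


@dataclass(frozen=True)
class StudyConfig:
    study_id: str
    study_label: str
    events: tuple[StudyEventDef, ...]
    crfs: tuple[CRFDefinition, ...]
    sites: tuple[str, ...]
    languages: tuple[str, ...]  # first entry is the default language

    def __post_init__(self):
        if not self.study_id:
            raise ConfigParseError("study_id must be nonempty")
        object.__setattr__(
            self, "events", tuple(sorted(self.events, key=lambda e: e.order))
        )
        object.__setattr__(self, "crfs", tuple(self.crfs))
        object.__setattr__(self, "sites", tuple(self.sites))
        langs = tuple(self.languages) or ("en",)
        object.__setattr__(self, "languages", langs)

    @property
    def default_language(self) -> str:
        return self.languages[0]

    def crf(self, crf_name: str) -> CRFDefinition:
        for c in self.crfs:
            if c.crf_name == crf_name:
                return c
        raise NotFoundError(f"CRF {crf_name!r} not in study {self.study_id}")

    def event(self, event_code: str) -> StudyEventDef:
        for e in self.events:
            if e.event_code == event_code:
                return e
        raise NotFoundError(f"event {event_code!r} not in study {self.study_id}")


def resolve_version(
    crf: CRFDefinition,
    record_created_at: datetime,
    user_choice: str | None = None,
) -> tuple[CRFVersion, CRFRevision]:
    """Pick the eCRF version/revision governing a record created at a time.

    If the CRF allows user version choice and one is given, that version is
    used; otherwise the system selects the version whose latest activated
    revision (≤ creation time) is the most recent.  Within the version the
    latest activated revision applies.  Selection is prospective: it is a
    pure function of the creation timestamp, so existing records never
    re-resolve when newer revisions are activated later.
    """
    if record_created_at.tzinfo is None:
        record_created_at = record_created_at.replace(tzinfo=timezone.utc)
    if user_choice is not None:
        if not crf.allow_change_version:
            raise EdcError(
                f"CRF {crf.crf_name} does not allow user version choice",
                code="VERSION_CHOICE_FORBIDDEN",
            )
        version = crf.version(user_choice)
        revision = version.active_revision(record_created_at)
        if revision is None:
            raise EdcError(
                f"version {user_choice!r} of {crf.crf_name} has no active revision",
                code="NO_ACTIVE_REVISION",
            )
        return version, revision

    best: tuple[CRFVersion, CRFRevision] | None = None
    for version in crf.versions:
        revision = version.active_revision(record_created_at)
        if revision is None:
            continue
        if best is None or revision.activated_at > best[1].activated_at:
            best = (version, revision)
    if best is None:
        raise EdcError(
            f"CRF {crf.crf_name} has no revision active at {record_created_at}",
            code="NO_ACTIVE_REVISION",
        )
    return best
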