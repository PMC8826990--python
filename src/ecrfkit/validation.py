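"""Edit-check and skip-pattern validation engine.

Raw text payloads submitted for an eCRF revision are checked against the
revision's metadata: data-type coercion, numeric range and step, length,
choice-key membership, date/time formats, required-ness and conditional
visibility.  Problems are reported as findings, never exceptions, so a
site user always gets a complete error list and entry cannot deadlock.

Two sentinels distinguish the reasons a clean value can be absent:
``MISSING`` (the site explicitly checked the missing box, only legal on
fields that allow it) and ``UNANSWERED`` (no value supplied, or the
field is hidden by a skip pattern).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field as dc_field
from datetime import date
from typing import Callable, Mapping, Optional

from .conditions import SkipCondition, parse_condition
from .errors import ConfigParseError, EdcError
from .model import CRFRevision, FieldDefinition

RULE_IDS = (
    "TYPE",
    "RANGE",
    "LENGTH",
    "CHOICE",
    "DATE_FORMAT",
    "TIME_FORMAT",
    "REQUIRED",
    "HIDDEN_VALUE",
    "MISSING_CONFLICT",
    "UNKNOWN_FIELD",
)


class _Sentinel:
    __slots__ = ("name",)

    def __init__(self, name: str):
        self.name = name

    def __repr__(self) -> str:
        return self.name

    def __deepcopy__(self, memo):
        return self


#: Explicitly collected as missing (missing checkbox checked).
MISSING = _Sentinel("MISSING")
#: No value: hidden by a skip pattern, or simply not answered.
UNANSWERED = _Sentinel("UNANSWERED")


@dataclass
class RecordPayload:
    """Raw site input for one record: field → text value, plus the set of
    fields whose missing checkbox was checked."""

    values: dict[str, str] = dc_field(default_factory=dict)
    missing: set[str] = dc_field(default_factory=set)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, object],
                     missing_token: str = "MISSING") -> "RecordPayload":
        """Build a payload from a flat mapping (CSV/JSON batch rows); a cell
        equal to ``missing_token`` sets the missing flag instead."""
        values: dict[str, str] = {}
        missing: set[str] = set()
        for k, v in mapping.items():
            if v is None:
                continue
            text = str(v)
            if text == missing_token:
                missing.add(k)
            else:
                values[k] = text
        return cls(values=values, missing=missing)


@dataclass(frozen=True)
class ValidationFinding:
    field_name: Optional[str]  # None = whole-record finding
    rule_id: str
    severity: str  # "error" | "warning"
    message: str


@dataclass
class CleanRecord:
    values: dict[str, object]  # typed value | MISSING | UNANSWERED
    visibility: dict[str, bool]

    def serialized_values(self) -> tuple[dict[str, str], set[str]]:
        """Raw-text form of the clean values, suitable for re-validation."""
        values: dict[str, str] = {}
        missing: set[str] = set()
        for name, v in self.values.items():
            if v is UNANSWERED:
                continue
            if v is MISSING:
                missing.add(name)
            else:
                values[name] = serialize_value(v)
        return values, missing


def serialize_value(v: object) -> str:
    if isinstance(v, float):
        return str(int(v)) if v.is_integer() else repr(v)
    if isinstance(v, tuple):
        return ",".join(str(x) for x in v)
    return str(v)


def revision_conditions(revision: CRFRevision) -> dict[str, SkipCondition]:
    """Parsed skip conditions per field (fields without one are absent)."""
    dtypes = {f.field_name: f.dtype for f in revision.iter_fields()}
    out: dict[str, SkipCondition] = {}
    for f in revision.iter_fields():
        if f.subquestion:
            out[f.field_name] = parse_condition(f.subquestion, dtypes)
    return out


def evaluate_visibility(
    revision: CRFRevision, payload: RecordPayload | Mapping[str, str]
) -> dict[str, bool]:
    """Visibility map for every field of the revision.

    A field with no condition is visible; one with a condition is visible
    iff all its clauses hold AND every field the condition references is
    itself visible (hiding is transitive).  Missing-flagged and absent
    parents evaluate clauses false.
    """
    if isinstance(payload, RecordPayload):
        raw = dict(payload.values)
        for name in payload.missing:
            raw[name] = ""
    else:
        raw = dict(payload)
    conditions = revision_conditions(revision)
    numeric = frozenset(
        f.field_name for f in revision.iter_fields() if f.dtype == "N"
    )
    visible: dict[str, bool] = {}
    for f in revision.iter_fields():
        cond = conditions.get(f.field_name)
        if cond is None:
            visible[f.field_name] = True
            continue
        parents_ok = all(visible.get(p, True) for p in cond.referenced_fields())
        visible[f.field_name] = parents_ok and cond.evaluate(raw, numeric)
    return visible


_TIME_RE = re.compile(r"^([01][0-9]|2[0-3]):[0-5][0-9]$")
_PARTIAL_DATE_RE = re.compile(r"^\d{4}(-(0[1-9]|1[0-2]))?$")


def _numeric_digits(raw: str) -> tuple[int, int]:
    """(total significant digits, decimal digits) of a numeral string."""
    body = raw.strip().lstrip("+-")
    int_part, _, frac_part = body.partition(".")
    digits = lambda s: sum(ch.isdigit() for ch in s)
    return digits(int_part) + digits(frac_part), digits(frac_part)


def validate_value(
    field: FieldDefinition, raw: str, missing_flag: bool = False
) -> tuple[object, list[ValidationFinding]]:
    """Coerce one raw value against a field definition.

    Returns the typed clean value (or a sentinel) plus findings.  All
    findings are errors; nothing raises.
    """
    name = field.field_name
    findings: list[ValidationFinding] = []

    def err(rule: str, message: str) -> None:
        findings.append(ValidationFinding(name, rule, "error", message))

    if missing_flag:
        if raw:
            err("MISSING_CONFLICT", "missing flag set but a value was supplied")
            return UNANSWERED, findings
        if not field.allow_missing:
            err("MISSING_CONFLICT", "missing flag set on a field that does not allow it")
            return UNANSWERED, findings
        return MISSING, findings

    if raw is None or raw == "":
        return UNANSWERED, findings

    # choice widgets: admissibility is key membership, regardless of dtype
    if field.has_choices:
        keys = field.choice_keys()
        if field.widget == "multiCheckbox":
            picked = tuple(p.strip() for p in raw.split(",") if p.strip())
            bad = [p for p in picked if p not in keys]
            if bad:
                err("CHOICE", f"unknown choice key(s) {bad} (allowed: {list(keys)})")
                return UNANSWERED, findings
            return picked, findings
        if raw not in keys:
            err("CHOICE", f"unknown choice key {raw!r} (allowed: {list(keys)})")
            return UNANSWERED, findings
        return raw, findings

    if field.widget == "timepicker24":
        if not _TIME_RE.match(raw):
            err("TIME_FORMAT", f"{raw!r} is not a 24-hour HH:MM time")
            return UNANSWERED, findings
        return raw, findings

    if field.dtype == "D":
        if field.widget == "datepicker" and _PARTIAL_DATE_RE.match(raw):
            return raw, findings  # partial date: YYYY or YYYY-MM
        try:
            date.fromisoformat(raw)
        except ValueError:
            kind = "full ISO date" if field.widget == "datepickerStrict" else "ISO date"
            err("DATE_FORMAT", f"{raw!r} is not a valid {kind} (YYYY-MM-DD)")
            return UNANSWERED, findings
        return raw, findings

    if field.dtype == "N":
        try:
            value = float(raw)
        except ValueError:
            err("TYPE", f"{raw!r} is not numeric")
            return UNANSWERED, findings
        if field.length is not None:
            total, decimals = _numeric_digits(raw)
            if total > field.length.total:
                err("LENGTH", f"{raw!r} has {total} digits, limit {field.length.total}")
            elif field.length.decimals is not None and decimals > field.length.decimals:
                err(
                    "LENGTH",
                    f"{raw!r} has {decimals} decimals, limit {field.length.decimals}",
                )
        if findings:
            return UNANSWERED, findings
        if field.value_range is not None and not field.value_range.admits(value):
            err(
                "RANGE",
                f"{raw!r} outside admissible range {field.value_range.as_text()}",
            )
            return UNANSWERED, findings
        return value, findings

    # text
    if field.widget == "pin" and not raw.isdigit():
        err("TYPE", f"pin value {raw!r} must be digits only")
        return UNANSWERED, findings
    if field.length is not None and len(raw) > field.length.total:
        err("LENGTH", f"value length {len(raw)} exceeds limit {field.length.total}")
        return UNANSWERED, findings
    return raw, findings


def validate_record(
    revision: CRFRevision, payload: RecordPayload
) -> tuple[CleanRecord, list[ValidationFinding]]:
    """Validate a full payload against a revision.

    Visibility is computed first; required-ness applies only to visible
    fields; a missing flag satisfies required-ness where the field allows
    missing; values supplied for hidden fields are flagged and cleared;
    defaults fill fields the payload never touched.
    """
    findings: list[ValidationFinding] = []
    known = set(revision.field_names())
    for name in sorted(set(payload.values) | set(payload.missing)):
        if name not in known:
            findings.append(
                ValidationFinding(
                    name, "UNKNOWN_FIELD", "error", "field not in this revision"
                )
            )

    # fill defaults for untouched fields before computing visibility, so a
    # defaulted parent drives skip logic exactly as it renders on screen
    effective = RecordPayload(values=dict(payload.values), missing=set(payload.missing))
    for f in revision.iter_fields():
        touched = f.field_name in payload.values or f.field_name in payload.missing
        if not touched and f.default_value is not None:
            effective.values[f.field_name] = f.default_value

    visibility = evaluate_visibility(revision, effective)
    clean: dict[str, object] = {}
    for f in revision.iter_fields():
        name = f.field_name
        raw = effective.values.get(name, "")
        missing_flag = name in effective.missing
        if not visibility[name]:
            # only user-supplied values count as hidden-value violations;
            # a default on a hidden field is simply not applied
            if payload.values.get(name, "") or name in payload.missing:
                findings.append(
                    ValidationFinding(
                        name,
                        "HIDDEN_VALUE",
                        "error",
                        "value supplied for a field hidden by its skip pattern",
                    )
                )
            clean[name] = UNANSWERED
            continue
        value, field_findings = validate_value(f, raw, missing_flag)
        findings.extend(field_findings)
        if value is UNANSWERED and not field_findings and f.required:
            findings.append(
                ValidationFinding(name, "REQUIRED", "error", "required field unanswered")
            )
        clean[name] = value

    findings.sort(key=lambda fd: (fd.field_name or "", fd.rule_id))
    return CleanRecord(values=clean, visibility=visibility), findings


@dataclass(frozen=True)
class Discrepancy:
    field_name: str
    first: object
    second: object


def compare_double_entry(
    first: RecordPayload, second: RecordPayload, revision: CRFRevision
) -> list[Discrepancy]:
    """Field-wise comparison of two independent entries.

    Only fields configured for double entry are compared; the comparison
    runs on clean (typed) values so formatting differences don't count.
    """
    clean1, _ = validate_record(revision, first)
    clean2, _ = validate_record(revision, second)
    out: list[Discrepancy] = []
    for f in revision.iter_fields():
        if not f.double_entry:
            continue
        v1 = clean1.values[f.field_name]
        v2 = clean2.values[f.field_name]
        if v1 is not v2 and v1 != v2:
            out.append(Discrepancy(f.field_name, v1, v2))
    return out


class QualityRuleRegistry:
    """Pluggable registry of study-specific quality rules.

    A rule is a callable ``(revision, clean_record) -> list[ValidationFinding]``
    whose findings are downgraded to warnings; edit checks derived from
    the metadata dictionary stay errors.
    """

    def __init__(self) -> None:
        self._rules: dict[str, Callable] = {}

    def register(self, name: str, rule: Callable) -> None:
        if name in self._rules:
            raise EdcError(f"quality rule {name!r} already registered", code="DUPLICATE")
        self._rules[name] = rule

    def apply(self, revision: CRFRevision, clean: CleanRecord) -> list[ValidationFinding]:
        findings: list[ValidationFinding] = []
        for name in sorted(self._rules):
            for fd in self._rules[name](revision, clean):
                findings.append(
                    ValidationFinding(fd.field_name, fd.rule_id, "warning", fd.message)
                )
        return findings
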