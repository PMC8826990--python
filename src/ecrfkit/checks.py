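"""Configuration quality and consistency checks.

A parsed study configuration is examined before deployment; problems are
returned as an ordered, deterministic list of findings rather than
raised, so a study team sees everything wrong at once.  An empty list
means the configuration is deployable; the capture workflow refuses any
configuration with an error-severity finding.
"""

from __future__ import annotations

from dataclasses import dataclass

from .conditions import parse_condition
from .errors import ConfigParseError
from .model import CHOICE_WIDGETS, CRFRevision, StudyConfig
from .validation import validate_value


@dataclass(frozen=True)
class ConfigFinding:
    code: str
    location: str
    message: str
    severity: str = "error"


def validate_config(config: StudyConfig) -> list[ConfigFinding]:
    findings: list[ConfigFinding] = []

    def add(code: str, location: str, message: str) -> None:
        findings.append(ConfigFinding(code, location, message))

    seen_events: set[str] = set()
    last_order: int | None = None
    crf_names = {c.crf_name for c in config.crfs}
    for ev in config.events:
        loc = f"event:{ev.event_code}"
        if ev.event_code in seen_events:
            add("DUPLICATE_EVENT", loc, "event code defined more than once")
        seen_events.add(ev.event_code)
        if last_order is not None and ev.order <= last_order:
            add("EVENT_ORDER", loc, "event order values must be strictly increasing")
        last_order = ev.order
        for crf_name in ev.required_crfs:
            if crf_name not in crf_names:
                add("UNKNOWN_CRF", loc, f"required CRF {crf_name!r} is not defined")

    seen_sites: set[str] = set()
    for site in config.sites:
        if site in seen_sites:
            add("DUPLICATE_SITE", f"site:{site}", "site code defined more than once")
        seen_sites.add(site)

    seen_crfs: set[str] = set()
    for crf in config.crfs:
        crf_loc = f"crf:{crf.crf_name}"
        if crf.crf_name in seen_crfs:
            add("DUPLICATE_CRF", crf_loc, "CRF name defined more than once")
        seen_crfs.add(crf.crf_name)
        if crf.is_cross_events and not crf.allow_multiple_entry:
            add(
                "CROSS_EVENT_MULTI",
                crf_loc,
                "a cross-event CRF must allow multiple entry",
            )
        for version in crf.versions:
            v_loc = f"{crf_loc}/version:{version.v_version}"
            expected = list(range(1, len(version.revisions) + 1))
            if [r.revision_no for r in version.revisions] != expected:
                add(
                    "REVISION_NUMBERING",
                    v_loc,
                    "revision numbers must start at 1 and be consecutive",
                )
            prev_ts = None
            for revision in version.revisions:
                r_loc = f"{v_loc}/rev:{revision.revision_no}"
                if prev_ts is not None and revision.activated_at < prev_ts:
                    add(
                        "ACTIVATION_ORDER",
                        r_loc,
                        "activation time decreases with revision number",
                    )
                prev_ts = revision.activated_at
                findings.extend(_check_revision(revision, r_loc))
                field_names = set(revision.field_names())
                for menu_field in crf.log_menu_fields:
                    if menu_field not in field_names:
                        add(
                            "LOG_MENU_UNKNOWN",
                            r_loc,
                            f"log menu field {menu_field!r} absent from revision",
                        )
    return findings


def _check_revision(revision: CRFRevision, loc: str) -> list[ConfigFinding]:
    findings: list[ConfigFinding] = []

    def add(code: str, field: str, message: str) -> None:
        findings.append(ConfigFinding(code, f"{loc}/field:{field}", message))

    fields = list(revision.iter_fields())
    dtypes = {f.field_name: f.dtype for f in fields}
    position = {}
    seen: set[str] = set()
    for idx, f in enumerate(fields):
        if f.field_name in seen:
            add("DUPLICATE_FIELD", f.field_name, "field name repeats within revision")
        seen.add(f.field_name)
        position.setdefault(f.field_name, idx)

    for idx, f in enumerate(fields):
        name = f.field_name
        if f.has_choices and not f.choices:
            add("CHOICES_REQUIRED", name, f"widget {f.widget} needs at least one choice")
        if not f.has_choices and f.choices:
            add("CHOICES_FORBIDDEN", name, f"widget {f.widget} takes no choices")
        if f.choices:
            keys = [c.key for c in f.choices]
            if len(keys) != len(set(keys)):
                add("DUPLICATE_CHOICE_KEY", name, "choice keys must be unique")
        if f.value_range is not None and f.dtype != "N":
            add("RANGE_ON_NONNUMERIC", name, "VALUE range only valid for numeric fields")
        if f.length is not None and f.dtype == "D":
            add("LENGTH_ON_DATE", name, "LENGTH not valid for date fields")
        if f.widget == "pin" and f.dtype != "T":
            add("PIN_TYPE", name, "pin widget implies text type")
        if f.widget in ("datepicker", "datepickerStrict") and f.dtype != "D":
            add("DATE_WIDGET_TYPE", name, "date widgets imply date type")
        if f.widget == "timepicker24" and f.dtype != "T":
            add("TIME_WIDGET_TYPE", name, "timepicker24 implies text type")
        if f.default_value is not None:
            _, value_findings = validate_value(f, f.default_value)
            for vf in value_findings:
                add("DEFAULT_INVALID", name, f"default value fails {vf.rule_id}: {vf.message}")
        if f.subquestion:
            try:
                cond = parse_condition(f.subquestion, dtypes)
            except ConfigParseError as exc:
                code = "UNKNOWN_PARENT" if "unknown field" in str(exc) else "CONDITION_SYNTAX"
                add(code, name, str(exc))
                continue
            for parent in cond.referenced_fields():
                if position.get(parent, len(fields)) >= idx:
                    add(
                        "PARENT_ORDER",
                        name,
                        f"condition parent {parent!r} must precede the dependent field",
                    )
    return findings
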