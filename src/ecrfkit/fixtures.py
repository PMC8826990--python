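"""Deterministic fixtures: synthetic study configurations and simulated
multi-site data entry.

The generator builds structurally realistic configurations — a mix of
every widget class, numeric ranges, length limits, choice lists, skip
patterns, PHI flags and missing-allowed fields — with composition counts
that exactly match the requested fractions, and simulates site data
entry in which each validated field is independently corrupted with a
configurable error probability so auto queries arise organically through
the capture path.  Values are structural, not epidemiological: no claim
is made about clinical value distributions.

All randomness flows through :class:`random.Random` seeded from the
fixture spec (a fixed, versioned pseudo-random algorithm), so identical
specs produce byte-identical workbooks and ledgers with identical
digests on every platform.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone

from .capture import Study
from .errors import EdcError
from .exporting import StudySummary
from .mls import MLSText
from .model import (
    CRFDefinition,
    CRFRevision,
    CRFVersion,
    Choice,
    FieldDefinition,
    Fieldset,
    LengthSpec,
    RangeSpec,
    StudyConfig,
    StudyEventDef,
)
from .validation import RecordPayload, revision_conditions


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    n_crfs: int = 3
    fields_per_crf: int = 10
    skip_fraction: float = 0.2
    phi_fraction: float = 0.1
    allow_missing_fraction: float = 0.2
    n_sites: int = 3
    n_participants: int = 10
    n_events: int = 3
    error_rate: float = 0.1
    missing_prob: float = 0.05  # chance an allow-missing field is marked missing

    def __post_init__(self):
        for name in ("skip_fraction", "phi_fraction", "allow_missing_fraction",
                     "error_rate", "missing_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise EdcError(f"{name} must be in [0,1], got {v}", code="BAD_SPEC")
        for name in ("n_crfs", "fields_per_crf", "n_sites", "n_participants",
                     "n_events"):
            if getattr(self, name) < 0:
                raise EdcError(f"{name} must be >= 0", code="BAD_SPEC")


_EPOCH = datetime(2020, 1, 1, tzinfo=timezone.utc)

# widget templates cycled across each CRF's fields (after the choice
# parent at position 0); together they exercise every edit-check rule
_TEMPLATES = (
    "numeric",
    "text",
    "radio",
    "select",
    "dateStrict",
    "time",
    "multi",
    "date",
    "textarea",
    "pin",
)


def _make_field(template: str, name: str, order: int) -> FieldDefinition:
    q = MLSText.of(f"Question for {name}")
    common = dict(field_name=name, question=q, order=order, required=True)
    if template == "numeric":
        return FieldDefinition(widget="input", dtype="N",
                               value_range=RangeSpec(0, 100, 1), **common)
    if template == "text":
        return FieldDefinition(widget="input", dtype="T",
                               length=LengthSpec(20), **common)
    if template == "textarea":
        return FieldDefinition(widget="textarea", dtype="T",
                               length=LengthSpec(60), **common)
    if template in ("radio", "select", "multi"):
        widget = {"radio": "radio", "select": "select", "multi": "multiCheckbox"}[template]
        n_choices = {"radio": 3, "select": 4, "multi": 3}[template]
        choices = tuple(
            Choice(key=str(k), label=MLSText.of(f"Choice {k}"))
            for k in range(1, n_choices + 1)
        )
        return FieldDefinition(widget=widget, dtype="T", choices=choices, **common)
    if template == "dateStrict":
        return FieldDefinition(widget="datepickerStrict", dtype="D", **common)
    if template == "date":
        return FieldDefinition(widget="datepicker", dtype="D", **common)
    if template == "time":
        return FieldDefinition(widget="timepicker24", dtype="T", **common)
    if template == "pin":
        return FieldDefinition(widget="pin", dtype="T", length=LengthSpec(4), **common)
    raise AssertionError(template)


def generate_study_config(spec: FixtureSpec) -> StudyConfig:
    """Build a deterministic configuration with exact composition counts.

    Field 0 of every CRF is a required radio (the skip-pattern parent);
    skip, PHI and missing-allowed flags are assigned to exactly
    ``round(fraction × total_fields)`` fields each.
    """
    rng = random.Random(spec.seed)
    total_fields = spec.n_crfs * spec.fields_per_crf
    n_skip = round(spec.skip_fraction * total_fields)
    n_phi = round(spec.phi_fraction * total_fields)
    n_missing = round(spec.allow_missing_fraction * total_fields)
    skip_eligible = [
        (c, i) for c in range(spec.n_crfs) for i in range(1, spec.fields_per_crf)
    ]
    if n_skip > len(skip_eligible):
        raise EdcError(
            f"cannot place {n_skip} skip patterns: CRFs too small",
            code="INFEASIBLE_COMPOSITION",
        )
    all_slots = [(c, i) for c in range(spec.n_crfs) for i in range(spec.fields_per_crf)]
    skip_slots = set(rng.sample(skip_eligible, n_skip))
    phi_slots = set(rng.sample(all_slots, min(n_phi, len(all_slots))))
    missing_slots = set(rng.sample(all_slots, min(n_missing, len(all_slots))))

    crfs = []
    for c in range(spec.n_crfs):
        crf_name = f"CRF{c + 1:02d}"
        fields = []
        parent_name = f"{crf_name}_F01"
        for i in range(spec.fields_per_crf):
            name = f"{crf_name}_F{i + 1:02d}"
            if i == 0:
                f = _make_field("radio", name, order=1)
            else:
                template = _TEMPLATES[(i - 1) % len(_TEMPLATES)]
                f = _make_field(template, name, order=i + 1)
            kwargs = {}
            if (c, i) in skip_slots:
                key = rng.choice(["1", "2"])
                kwargs["subquestion"] = f"{parent_name} = {key}"
            if (c, i) in phi_slots:
                kwargs["phi"] = True
            if (c, i) in missing_slots:
                kwargs["allow_missing"] = True
            if kwargs:
                from dataclasses import replace

                f = replace(f, **kwargs)
            fields.append(f)
        revision = CRFRevision(
            revision_no=1,
            activated_at=_EPOCH,
            fieldsets=(Fieldset(title=MLSText.of("Assessment"), fields=tuple(fields)),),
            form_subtitle=MLSText.of(f"Synthetic form {crf_name}"),
        )
        crfs.append(
            CRFDefinition(
                crf_name=crf_name,
                crf_label=f"Synthetic CRF {c + 1}",
                versions=(CRFVersion(v_version="v1", revisions=(revision,)),),
            )
        )
    events = tuple(
        StudyEventDef(
            event_code=f"EV{e + 1}",
            label=f"Visit {e + 1}",
            order=e + 1,
            required_crfs=tuple(c.crf_name for c in crfs),
        )
        for e in range(spec.n_events)
    )
    return StudyConfig(
        study_id=f"SYN{spec.seed:04d}",
        study_label="Synthetic fixture study",
        events=events,
        crfs=tuple(crfs),
        sites=tuple(f"S{s + 1:02d}" for s in range(spec.n_sites)),
        languages=("en",),
    )


# -- simulated data entry ----------------------------------------------------


def _clean_value(f: FieldDefinition, rng: random.Random) -> str:
    if f.has_choices:
        keys = f.choice_keys()
        if f.widget == "multiCheckbox":
            n = rng.randint(1, min(2, len(keys)))
            return ",".join(sorted(rng.sample(list(keys), n)))
        return rng.choice(keys)
    if f.widget == "timepicker24":
        return f"{rng.randint(0, 23):02d}:{rng.randint(0, 59):02d}"
    if f.dtype == "D":
        d = _EPOCH + timedelta(days=rng.randint(0, 1000))
        return d.date().isoformat()
    if f.dtype == "N":
        lo = int(f.value_range.min) if f.value_range else 0
        hi = int(f.value_range.max) if f.value_range else 100
        return str(rng.randint(lo, hi))
    if f.widget == "pin":
        return "".join(str(rng.randint(0, 9)) for _ in range(f.length.total if f.length else 4))
    limit = f.length.total if f.length else 20
    n = rng.randint(1, max(1, limit - 1))
    return ("v" * n)[:limit]


def _corrupt_value(f: FieldDefinition, rng: random.Random) -> str:
    """A value guaranteed to fail exactly one edit check for this field."""
    if f.has_choices:
        if f.widget == "multiCheckbox":
            return f"{f.choice_keys()[0]},ZZZ"  # CHOICE
        return "ZZZ"  # CHOICE
    if f.widget == "timepicker24":
        return "25:61"  # TIME_FORMAT
    if f.dtype == "D":
        return "2021-13-01"  # DATE_FORMAT (month 13)
    if f.dtype == "N":
        hi = f.value_range.max if f.value_range else 100
        return str(int(hi) + 50)  # RANGE
    if f.widget == "pin":
        return "12x4"[: (f.length.total if f.length else 4)]  # TYPE
    limit = f.length.total if f.length else 20
    return "X" * (limit + 1)  # LENGTH


@dataclass
class SimulationResult:
    study: Study
    n_records: int = 0
    n_validated_fields: int = 0
    n_corrupted_fields: int = 0
    n_missing_marked: int = 0


def simulate_entry(study: Study, spec: FixtureSpec,
                   actor: str = "sim-user") -> SimulationResult:
    """Simulate multi-site data entry through the real capture path.

    For every participant/event/required CRF a payload is generated field
    by field in form order, honouring skip patterns against the values
    actually generated; each visible (validated) field is independently
    corrupted with probability ``error_rate``, so open auto-query counts
    follow a Binomial(F, error_rate) law exactly.
    """
    rng = random.Random(spec.seed + 1)
    result = SimulationResult(study=study)
    for p in range(spec.n_participants):
        pid = f"P{p + 1:04d}"
        site = f"S{(p % max(spec.n_sites, 1)) + 1:02d}"
        study.register_participant(site, pid, actor=actor)
        for event in study.config.events:
            for crf_name in event.required_crfs:
                crf = study.config.crf(crf_name)
                revision = crf.versions[-1].revisions[-1]
                payload = _generate_payload(revision, spec, rng, result)
                study.submit_record(pid, event.event_code, crf_name, payload, actor)
                result.n_records += 1
    return result


def _generate_payload(revision: CRFRevision, spec: FixtureSpec,
                      rng: random.Random, result: SimulationResult) -> RecordPayload:
    conditions = revision_conditions(revision)
    numeric = frozenset(f.field_name for f in revision.iter_fields() if f.dtype == "N")
    raws: dict[str, str] = {}
    missing: set[str] = set()
    visible: dict[str, bool] = {}
    for f in revision.iter_fields():
        cond = conditions.get(f.field_name)
        if cond is None:
            vis = True
        else:
            vis = all(visible.get(p, True) for p in cond.referenced_fields()) and \
                cond.evaluate(raws, numeric)
        visible[f.field_name] = vis
        if not vis:
            continue
        result.n_validated_fields += 1
        if rng.random() < spec.error_rate:
            raws[f.field_name] = _corrupt_value(f, rng)
            result.n_corrupted_fields += 1
        elif f.allow_missing and rng.random() < spec.missing_prob:
            missing.add(f.field_name)
            result.n_missing_marked += 1
        else:
            raws[f.field_name] = _clean_value(f, rng)
    return RecordPayload(values=raws, missing=missing)


# -- printed operational counts of the supported studies ---------------------


def table3_fixture() -> list[StudySummary]:
    """Operational counts of the seven production studies with complete
    published figures (observational cohorts and randomized trials in
    AD/ADRD research), used as worked examples for the summary report and
    query-rate arithmetic."""
    rows = [
        ("ADNI3", "OC", 836, 63, 1802, 136876, 152773, 11644, 1217, 135797, None),
        ("AHEAD3-45", "RCT", 1065, 108, 1147, 63200, 69047, 9275, 4161, 14333, 449),
        ("LEADS", "OC", 311, 19, 415, 28843, 34497, 4919, 539, 11721, None),
        ("MIND", "RCT", 443, 51, 623, 61656, 72588, 7361, 446, 34040, None),
        ("NiAD", "OC", 102, 5, 248, 20623, 24391, 2601, 11, 4186, None),
        ("TRC-PAD", "OC", 598, 51, 360, 26592, 28545, 1086, 486, 13740, 252),
        ("TRC-DS", "OC", 149, 17, 1, 26, 27, 1, 410, 419, 2),
    ]
    from .queries import rate_pct

    return [
        StudySummary(
            study_id=sid,
            study_type=stype,
            n_users=users,
            n_sites=sites,
            n_participants_screened=participants,
            n_ecrfs=ecrfs,
            n_transactions=transactions,
            n_queries=queries,
            query_rate_pct=rate_pct(queries, ecrfs),
            n_files=files,
            n_file_versions=file_versions,
            n_image_studies=images,
        )
        for sid, stype, users, sites, participants, ecrfs, transactions,
            queries, files, file_versions, images in rows
    ]
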