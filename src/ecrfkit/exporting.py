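"""Standardized study data export and the study summary report.

Exports come in two shapes: CSV (2-dimensional, one file per eCRF, RFC
4180) and JSON (multi-dimensional, nested study → participants → events
→ records → items).  Fields flagged as PHI are masked (``[MASKED]``) or
dropped by default; including them requires an explicit override.  An
explicitly-missing value exports as the token ``MISSING``; an unanswered
or hidden one as an empty cell, so the two are never conflated.

The study summary reproduces the operational counts a data-management
report carries: users, sites, participants screened, eCRFs, record-level
transactions, queries with their rate, and document repository volumes.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence, Union

from .capture import FormRecord, Study
from .errors import EdcError, NotFoundError
from .queries import rate_pct
from .validation import MISSING, UNANSWERED, serialize_value

MASK_TOKEN = "[MASKED]"
MISSING_TOKEN = "MISSING"


@dataclass(frozen=True)
class ExportOptions:
    phi_mode: str = "mask"  # mask | drop | include
    include_audit: bool = False
    language: Optional[str] = None
    site: Optional[str] = None
    participants: Optional[tuple[str, ...]] = None
    confirm_include_phi: bool = False

    def __post_init__(self):
        if self.phi_mode not in ("mask", "drop", "include"):
            raise EdcError(f"unknown phi_mode {self.phi_mode!r}", code="BAD_OPTION")
        if self.phi_mode == "include" and not self.confirm_include_phi:
            raise EdcError(
                "phi_mode='include' requires confirm_include_phi=True",
                code="PHI_OVERRIDE_REQUIRED",
            )


def _selected_records(study: Study, options: ExportOptions,
                      crf_name: Optional[str] = None) -> list[FormRecord]:
    event_order = {e.event_code: e.order for e in study.config.events}
    recs = [
        r
        for r in study.records.values()
        if r.state == "active"
        and (crf_name is None or r.crf_name == crf_name)
        and (options.site is None
             or study.participants[r.participant_id].site_code == options.site)
        and (options.participants is None
             or r.participant_id in options.participants)
    ]
    recs.sort(
        key=lambda r: (
            r.participant_id,
            event_order.get(r.event_code, 10**9),
            r.event_code,
            r.crf_name,
            r.instance_no,
        )
    )
    return recs


def _field_columns(study: Study, crf_name: str) -> tuple[list[str], dict[str, bool]]:
    """Export field order (newest revision first, older-only fields after)
    and the PHI flag per field."""
    crf = study.config.crf(crf_name)
    revisions = [r for v in crf.versions for r in v.revisions]
    revisions.sort(key=lambda r: (r.activated_at, r.revision_no))
    columns: list[str] = []
    phi: dict[str, bool] = {}
    for revision in revisions:  # newest last wins the ordering
        columns = [f.field_name for f in revision.iter_fields()]
        for f in revision.iter_fields():
            phi[f.field_name] = f.phi
    newest = set(columns)
    extras = sorted(name for name in phi if name not in newest)
    return columns + extras, phi


def _cell(record: FormRecord, name: str) -> str:
    value = record.clean.values.get(name, UNANSWERED)
    if value is MISSING:
        return MISSING_TOKEN
    if value is UNANSWERED:
        return ""
    return serialize_value(value)


def export_csv(study: Study, crf_name: str, options: ExportOptions = ExportOptions()) -> str:
    """One CSV table for one eCRF: a row per live record instance (current
    version), key columns then fields in their configured order."""
    try:
        study.config.crf(crf_name)
    except NotFoundError:
        raise EdcError(f"unknown CRF {crf_name!r}", code="UNKNOWN_CRF")
    columns, phi = _field_columns(study, crf_name)
    if options.phi_mode == "drop":
        columns = [c for c in columns if not phi.get(c)]
    key_cols = [
        "study_id", "site_id", "participant_id", "event_code",
        "instance_no", "version", "revision",
    ]
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\r\n")
    writer.writerow(key_cols + columns)
    for rec in _selected_records(study, options, crf_name):
        site = study.participants[rec.participant_id].site_code
        row = [
            study.config.study_id, site, rec.participant_id, rec.event_code,
            str(rec.instance_no), rec.v_version, str(rec.revision_no),
        ]
        for name in columns:
            if phi.get(name) and options.phi_mode == "mask":
                row.append(MASK_TOKEN)
            else:
                row.append(_cell(rec, name))
        writer.writerow(row)
    return buf.getvalue()


def export_all_csv(study: Study, options: ExportOptions = ExportOptions()) -> dict[str, str]:
    return {
        crf.crf_name: export_csv(study, crf.crf_name, options)
        for crf in study.config.crfs
    }


def export_json(study: Study, options: ExportOptions = ExportOptions()) -> dict:
    """Multi-dimensional export: study → participants → events → records →
    items, each item with value, status, last-modified time and its open
    query count; optionally per-item audit history."""
    out = {
        "study_id": study.config.study_id,
        "study_label": study.config.study_label,
        "participants": [],
    }
    recs = _selected_records(study, options)
    by_participant: dict[str, dict[str, list[FormRecord]]] = {}
    for rec in recs:
        by_participant.setdefault(rec.participant_id, {}).setdefault(
            rec.event_code, []
        ).append(rec)
    for pid in sorted(by_participant):
        participant = study.participants[pid]
        p_doc = {
            "participant_id": pid,
            "site_code": participant.site_code,
            "status": participant.status,
            "events": [],
        }
        for event_code in sorted(
            by_participant[pid],
            key=lambda e: ({ev.event_code: ev.order for ev in study.config.events}
                           .get(e, 10**9), e),
        ):
            e_doc = {"event_code": event_code, "records": []}
            for rec in by_participant[pid][event_code]:
                e_doc["records"].append(_record_doc(study, rec, options))
            p_doc["events"].append(e_doc)
        out["participants"].append(p_doc)
    return out


def _record_doc(study: Study, rec: FormRecord, options: ExportOptions) -> dict:
    _, phi = _field_columns(study, rec.crf_name)
    revision = study._revision_for(rec)
    record_entry = study.ledger.current(rec.record_doi)
    items = {}
    for f in revision.iter_fields():
        name = f.field_name
        if phi.get(name) and options.phi_mode == "drop":
            continue
        value = rec.clean.values.get(name, UNANSWERED)
        if value is MISSING:
            status, out_value = "missing", MISSING_TOKEN
        elif value is UNANSWERED:
            status = "hidden" if not rec.clean.visibility.get(name, True) else "unanswered"
            out_value = None
        else:
            status, out_value = "answered", serialize_value(value)
        if phi.get(name) and options.phi_mode == "mask" and out_value is not None:
            out_value = MASK_TOKEN
        item_doi = rec.item_dois.get(name)
        last_modified = (
            study.ledger.current(item_doi).timestamp if item_doi else record_entry.timestamp
        )
        open_queries = sum(
            1
            for q in study.queries.for_record(rec.record_doi)
            if q.is_open and q.field_name == name
        )
        item = {
            "value": out_value,
            "status": status,
            "last_modified": last_modified,
            "open_query_count": open_queries,
        }
        if options.include_audit and item_doi:
            history = study.ledger.history(item_doi)
            item["history"] = [
                {
                    "version": e.version,
                    "value": (
                        MASK_TOKEN
                        if phi.get(name) and options.phi_mode == "mask"
                        and isinstance(e.payload, dict) and e.payload.get("value")
                        else (e.payload.get("value") if isinstance(e.payload, dict) else None)
                    ),
                    "actor": e.actor,
                    "timestamp": e.timestamp,
                    "rfc": e.rfc,
                }
                for e in history.versions
            ]
        items[name] = item
    doc = {
        "crf_name": rec.crf_name,
        "instance_no": rec.instance_no,
        "version": rec.v_version,
        "revision": rec.revision_no,
        "complete": rec.is_complete,
        "open_query_count": study.queries.open_count(rec.record_doi),
        "items": items,
    }
    if options.include_audit:
        doc["record_history_length"] = study.ledger.history(rec.record_doi).version_count
    return doc


# ---------------------------------------------------------------------------
# study summary report


@dataclass(frozen=True)
class StudySummary:
    study_id: str
    study_type: str = ""
    n_users: int = 0
    n_sites: int = 0
    n_participants_screened: int = 0
    n_ecrfs: int = 0
    n_transactions: int = 0
    n_queries: int = 0
    query_rate_pct: Optional[float] = None
    n_files: int = 0
    n_file_versions: int = 0
    n_image_studies: Optional[int] = None  # always reported, may be blank

    def as_row(self) -> dict:
        return {
            "study_id": self.study_id,
            "study_type": self.study_type,
            "n_users": self.n_users,
            "n_sites": self.n_sites,
            "n_participants_screened": self.n_participants_screened,
            "n_ecrfs": self.n_ecrfs,
            "n_transactions": self.n_transactions,
            "n_queries": self.n_queries,
            "query_rate_pct": self.query_rate_pct,
            "n_files": self.n_files,
            "n_file_versions": self.n_file_versions,
            "n_image_studies": self.n_image_studies,
        }


def summarize_study(study: Study, study_type: str = "", n_users: int = 0) -> StudySummary:
    """Operational counts for one live study, scanned from its stores."""
    n_files, n_file_versions = study.docs.file_counts()
    n_ecrfs = study.n_ecrfs()
    n_queries = len(study.queries.queries)
    return StudySummary(
        study_id=study.config.study_id,
        study_type=study_type,
        n_users=n_users,
        n_sites=len(study.sites),
        n_participants_screened=len(study.participants),
        n_ecrfs=n_ecrfs,
        n_transactions=study.n_record_transactions(),
        n_queries=n_queries,
        query_rate_pct=rate_pct(n_queries, n_ecrfs),
        n_files=n_files,
        n_file_versions=n_file_versions,
        n_image_studies=None,
    )


def study_summary(
    studies: Sequence[Union[Study, StudySummary]]
) -> tuple[list[StudySummary], StudySummary]:
    """Per-study summary rows plus a totals row.

    The totals row sums every count column; its rate cell is left blank,
    as is conventional for pooled query rates.
    """
    rows = [s if isinstance(s, StudySummary) else summarize_study(s) for s in studies]
    image_values = [r.n_image_studies for r in rows if r.n_image_studies is not None]
    totals = StudySummary(
        study_id="Total",
        study_type="",
        n_users=sum(r.n_users for r in rows),
        n_sites=sum(r.n_sites for r in rows),
        n_participants_screened=sum(r.n_participants_screened for r in rows),
        n_ecrfs=sum(r.n_ecrfs for r in rows),
        n_transactions=sum(r.n_transactions for r in rows),
        n_queries=sum(r.n_queries for r in rows),
        query_rate_pct=None,
        n_files=sum(r.n_files for r in rows),
        n_file_versions=sum(r.n_file_versions for r in rows),
        n_image_studies=sum(image_values) if image_values else None,
    )
    return rows, totals


def summary_csv(rows: Iterable[StudySummary], totals: Optional[StudySummary] = None) -> str:
    buf = io.StringIO()
    header = list(StudySummary("x").as_row().keys())
    writer = csv.DictWriter(buf, fieldnames=header, lineterminator="\r\n")
    writer.writeheader()
    for r in rows:
        writer.writerow({k: ("" if v is None else v) for k, v in r.as_row().items()})
    if totals is not None:
        writer.writerow({k: ("" if v is None else v) for k, v in totals.as_row().items()})
    return buf.getvalue()
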