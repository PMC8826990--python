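"""Participant registry, record capture and the workflow interpreter.

A :class:`Study` binds a validated configuration to a ledger, a query
store and a document repository.  Every state change — participant
registration, record submission, edits, deletes, control marks, query
activity, file uploads, workflow runs — flows through the ledger, so the
complete study state can be rebuilt from the ledger log alone
(:meth:`Study.replay`).

Record capture is prospective with respect to form revisions: the
version/revision resolved at a record's creation time governs it
forever; activating a newer revision affects only records created
afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Callable, Mapping, Optional

from .checks import validate_config
from .conditions import evaluate_context, parse_condition
from .documents import DocumentRepository
from .errors import DuplicateError, EdcError, LockedError, NotFoundError, RfcRequiredError
from .ledger import Ledger, ScopeKey
from .model import CRFRevision, StudyConfig, resolve_version
from .queries import Query, QueryStore, StudyQueryMetrics
from .validation import (
    MISSING,
    UNANSWERED,
    CleanRecord,
    RecordPayload,
    ValidationFinding,
    validate_record,
)
from .workbook import config_to_dict

WORKFLOW_ACTIONS = ("insert", "edit", "delete", "annotate", "link", "copy", "execute")


@dataclass
class Participant:
    participant_id: str
    site_code: str
    doi_id: str
    status: str = "screened"
    registered_at: str = ""


@dataclass
class FormRecord:
    participant_id: str
    event_code: str
    crf_name: str
    instance_no: int
    v_version: str
    revision_no: int
    record_doi: str
    payload: RecordPayload
    clean: CleanRecord
    findings: list[ValidationFinding]
    item_dois: dict[str, str] = field(default_factory=dict)
    state: str = "active"
    created_at: str = ""

    @property
    def is_complete(self) -> bool:
        if any(f.severity == "error" for f in self.findings):
            return False
        answered, total = self.required_progress
        return answered == total

    @property
    def required_progress(self) -> tuple[int, int]:
        """(answered, total) over required visible fields; an explicit
        missing mark counts as answered."""
        answered = total = 0
        for name, visible in self.clean.visibility.items():
            if not visible:
                continue
            # required-ness comes from the governing revision via clean map
            if name not in self._required_fields:
                continue
            total += 1
            if self.clean.values.get(name) is not UNANSWERED:
                answered += 1
        return answered, total

    _required_fields: frozenset = frozenset()

    def attach_revision(self, revision: CRFRevision) -> None:
        self._required_fields = frozenset(
            f.field_name for f in revision.iter_fields() if f.required
        )


@dataclass
class MatrixCell:
    status: str  # missing | incomplete | complete | complete-with-queries | locked
    progress: tuple[int, int]  # answered / total required-visible fields
    open_queries: int
    instances: int


@dataclass
class EventMatrix:
    participant_id: str
    cells: dict[tuple[str, str], MatrixCell]
    event_open_queries: dict[str, int]
    event_locked: dict[str, bool]
    supplemental: dict[str, list[str]]  # event -> cross-event/extra record DOIs


@dataclass(frozen=True)
class WorkflowStep:
    action: str
    target: Mapping[str, object] = field(default_factory=dict)
    condition: Optional[str] = None
    async_eligible: bool = False
    handler: Optional[str] = None


@dataclass(frozen=True)
class WorkflowDefinition:
    name: str
    steps: tuple[WorkflowStep, ...]


@dataclass
class WorkflowRun:
    workflow: str
    outcomes: list[dict]
    context: dict
    started_at: str
    finished_at: str = ""


class Study:
    """A deployed study: validated configuration plus live data stores."""

    def __init__(
        self,
        config: StudyConfig,
        study_secret: bytes | str,
        clock: Optional[Callable[[], datetime]] = None,
        blob_dir=None,
        _replaying: bool = False,
    ):
        findings = validate_config(config)
        errors = [f for f in findings if f.severity == "error"]
        if errors:
            raise EdcError(
                f"configuration has {len(errors)} error finding(s); first: "
                f"{errors[0].code} at {errors[0].location}",
                code="CONFIG_INVALID",
            )
        self.config = config
        self.ledger = Ledger(study_secret, clock=clock)
        self.ledger.scope_resolver = self._scopes_for
        self.queries = QueryStore(self.ledger, scope_checker=self._check_query_scope)
        self.docs = DocumentRepository(self.ledger, blob_dir=blob_dir)
        self.docs.sites = list(config.sites)
        self.participants: dict[str, Participant] = {}
        self.records: dict[str, FormRecord] = {}
        self._instances: dict[tuple[str, Optional[str], str], list[str]] = {}
        self.sites: list[str] = list(config.sites)
        self.handlers: dict[str, Callable] = {}
        self.workflows: dict[str, WorkflowDefinition] = {}
        self.study_doi: Optional[str] = None
        if not _replaying:
            entry = self.ledger.append_doi(
                "study",
                {"study_id": config.study_id, "config": config_to_dict(config)},
                "system",
            )
            self.study_doi = entry.doi_id

    # -- scope plumbing ----------------------------------------------------

    def _scopes_for(self, doi_id: str) -> list[ScopeKey]:
        rec = self.records.get(doi_id)
        if rec is None:
            return []
        return [
            ("record", doi_id),
            ("event", rec.participant_id, rec.event_code),
            ("participant", rec.participant_id),
        ]

    def _check_query_scope(self, record_doi: str, field_name: Optional[str]) -> None:
        rec = self.records.get(record_doi)
        if rec is None:
            raise EdcError(f"record {record_doi!r} unknown", code="UNKNOWN_SCOPE")
        if field_name is not None:
            revision = self._revision_for(rec)
            if field_name not in revision.field_names():
                raise EdcError(
                    f"field {field_name!r} not in revision governing the record",
                    code="UNKNOWN_SCOPE",
                )

    def _revision_for(self, rec: FormRecord) -> CRFRevision:
        version = self.config.crf(rec.crf_name).version(rec.v_version)
        for revision in version.revisions:
            if revision.revision_no == rec.revision_no:
                return revision
        raise NotFoundError(
            f"revision {rec.revision_no} of {rec.crf_name}/{rec.v_version} not found"
        )

    # -- sites and participants -------------------------------------------

    def add_site(self, site_code: str, actor: str = "system") -> None:
        if site_code in self.sites:
            raise DuplicateError(f"site {site_code!r} already registered")
        self.sites.append(site_code)
        self.ledger.append_doi("event", {"kind": "site-registered", "site": site_code}, actor)
        self.docs.on_site_added(site_code, actor)

    def register_participant(
        self, site_code: str, participant_id: str, actor: str = "system"
    ) -> Participant:
        if participant_id in self.participants:
            raise DuplicateError(
                f"participant {participant_id!r} already registered", code="DUPLICATE_ID"
            )
        if site_code not in self.sites:
            raise EdcError(f"site {site_code!r} not registered", code="UNKNOWN_SITE")
        entry = self.ledger.append_doi(
            "participant",
            {"participant_id": participant_id, "site_code": site_code,
             "status": "screened"},
            actor,
        )
        p = Participant(
            participant_id=participant_id,
            site_code=site_code,
            doi_id=entry.doi_id,
            registered_at=entry.timestamp,
        )
        self.participants[participant_id] = p
        return p

    def set_participant_status(self, participant_id: str, status: str, actor: str,
                               rfc: str) -> None:
        if status not in ("screened", "enrolled", "discontinued"):
            raise EdcError(f"unknown participant status {status!r}", code="BAD_STATUS")
        p = self.participants[participant_id]
        self.ledger.amend_doi(
            p.doi_id,
            {"participant_id": participant_id, "site_code": p.site_code, "status": status},
            actor,
            rfc,
        )
        p.status = status

    # -- record capture ----------------------------------------------------

    def _instance_key(self, participant_id: str, event_code: str,
                      crf_name: str) -> tuple[str, Optional[str], str]:
        crf = self.config.crf(crf_name)
        # cross-event CRFs share one instance sequence across events
        return (participant_id, None if crf.is_cross_events else event_code, crf_name)

    def find_record(
        self, participant_id: str, event_code: str, crf_name: str, instance_no: int = 1
    ) -> FormRecord:
        key = self._instance_key(participant_id, event_code, crf_name)
        for doi in self._instances.get(key, []):
            rec = self.records[doi]
            if rec.instance_no == instance_no and rec.state == "active":
                return rec
        raise NotFoundError(
            f"no record for {participant_id}/{event_code}/{crf_name} "
            f"instance {instance_no}"
        )

    def submit_record(
        self,
        participant_id: str,
        event_code: str,
        crf_name: str,
        payload: RecordPayload | Mapping[str, object],
        actor: str,
        version_choice: Optional[str] = None,
    ) -> tuple[FormRecord, list[ValidationFinding], list[Query]]:
        """Submit a new record; raw values are stored even when findings
        exist, and one auto query opens per error finding."""
        if participant_id not in self.participants:
            raise NotFoundError(f"participant {participant_id!r} unknown")
        try:
            crf = self.config.crf(crf_name)
        except NotFoundError:
            raise EdcError(f"unknown CRF {crf_name!r}", code="UNKNOWN_CRF")
        if not crf.is_cross_events:
            try:
                event = self.config.event(event_code)
            except NotFoundError:
                raise EdcError(f"unknown event {event_code!r}", code="UNKNOWN_EVENT")
        for scope in (
            ("participant", participant_id),
            ("event", participant_id, event_code),
        ):
            if self.ledger.is_locked(scope):
                raise LockedError(f"scope {scope} is locked")
        if not isinstance(payload, RecordPayload):
            payload = RecordPayload.from_mapping(payload)

        key = self._instance_key(participant_id, event_code, crf_name)
        live = [
            d for d in self._instances.get(key, []) if self.records[d].state == "active"
        ]
        if live and not crf.allow_multiple_entry:
            raise EdcError(
                f"CRF {crf_name!r} does not allow multiple records",
                code="MULTIPLE_ENTRY_FORBIDDEN",
            )
        created_at = self.ledger.clock()
        if created_at.tzinfo is None:
            created_at = created_at.replace(tzinfo=timezone.utc)
        version, revision = resolve_version(crf, created_at, version_choice)
        clean, findings = validate_record(revision, payload)

        instance_no = (
            max((self.records[d].instance_no for d in self._instances.get(key, [])),
                default=0) + 1
        )
        record_payload = {
            "participant": participant_id,
            "event": event_code,
            "crf": crf_name,
            "instance": instance_no,
            "v_version": version.v_version,
            "revision": revision.revision_no,
            "values": dict(sorted(payload.values.items())),
            "missing": sorted(payload.missing),
        }
        entry = self.ledger.append_doi("form-record", record_payload, actor)
        rec = FormRecord(
            participant_id=participant_id,
            event_code=event_code,
            crf_name=crf_name,
            instance_no=instance_no,
            v_version=version.v_version,
            revision_no=revision.revision_no,
            record_doi=entry.doi_id,
            payload=payload,
            clean=clean,
            findings=findings,
            created_at=entry.timestamp,
        )
        rec.attach_revision(revision)
        self.records[entry.doi_id] = rec
        self._instances.setdefault(key, []).append(entry.doi_id)
        for name in sorted(set(payload.values) | set(payload.missing)):
            item_entry = self.ledger.append_doi(
                "field-value",
                {
                    "record": entry.doi_id,
                    "field": name,
                    "value": payload.values.get(name),
                    "missing": name in payload.missing,
                },
                actor,
            )
            rec.item_dois[name] = item_entry.doi_id
        opened, _ = self.queries.sync_auto_queries(entry.doi_id, findings)
        return rec, findings, opened

    def edit_record(
        self,
        record_doi: str,
        changes: Mapping[str, str],
        actor: str,
        rfc: str,
        missing: Optional[set[str]] = None,
    ) -> tuple[FormRecord, list[ValidationFinding], list[Query]]:
        """Amend a record: merge changed fields, re-validate under the
        record's original revision, system-close auto queries now passing."""
        if record_doi not in self.records:
            raise NotFoundError(f"record {record_doi!r} unknown")
        if not rfc:
            raise RfcRequiredError("record edit requires a reason for change")
        self.ledger.check_writable(record_doi)
        rec = self.records[record_doi]
        new_values = dict(rec.payload.values)
        new_missing = set(rec.payload.missing)
        for name, value in changes.items():
            new_missing.discard(name)
            if value == "":
                new_values.pop(name, None)
            else:
                new_values[name] = str(value)
        for name in missing or set():
            new_values.pop(name, None)
            new_missing.add(name)
        payload = RecordPayload(values=new_values, missing=new_missing)
        revision = self._revision_for(rec)
        clean, findings = validate_record(revision, payload)

        record_payload = {
            "participant": rec.participant_id,
            "event": rec.event_code,
            "crf": rec.crf_name,
            "instance": rec.instance_no,
            "v_version": rec.v_version,
            "revision": rec.revision_no,
            "values": dict(sorted(new_values.items())),
            "missing": sorted(new_missing),
        }
        self.ledger.amend_doi(record_doi, record_payload, actor, rfc)
        touched = set(changes) | set(missing or set())
        for name in sorted(touched):
            item_payload = {
                "record": record_doi,
                "field": name,
                "value": new_values.get(name),
                "missing": name in new_missing,
            }
            if name in rec.item_dois:
                self.ledger.amend_doi(rec.item_dois[name], item_payload, actor, rfc)
            else:
                item_entry = self.ledger.append_doi("field-value", item_payload, actor)
                rec.item_dois[name] = item_entry.doi_id
        rec.payload = payload
        rec.clean = clean
        rec.findings = findings
        opened, closed = self.queries.sync_auto_queries(record_doi, findings)
        return rec, findings, closed

    def delete_record(self, record_doi: str, actor: str, rfc: str) -> None:
        if record_doi not in self.records:
            raise NotFoundError(f"record {record_doi!r} unknown")
        self.ledger.delete_doi(record_doi, actor, rfc)
        self.records[record_doi].state = "deleted"

    # -- control marks -----------------------------------------------------

    def lock(self, scope: ScopeKey, actor: str):
        return self.ledger.apply_control_mark(scope, "lock", actor)

    def unlock(self, scope: ScopeKey, actor: str, rfc: str):
        return self.ledger.apply_control_mark(scope, "unlock", actor, rfc)

    def sdv(self, scope: ScopeKey, actor: str):
        return self.ledger.apply_control_mark(scope, "sdv", actor)

    def sdv_clear(self, scope: ScopeKey, actor: str):
        return self.ledger.apply_control_mark(scope, "sdv-clear", actor)

    def record_scope(self, record_doi: str) -> ScopeKey:
        return ("record", record_doi)

    def event_scope(self, participant_id: str, event_code: str) -> ScopeKey:
        return ("event", participant_id, event_code)

    def participant_scope(self, participant_id: str) -> ScopeKey:
        return ("participant", participant_id)

    # -- event matrix ------------------------------------------------------

    def compute_event_matrix(self, participant_id: str) -> EventMatrix:
        """Per-(event, required CRF) status, completion progress and open
        query counts; a pure function of ledger plus query store."""
        if participant_id not in self.participants:
            raise NotFoundError(f"participant {participant_id!r} unknown")
        cells: dict[tuple[str, str], MatrixCell] = {}
        event_queries: dict[str, int] = {}
        event_locked: dict[str, bool] = {}
        supplemental: dict[str, list[str]] = {}
        p_locked = self.ledger.is_locked(("participant", participant_id))
        for event in self.config.events:
            ev = event.event_code
            ev_locked = p_locked or self.ledger.is_locked(("event", participant_id, ev))
            event_locked[ev] = ev_locked
            event_queries[ev] = 0
            supplemental[ev] = []
            for crf_name in event.required_crfs:
                recs = self._live_records(participant_id, ev, crf_name)
                open_q = sum(self.queries.open_count(r.record_doi) for r in recs)
                event_queries[ev] += open_q
                if not recs:
                    cells[(ev, crf_name)] = MatrixCell("missing", (0, 0), 0, 0)
                    continue
                answered = sum(r.required_progress[0] for r in recs)
                total = sum(r.required_progress[1] for r in recs)
                locked = ev_locked or any(
                    self.ledger.is_locked(("record", r.record_doi)) for r in recs
                )
                if locked:
                    status = "locked"
                elif not all(r.is_complete for r in recs):
                    status = "incomplete"
                elif open_q:
                    status = "complete-with-queries"
                else:
                    status = "complete"
                cells[(ev, crf_name)] = MatrixCell(status, (answered, total), open_q,
                                                   len(recs))
            # cross-event records are visible from every event view
            for rec in self.records.values():
                if rec.state != "active" or rec.participant_id != participant_id:
                    continue
                crf = self.config.crf(rec.crf_name)
                if crf.is_cross_events:
                    supplemental[ev].append(rec.record_doi)
        return EventMatrix(
            participant_id=participant_id,
            cells=cells,
            event_open_queries=event_queries,
            event_locked=event_locked,
            supplemental=supplemental,
        )

    def _live_records(self, participant_id: str, event_code: str,
                      crf_name: str) -> list[FormRecord]:
        key = self._instance_key(participant_id, event_code, crf_name)
        return [
            self.records[d]
            for d in self._instances.get(key, [])
            if self.records[d].state == "active"
        ]

    # -- workflows ---------------------------------------------------------

    def register_handler(self, name: str, handler: Callable) -> None:
        self.handlers[name] = handler

    def register_workflow(self, definition: WorkflowDefinition) -> None:
        for step in definition.steps:
            if step.action not in WORKFLOW_ACTIONS:
                raise EdcError(f"unknown workflow action {step.action!r}",
                               code="BAD_ACTION")
            if step.action == "execute":
                if not step.handler or step.handler not in self.handlers:
                    raise EdcError(
                        f"execute step names unregistered handler {step.handler!r}",
                        code="HANDLER_UNKNOWN",
                    )
        self.workflows[definition.name] = definition

    def run_workflow(self, name: str, context: Mapping[str, object],
                     actor: str) -> WorkflowRun:
        """Run a registered workflow's steps in order.

        A false condition logs the step as skipped with no ledger write; a
        failing step halts the run.  Async-eligible steps are recorded as
        such but executed sequentially.  Every applied effect goes through
        the public capture operations, never around the ledger.
        """
        if name not in self.workflows:
            raise NotFoundError(f"workflow {name!r} not registered")
        definition = self.workflows[name]
        context = dict(context)
        run = WorkflowRun(
            workflow=name, outcomes=[], context=dict(context),
            started_at=self.ledger._now(),
        )
        for i, step in enumerate(definition.steps):
            outcome = {"step": i, "action": step.action,
                       "async_eligible": step.async_eligible}
            if step.condition:
                cond = parse_condition(step.condition)
                if not evaluate_context(cond, context):
                    outcome["outcome"] = "skipped"
                    run.outcomes.append(outcome)
                    continue
            try:
                detail = self._apply_step(step, context, actor)
                outcome["outcome"] = "applied"
                if detail:
                    outcome["detail"] = detail
                run.outcomes.append(outcome)
            except EdcError as exc:
                outcome["outcome"] = "failed"
                outcome["error"] = str(exc)
                run.outcomes.append(outcome)
                break
        run.finished_at = self.ledger._now()
        self.ledger.append_doi(
            "workflow-run",
            {"workflow": name, "outcomes": run.outcomes,
             "started_at": run.started_at, "finished_at": run.finished_at},
            actor,
        )
        return run

    def _apply_step(self, step: WorkflowStep, context: dict, actor: str):
        t = {k: self._resolve(v, context) for k, v in step.target.items()}
        if step.action == "insert":
            rec, findings, _ = self.submit_record(
                t["participant"], t["event"], t["crf"], t.get("values", {}), actor,
            )
            context["record_doi"] = rec.record_doi
            return {"record_doi": rec.record_doi, "findings": len(findings)}
        if step.action == "edit":
            doi = t.get("record_doi") or context.get("record_doi")
            rec, findings, _ = self.edit_record(
                doi, t.get("values", {}), actor, t.get("rfc", "workflow edit"),
            )
            return {"record_doi": rec.record_doi, "findings": len(findings)}
        if step.action == "delete":
            doi = t.get("record_doi") or context.get("record_doi")
            self.delete_record(doi, actor, t.get("rfc", "workflow delete"))
            return {"record_doi": doi}
        if step.action == "annotate":
            doi = t.get("record_doi") or context.get("record_doi")
            self.ledger.append_doi(
                "annotation", {"target_doi": doi, "text": t.get("text", "")}, actor
            )
            return {"target_doi": doi}
        if step.action == "link":
            self.ledger.append_doi(
                "link",
                {"from_doi": t["from_doi"], "to_doi": t["to_doi"],
                 "relation": t.get("relation", "related")},
                actor,
            )
            return None
        if step.action == "copy":
            source = self.records[t.get("record_doi") or context["record_doi"]]
            rec, findings, _ = self.submit_record(
                t.get("participant", source.participant_id),
                t["event"],
                source.crf_name,
                RecordPayload(values=dict(source.payload.values),
                              missing=set(source.payload.missing)),
                actor,
            )
            context["record_doi"] = rec.record_doi
            return {"record_doi": rec.record_doi}
        if step.action == "execute":
            result = self.handlers[step.handler](self, context)
            return {"handler": step.handler, "result": result}
        raise EdcError(f"unknown action {step.action!r}", code="BAD_ACTION")

    @staticmethod
    def _resolve(value, context):
        if isinstance(value, str) and value.startswith("$"):
            return context.get(value[1:])
        if isinstance(value, Mapping):
            return {k: Study._resolve(v, context) for k, v in value.items()}
        return value

    # -- metrics and counting ---------------------------------------------

    def n_ecrfs(self) -> int:
        """Number of live eCRF record instances."""
        return sum(1 for r in self.records.values() if r.state == "active")

    def n_record_transactions(self) -> int:
        """Record-level transactions: form-record inserts + amendments."""
        return sum(1 for e in self.ledger.entries if e.object_type == "form-record")

    def query_metrics(self) -> StudyQueryMetrics:
        return self.queries.query_metrics(self.n_ecrfs())

    # -- replay ------------------------------------------------------------

    @classmethod
    def replay(
        cls,
        config: StudyConfig,
        ledger: Ledger,
        clock: Optional[Callable[[], datetime]] = None,
        blob_dir=None,
    ) -> "Study":
        """Rebuild full study state from a ledger log.

        Records are re-validated under the revision stored in their
        payload (never re-resolved), so replay reproduces the original
        statuses exactly.
        """
        study = cls(config, ledger.secret, clock=clock, blob_dir=blob_dir,
                    _replaying=True)
        study.ledger = Ledger.from_entries(ledger.entries, ledger.secret, clock=clock)
        study.ledger.scope_resolver = study._scopes_for
        study.queries = QueryStore.rebuild(study.ledger, study._check_query_scope)
        study.docs = DocumentRepository.rebuild(
            study.ledger, blob_dir=blob_dir, sites=list(config.sites)
        )

        for entry in study.ledger.entries:
            p = entry.payload if isinstance(entry.payload, dict) else {}
            if entry.object_type == "study" and study.study_doi is None:
                study.study_doi = entry.doi_id
            elif entry.object_type == "participant":
                pid = p["participant_id"]
                if pid not in study.participants:
                    study.participants[pid] = Participant(
                        participant_id=pid, site_code=p["site_code"],
                        doi_id=entry.doi_id, status=p["status"],
                        registered_at=entry.timestamp,
                    )
                else:
                    study.participants[pid].status = p["status"]
            elif entry.object_type == "event" and p.get("kind") == "site-registered":
                if p["site"] not in study.sites:
                    study.sites.append(p["site"])
                study.docs.on_site_added(p["site"])
            elif entry.object_type == "form-record":
                study._replay_record(entry, p)
            elif entry.object_type == "field-value":
                rec = study.records.get(p.get("record"))
                if rec is not None and entry.version == 1:
                    rec.item_dois[p["field"]] = entry.doi_id
        return study

    def _replay_record(self, entry, p: dict) -> None:
        payload = RecordPayload(
            values=dict(p["values"]), missing=set(p["missing"])
        )
        crf = self.config.crf(p["crf"])
        version = crf.version(p["v_version"])
        revision = next(r for r in version.revisions if r.revision_no == p["revision"])
        clean, findings = validate_record(revision, payload)
        if entry.version == 1:
            rec = FormRecord(
                participant_id=p["participant"],
                event_code=p["event"],
                crf_name=p["crf"],
                instance_no=p["instance"],
                v_version=p["v_version"],
                revision_no=p["revision"],
                record_doi=entry.doi_id,
                payload=payload,
                clean=clean,
                findings=findings,
                created_at=entry.timestamp,
            )
            rec.attach_revision(revision)
            self.records[entry.doi_id] = rec
            key = self._instance_key(p["participant"], p["event"], p["crf"])
            self._instances.setdefault(key, []).append(entry.doi_id)
        else:
            rec = self.records[entry.doi_id]
            rec.payload = payload
            rec.clean = clean
            rec.findings = findings
        if entry.state == "deleted":
            self.records[entry.doi_id].state = "deleted"
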