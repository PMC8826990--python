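"""Data query lifecycle and study-level query metrics.

A query is a tracked clarification conversation between the study team
and a site about one record or one field of it.  Queries are either
manual (opened by a person) or automatic (opened by the system for each
unresolved edit-check error, deduplicated per record/field/rule, and
system-closed once the offending rule passes after an edit).

Lifecycle: open → answered (respond) → closed; open → closed directly
(with a closure note); closed → open (reopen); open → cancelled.
Comments are allowed while a query is not terminal.  The conversation is
append-only; every state change is persisted as a new version of the
query's ledger DOI and emits a notification record.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field, asdict
from datetime import datetime
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Iterable, Optional

from .errors import EdcError, IllegalTransitionError, NotFoundError
from .ledger import Ledger
from .validation import ValidationFinding

_TRANSITIONS = {
    ("open", "respond"): "answered",
    ("open", "close"): "closed",
    ("answered", "close"): "closed",
    ("closed", "reopen"): "open",
    ("open", "cancel"): "cancelled",
    ("open", "comment"): "open",
    ("answered", "comment"): "answered",
}

SYSTEM_ACTOR = "system"


@dataclass
class ConversationEntry:
    actor: str
    role: str
    action: str
    text: str
    timestamp: str


@dataclass
class Query:
    query_id: str
    record_doi: str
    field_name: Optional[str]
    origin: str  # "auto" | "manual"
    status: str = "open"
    rule_id: Optional[str] = None  # auto queries only
    category: Optional[str] = None
    conversation: list[ConversationEntry] = field(default_factory=list)
    created_at: str = ""
    closed_at: Optional[str] = None

    @property
    def is_open(self) -> bool:
        return self.status in ("open", "answered")

    def to_payload(self) -> dict:
        return {
            "query_id": self.query_id,
            "record_doi": self.record_doi,
            "field_name": self.field_name,
            "origin": self.origin,
            "status": self.status,
            "rule_id": self.rule_id,
            "category": self.category,
            "conversation": [asdict(c) for c in self.conversation],
            "created_at": self.created_at,
            "closed_at": self.closed_at,
        }

    @classmethod
    def from_payload(cls, p: dict) -> "Query":
        q = cls(
            query_id=p["query_id"],
            record_doi=p["record_doi"],
            field_name=p["field_name"],
            origin=p["origin"],
            status=p["status"],
            rule_id=p["rule_id"],
            category=p["category"],
            created_at=p["created_at"],
            closed_at=p["closed_at"],
        )
        q.conversation = [ConversationEntry(**c) for c in p["conversation"]]
        return q


@dataclass
class StudyQueryMetrics:
    n_queries: int
    n_ecrfs: int
    rate_pct: Optional[float]  # None (reported blank) when n_ecrfs == 0
    n_open: int
    n_answered: int
    n_closed: int
    n_cancelled: int
    median_resolution_seconds: Optional[float]


def rate_pct(n_queries: int, n_ecrfs: int) -> Optional[float]:
    """Query rate 100·q/n, rounded half-up to one decimal; blank when n=0."""
    if n_ecrfs == 0:
        return None
    rate = Decimal(100) * Decimal(n_queries) / Decimal(n_ecrfs)
    return float(rate.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


class QueryStore:
    """Query registry persisted through the study ledger.

    The in-memory index rebuilds from the ledger by replay; the latest
    version of each query DOI is authoritative.
    """

    def __init__(
        self,
        ledger: Ledger,
        scope_checker: Optional[Callable[[str, Optional[str]], None]] = None,
    ):
        self.ledger = ledger
        self.queries: dict[str, Query] = {}
        #: validates (record_doi, field_name); raises UNKNOWN_SCOPE
        self.scope_checker = scope_checker

    # -- persistence -------------------------------------------------------

    def _persist_new(self, query: Query, actor: str) -> Query:
        # DOI ids are deterministic (type + creation seq), so the id can be
        # embedded in the version-1 payload
        query.query_id = f"query-{len(self.ledger.entries) + 1:06d}"
        entry = self.ledger.append_doi("query", query.to_payload(), actor)
        assert entry.doi_id == query.query_id
        self.queries[query.query_id] = query
        return query

    def _persist_update(self, query: Query, actor: str, action: str) -> None:
        self.ledger.amend_doi(
            query.query_id, query.to_payload(), actor, rfc=f"query:{action}"
        )

    def _notify(self, query: Query, event: str, recipient_role: str, actor: str) -> None:
        self.ledger.append_doi(
            "notification",
            {
                "recipient_role": recipient_role,
                "event": event,
                "query_id": query.query_id,
                "record_doi": query.record_doi,
            },
            actor,
        )

    @classmethod
    def rebuild(cls, ledger: Ledger,
                scope_checker: Optional[Callable] = None) -> "QueryStore":
        store = cls(ledger, scope_checker)
        for entry in ledger.entries:
            if entry.object_type == "query" and isinstance(entry.payload, dict):
                payload = dict(entry.payload)
                payload["query_id"] = payload["query_id"] or entry.doi_id
                store.queries[entry.doi_id] = Query.from_payload(payload)
        return store

    # -- operations --------------------------------------------------------

    def open_query(
        self,
        record_doi: str,
        actor: str,
        text: str,
        field_name: Optional[str] = None,
        origin: str = "manual",
        rule_id: Optional[str] = None,
        category: Optional[str] = None,
        role: str = "study-team",
    ) -> Query:
        """Open a query on a record or one of its fields.

        A duplicate open auto query (same record/field/rule) is not
        created; the existing one is returned.
        """
        if self.scope_checker is not None:
            self.scope_checker(record_doi, field_name)
        if origin == "auto":
            existing = self._find_open_auto(record_doi, field_name, rule_id)
            if existing is not None:
                return existing
        now = self.ledger._now()
        query = Query(
            query_id="",
            record_doi=record_doi,
            field_name=field_name,
            origin=origin,
            rule_id=rule_id if origin == "auto" else None,
            category=category,
            created_at=now,
        )
        query.conversation.append(
            ConversationEntry(actor=actor, role=role, action="open", text=text, timestamp=now)
        )
        self._persist_new(query, actor)
        self._notify(query, "query-opened", "site", actor)
        return query

    def _find_open_auto(
        self, record_doi: str, field_name: Optional[str], rule_id: Optional[str]
    ) -> Optional[Query]:
        for q in self.queries.values():
            if (
                q.origin == "auto"
                and q.is_open
                and q.record_doi == record_doi
                and q.field_name == field_name
                and q.rule_id == rule_id
            ):
                return q
        return None

    def get(self, query_id: str) -> Query:
        if query_id not in self.queries:
            raise NotFoundError(f"query {query_id!r} not found")
        return self.queries[query_id]

    def update_query(
        self,
        query_id: str,
        action: str,
        actor: str,
        text: str = "",
        role: str = "study-team",
    ) -> Query:
        query = self.get(query_id)
        key = (query.status, action)
        if key not in _TRANSITIONS:
            raise IllegalTransitionError(
                f"action {action!r} not legal in status {query.status!r}"
            )
        if action == "close" and not text:
            raise EdcError(
                "closing a query requires a closure note",
                code="CLOSURE_REASON_REQUIRED",
            )
        now = self.ledger._now()
        query.conversation.append(
            ConversationEntry(actor=actor, role=role, action=action, text=text, timestamp=now)
        )
        old_status = query.status
        query.status = _TRANSITIONS[key]
        if query.status == "closed":
            query.closed_at = now
        elif old_status == "closed":
            query.closed_at = None
        self._persist_update(query, actor, action)
        if query.status != old_status:
            recipient = "site" if role == "study-team" else "study-team"
            self._notify(query, f"query-{action}", recipient, actor)
        return query

    def sync_auto_queries(
        self,
        record_doi: str,
        findings: Iterable[ValidationFinding],
        actor: str = SYSTEM_ACTOR,
    ) -> tuple[list[Query], list[Query]]:
        """Reconcile open auto queries with the current error findings.

        One open auto query per failing (field, rule); rules no longer
        failing get their auto query system-closed; manual queries are
        never touched.
        """
        failing = {
            (f.field_name, f.rule_id): f
            for f in findings
            if f.severity == "error"
        }
        opened: list[Query] = []
        closed: list[Query] = []
        for (field_name, rule_id), finding in sorted(
            failing.items(), key=lambda kv: (kv[0][0] or "", kv[0][1])
        ):
            if self._find_open_auto(record_doi, field_name, rule_id) is None:
                opened.append(
                    self.open_query(
                        record_doi,
                        actor,
                        finding.message,
                        field_name=field_name,
                        origin="auto",
                        rule_id=rule_id,
                        category="edit-check",
                        role="system",
                    )
                )
        for q in list(self.queries.values()):
            if (
                q.origin == "auto"
                and q.is_open
                and q.record_doi == record_doi
                and (q.field_name, q.rule_id) not in failing
            ):
                self.update_query(
                    q.query_id, "close", actor,
                    text="edit check passes after correction", role="system",
                )
                closed.append(q)
        return opened, closed

    # -- reporting ---------------------------------------------------------

    def for_record(self, record_doi: str) -> list[Query]:
        return [q for q in self.queries.values() if q.record_doi == record_doi]

    def open_count(self, record_doi: Optional[str] = None) -> int:
        return sum(
            1
            for q in self.queries.values()
            if q.is_open and (record_doi is None or q.record_doi == record_doi)
        )

    def by_category(self, category: str) -> list[Query]:
        return [q for q in self.queries.values() if q.category == category]

    def query_metrics(self, n_ecrfs: int) -> StudyQueryMetrics:
        statuses = [q.status for q in self.queries.values()]
        durations = []
        for q in self.queries.values():
            if q.closed_at:
                dt = datetime.fromisoformat(q.closed_at) - datetime.fromisoformat(
                    q.created_at
                )
                durations.append(dt.total_seconds())
        return StudyQueryMetrics(
            n_queries=len(statuses),
            n_ecrfs=n_ecrfs,
            rate_pct=rate_pct(len(statuses), n_ecrfs),
            n_open=statuses.count("open"),
            n_answered=statuses.count("answered"),
            n_closed=statuses.count("closed"),
            n_cancelled=statuses.count("cancelled"),
            median_resolution_seconds=(
                statistics.median(durations) if durations else None
            ),
        )
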