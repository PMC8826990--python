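"""Append-only, digest-authenticated data ledger.

Every data value in a study — the study itself, participants, events,
form records, item values, files, and the auxiliary records around them
(control marks, queries, notifications, workflow runs) — is a *data
object instance* (DOI): a version-controlled payload whose every version
is one entry in an append-only ledger.

Each entry carries a SHA-256 digest of its canonical payload (key-sorted
compact JSON, UTF-8), the chain digest of the previous entry, a chain
digest over (previous digest, content digest, sequence number,
timestamp), and an HMAC-SHA-256 authentication code over the chain
digest keyed with a per-study secret.  The sequence number, not the
timestamp, orders the chain, so clock skew is tolerated.  Verification
recomputes every digest and code in order and reports the earliest
mismatch; any single-byte tamper in a stored entry is detected at or
before that entry.

Deletion is logical: a delete appends a new version in state "deleted";
no entry is ever rewritten or removed, so the full history of every
value remains reviewable.
"""

from __future__ import annotations

import hashlib
import hmac
import json
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from pathlib import Path
from typing import Callable, Iterable, Optional

from .errors import EdcError, LockedError, NotFoundError, RfcRequiredError

ZERO_DIGEST = "0" * 64

#: Primary data object types.
PRIMARY_OBJECT_TYPES = ("study", "participant", "event", "form-record", "field-value", "file")
#: Auxiliary object types: operational records that are themselves ledger
#: transactions (control marks, queries, notifications, workflow runs...).
AUX_OBJECT_TYPES = ("control-mark", "query", "notification", "workflow-run", "annotation", "link")

MARK_KINDS = ("lock", "unlock", "sdv", "sdv-clear")

ScopeKey = tuple[str, ...]


def canonical_payload_bytes(payload: object) -> bytes:
    """Canonical serialization of a payload: key-sorted, compact JSON."""
    return json.dumps(
        payload, sort_keys=True, separators=(",", ":"), ensure_ascii=False
    ).encode("utf-8")


def content_digest(payload: object) -> str:
    return hashlib.sha256(canonical_payload_bytes(payload)).hexdigest()


def chain_digest(
    prev_digest: str,
    content: str,
    seq: int,
    timestamp: str,
    doi_id: str = "",
    object_type: str = "",
    version: int = 0,
    actor: str = "",
    rfc: Optional[str] = None,
    state: str = "",
) -> str:
    """Chain digest over the previous digest, the content digest and the
    full entry header, so attribution (actor, RFC, state) is as
    tamper-evident as the payload itself."""
    material = "|".join(
        [prev_digest, content, str(seq), timestamp, doi_id, object_type,
         str(version), actor, rfc or "", state]
    ).encode("utf-8")
    return hashlib.sha256(material).hexdigest()


def auth_code(secret: bytes, chain: str) -> str:
    return hmac.new(secret, chain.encode("utf-8"), hashlib.sha256).hexdigest()


@dataclass(frozen=True)
class LedgerEntry:
    seq: int
    doi_id: str
    object_type: str
    version: int
    payload: object
    actor: str
    timestamp: str  # ISO 8601 UTC
    rfc: Optional[str]
    state: str  # "active" | "deleted"
    content_digest: str
    prev_digest: str
    chain_digest: str
    auth_code: str

    FIELD_ORDER = (
        "seq",
        "doi_id",
        "object_type",
        "version",
        "payload",
        "actor",
        "timestamp",
        "rfc",
        "state",
        "content_digest",
        "prev_digest",
        "chain_digest",
        "auth_code",
    )

    def to_json_line(self) -> str:
        return json.dumps(
            {name: getattr(self, name) for name in self.FIELD_ORDER},
            sort_keys=True,
            separators=(",", ":"),
            ensure_ascii=False,
        )

    @classmethod
    def from_json_line(cls, line: str) -> "LedgerEntry":
        d = json.loads(line)
        return cls(**{name: d[name] for name in cls.FIELD_ORDER})


@dataclass
class VersionDiff:
    from_version: int
    to_version: int
    changed_fields: tuple[str, ...]
    rfc: Optional[str]


@dataclass
class AuditView:
    """Full audit history of one DOI: every version, field-level diffs
    between consecutive form-record versions, and the control marks and
    queries that reference it."""

    doi_id: str
    versions: list[LedgerEntry]
    diffs: list[VersionDiff]
    control_marks: list[LedgerEntry] = field(default_factory=list)
    queries: list[LedgerEntry] = field(default_factory=list)

    @property
    def version_count(self) -> int:
        return len(self.versions)


def _diff_values(old: object, new: object) -> tuple[str, ...]:
    if not isinstance(old, dict) or not isinstance(new, dict):
        return ()
    a = old.get("values", old) if isinstance(old.get("values", None), dict) else old
    b = new.get("values", new) if isinstance(new.get("values", None), dict) else new
    changed = [k for k in sorted(set(a) | set(b)) if a.get(k) != b.get(k)]
    return tuple(changed)


class Ledger:
    """The per-study append-only ledger and its rebuildable indexes.

    The entry list is the source of truth; the per-DOI index and the
    lock/SDV state are derived and can be rebuilt by replay (see
    :meth:`from_entries`).
    """

    def __init__(
        self,
        study_secret: bytes | str,
        clock: Optional[Callable[[], datetime]] = None,
    ):
        self.secret = study_secret.encode() if isinstance(study_secret, str) else study_secret
        self.clock = clock or (lambda: datetime.now(timezone.utc))
        self.entries: list[LedgerEntry] = []
        self._by_doi: dict[str, list[int]] = {}
        self._locked: set[ScopeKey] = set()
        self._sdv: set[ScopeKey] = set()
        #: installed by the capture workflow: doi_id -> enclosing scope keys
        self.scope_resolver: Callable[[str], list[ScopeKey]] = lambda doi_id: []

    # -- core append -------------------------------------------------------

    def _now(self) -> str:
        ts = self.clock()
        if ts.tzinfo is None:
            ts = ts.replace(tzinfo=timezone.utc)
        return ts.astimezone(timezone.utc).isoformat()

    def _append(
        self,
        object_type: str,
        payload: object,
        actor: str,
        *,
        doi_id: Optional[str],
        version: int,
        rfc: Optional[str],
        state: str,
    ) -> LedgerEntry:
        if not actor:
            raise EdcError("actor must be nonempty", code="ACTOR_REQUIRED")
        try:
            content = content_digest(payload)
        except (TypeError, ValueError) as exc:
            raise EdcError(f"payload not canonicalizable: {exc}", code="BAD_PAYLOAD")
        seq = len(self.entries) + 1
        prev = self.entries[-1].chain_digest if self.entries else ZERO_DIGEST
        timestamp = self._now()
        if doi_id is None:
            doi_id = f"{object_type}-{seq:06d}"
        chain = chain_digest(prev, content, seq, timestamp, doi_id, object_type,
                             version, actor, rfc, state)
        entry = LedgerEntry(
            seq=seq,
            doi_id=doi_id,
            object_type=object_type,
            version=version,
            payload=payload,
            actor=actor,
            timestamp=timestamp,
            rfc=rfc,
            state=state,
            content_digest=content,
            prev_digest=prev,
            chain_digest=chain,
            auth_code=auth_code(self.secret, chain),
        )
        self.entries.append(entry)
        self._by_doi.setdefault(doi_id, []).append(seq - 1)
        return entry

    # -- DOI operations ----------------------------------------------------

    def append_doi(self, object_type: str, payload: object, actor: str) -> LedgerEntry:
        """Create a new DOI at version 1."""
        return self._append(
            object_type, payload, actor, doi_id=None, version=1, rfc=None, state="active"
        )

    def exists(self, doi_id: str) -> bool:
        return doi_id in self._by_doi

    def current(self, doi_id: str) -> LedgerEntry:
        if doi_id not in self._by_doi:
            raise NotFoundError(f"DOI {doi_id!r} not in ledger")
        return self.entries[self._by_doi[doi_id][-1]]

    def versions_of(self, doi_id: str) -> list[LedgerEntry]:
        if doi_id not in self._by_doi:
            raise NotFoundError(f"DOI {doi_id!r} not in ledger")
        return [self.entries[i] for i in self._by_doi[doi_id]]

    def check_writable(self, doi_id: str) -> None:
        for scope in [("doi", doi_id), *self.scope_resolver(doi_id)]:
            if tuple(scope) in self._locked:
                raise LockedError(f"scope {scope} is locked")

    def amend_doi(
        self,
        doi_id: str,
        payload: object,
        actor: str,
        rfc: str,
        state: str = "active",
    ) -> LedgerEntry:
        """Append the next version of an existing DOI.  Requires a reason
        for change and an unlocked scope; prior entries are untouched."""
        tip = self.current(doi_id)
        if not rfc:
            raise RfcRequiredError(f"amendment of {doi_id} requires a reason for change")
        self.check_writable(doi_id)
        return self._append(
            tip.object_type,
            payload,
            actor,
            doi_id=doi_id,
            version=tip.version + 1,
            rfc=rfc,
            state=state,
        )

    def delete_doi(self, doi_id: str, actor: str, rfc: str) -> LedgerEntry:
        """Logical delete: a terminal version in state 'deleted'."""
        tip = self.current(doi_id)
        return self.amend_doi(doi_id, tip.payload, actor, rfc, state="deleted")

    # -- control marks -----------------------------------------------------

    def apply_control_mark(
        self,
        scope: ScopeKey,
        kind: str,
        actor: str,
        rfc: Optional[str] = None,
    ) -> LedgerEntry:
        """Record a lock/unlock/SDV/SDV-clear mark on a scope.

        Scope keys nest (participant ⊃ event ⊃ record); a lock at any
        enclosing scope blocks writes within it.  Unlock and SDV-clear
        require a matching prior mark; unlock requires a reason for change.
        """
        scope = tuple(scope)
        if kind not in MARK_KINDS:
            raise EdcError(f"unknown control mark kind {kind!r}", code="BAD_MARK")
        if kind == "unlock":
            if scope not in self._locked:
                raise EdcError(f"scope {scope} is not locked", code="NO_PRIOR_MARK")
            if not rfc:
                raise RfcRequiredError("unlock requires a reason for change")
        if kind == "sdv-clear" and scope not in self._sdv:
            raise EdcError(f"scope {scope} has no SDV mark", code="NO_PRIOR_MARK")
        entry = self._append(
            "control-mark",
            {"scope": list(scope), "kind": kind},
            actor,
            doi_id=None,
            version=1,
            rfc=rfc,
            state="active",
        )
        self._apply_mark_state(scope, kind)
        return entry

    def _apply_mark_state(self, scope: ScopeKey, kind: str) -> None:
        if kind == "lock":
            self._locked.add(scope)
        elif kind == "unlock":
            self._locked.discard(scope)
        elif kind == "sdv":
            self._sdv.add(scope)
        elif kind == "sdv-clear":
            self._sdv.discard(scope)

    def is_locked(self, scope: ScopeKey) -> bool:
        return tuple(scope) in self._locked

    def is_sdv(self, scope: ScopeKey) -> bool:
        return tuple(scope) in self._sdv

    # -- audit -------------------------------------------------------------

    def history(self, doi_id: str) -> AuditView:
        versions = self.versions_of(doi_id)
        diffs = [
            VersionDiff(
                from_version=a.version,
                to_version=b.version,
                changed_fields=_diff_values(a.payload, b.payload),
                rfc=b.rfc,
            )
            for a, b in zip(versions, versions[1:])
        ]
        marks: list[LedgerEntry] = []
        queries: list[LedgerEntry] = []
        for entry in self.entries:
            p = entry.payload
            if not isinstance(p, dict):
                continue
            if entry.object_type == "control-mark" and doi_id in p.get("scope", []):
                marks.append(entry)
            elif entry.object_type == "query" and p.get("record_doi") == doi_id:
                queries.append(entry)
        return AuditView(
            doi_id=doi_id,
            versions=versions,
            diffs=diffs,
            control_marks=marks,
            queries=queries,
        )

    # -- verification ------------------------------------------------------

    def verify_chain(self, secret: bytes | str | None = None) -> Optional[int]:
        """Recompute every digest and authentication code in order.

        Returns ``None`` if the whole chain verifies, else the sequence
        number of the earliest failing entry.
        """
        key = self.secret if secret is None else (
            secret.encode() if isinstance(secret, str) else secret
        )
        return verify_entries(self.entries, key)

    # -- persistence -------------------------------------------------------

    def to_jsonl(self, path: str | Path) -> None:
        Path(path).write_text(
            "".join(e.to_json_line() + "\n" for e in self.entries), encoding="utf-8"
        )

    @classmethod
    def from_jsonl(
        cls,
        path: str | Path,
        study_secret: bytes | str,
        clock: Optional[Callable[[], datetime]] = None,
    ) -> "Ledger":
        text = Path(path).read_text(encoding="utf-8")
        entries = []
        for i, line in enumerate(text.splitlines()):
            if not line:
                continue
            try:
                entries.append(LedgerEntry.from_json_line(line))
            except (KeyError, TypeError, ValueError) as exc:
                raise EdcError(
                    f"ledger entry at line {i + 1} is unreadable: {exc!r}",
                    code="CORRUPT",
                )
        return cls.from_entries(entries, study_secret, clock=clock)

    @classmethod
    def from_entries(
        cls,
        entries: Iterable[LedgerEntry],
        study_secret: bytes | str,
        clock: Optional[Callable[[], datetime]] = None,
    ) -> "Ledger":
        """Rebuild a ledger (and all derived indexes) by replaying entries."""
        ledger = cls(study_secret, clock=clock)
        for entry in entries:
            ledger.entries.append(entry)
            ledger._by_doi.setdefault(entry.doi_id, []).append(entry.seq - 1)
            if entry.object_type == "control-mark" and isinstance(entry.payload, dict):
                ledger._apply_mark_state(
                    tuple(entry.payload["scope"]), entry.payload["kind"]
                )
        return ledger


def verify_entries(entries: list[LedgerEntry], secret: bytes) -> Optional[int]:
    prev = ZERO_DIGEST
    for i, entry in enumerate(entries):
        seq = i + 1
        if entry.seq != seq:
            return seq
        if entry.prev_digest != prev:
            return seq
        if content_digest(entry.payload) != entry.content_digest:
            return seq
        expected_chain = chain_digest(
            entry.prev_digest, entry.content_digest, entry.seq, entry.timestamp,
            entry.doi_id, entry.object_type, entry.version, entry.actor,
            entry.rfc, entry.state,
        )
        if expected_chain != entry.chain_digest:
            return seq
        if not hmac.compare_digest(auth_code(secret, entry.chain_digest), entry.auth_code):
            return seq
        prev = entry.chain_digest
    return None
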