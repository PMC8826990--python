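"""Topic-organized, version-controlled document repository.

Files are organized into *topics* (single-level, permissioned folders).
Topic types: ``standard`` (version control, annotations, RFC),
``site`` (same, but automatically spawns one sub-topic per trial site,
including sites registered later), ``archive`` (read-only) and
``transfer`` (read-write, with indexing metadata — source, received-at,
schema note — so it can front a study data lake).

Uploads can be validated at the point of entry against a topic's naming
rule (an anchored regular expression) and a registered content
validator.  Every upload, fetch and delete is appended to the usage log
and recorded as a ledger transaction; file versions are never deleted
and each version's bytes are retrievable and digest-verified.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

from .errors import DuplicateError, EdcError, NotFoundError
from .ledger import Ledger

TOPIC_TYPES = ("standard", "site", "archive", "transfer")

#: content validator: bytes -> None (ok) or an error message
ContentValidator = Callable[[bytes], Optional[str]]


@dataclass
class FileVersion:
    version: int
    digest: str
    size: int
    uploader: str
    timestamp: str
    rfc: Optional[str] = None
    annotation: Optional[str] = None
    deleted: bool = False


@dataclass
class StoredFile:
    file_name: str
    topic_name: str
    doi_id: str
    versions: list[FileVersion] = field(default_factory=list)

    @property
    def current_version(self) -> int:
        return self.versions[-1].version

    @property
    def is_deleted(self) -> bool:
        return self.versions[-1].deleted


@dataclass
class Topic:
    topic_name: str
    topic_type: str
    naming_rule: Optional[str] = None
    content_validator: Optional[str] = None
    retention: bool = False
    metadata: dict = field(default_factory=dict)  # transfer topics: indexing info
    subscribers: set[str] = field(default_factory=set)
    parent: Optional[str] = None  # site sub-topics
    site_code: Optional[str] = None


@dataclass(frozen=True)
class UsageLogEntry:
    actor: str
    action: str  # preview | download | upload | delete
    topic_name: str
    file_name: str
    version: int
    timestamp: str


# -- reference content validators -------------------------------------------


def utf8_text_validator(data: bytes) -> Optional[str]:
    """Accepts only valid UTF-8 text content."""
    try:
        data.decode("utf-8")
    except UnicodeDecodeError:
        return "content is not valid UTF-8 text"
    return None


def csv_required_columns(*columns: str) -> ContentValidator:
    """Validator factory: tabular (CSV) content must carry these columns."""

    def validator(data: bytes) -> Optional[str]:
        err = utf8_text_validator(data)
        if err:
            return err
        header = data.decode("utf-8").splitlines()
        if not header:
            return "empty file"
        present = [c.strip() for c in header[0].split(",")]
        missing = [c for c in columns if c not in present]
        if missing:
            return f"missing required column(s): {missing}"
        return None

    return validator


class DocumentRepository:
    def __init__(self, ledger: Ledger, blob_dir: str | Path | None = None):
        self.ledger = ledger
        self.topics: dict[str, Topic] = {}
        self.files: dict[tuple[str, str], StoredFile] = {}
        self.usage_log: list[UsageLogEntry] = []
        self.validators: dict[str, ContentValidator] = {}
        self.sites: list[str] = []
        self._blobs: dict[str, bytes] = {}
        self.blob_dir = Path(blob_dir) if blob_dir else None
        if self.blob_dir:
            self.blob_dir.mkdir(parents=True, exist_ok=True)

    # -- blob store (content-addressed) -----------------------------------

    def _store_bytes(self, data: bytes) -> str:
        digest = hashlib.sha256(data).hexdigest()
        if self.blob_dir:
            path = self.blob_dir / digest
            if not path.exists():
                path.write_bytes(data)
        self._blobs[digest] = data
        return digest

    def _load_bytes(self, digest: str) -> bytes:
        if digest in self._blobs:
            return self._blobs[digest]
        if self.blob_dir:
            path = self.blob_dir / digest
            if path.exists():
                data = path.read_bytes()
                self._blobs[digest] = data
                return data
        raise NotFoundError(f"blob {digest} not available")

    # -- validators --------------------------------------------------------

    def register_validator(self, name: str, validator: ContentValidator) -> None:
        self.validators[name] = validator

    # -- topics ------------------------------------------------------------

    def create_topic(
        self,
        topic_name: str,
        topic_type: str = "standard",
        naming_rule: Optional[str] = None,
        content_validator: Optional[str] = None,
        retention: bool = False,
        metadata: Optional[dict] = None,
        actor: str = "system",
    ) -> Topic:
        if topic_name in self.topics:
            raise DuplicateError(f"topic {topic_name!r} exists", code="DUPLICATE_TOPIC")
        if topic_type not in TOPIC_TYPES:
            raise EdcError(f"unknown topic type {topic_type!r}", code="BAD_TOPIC_TYPE")
        if content_validator is not None and content_validator not in self.validators:
            raise EdcError(
                f"content validator {content_validator!r} not registered",
                code="UNKNOWN_VALIDATOR",
            )
        topic = Topic(
            topic_name=topic_name,
            topic_type=topic_type,
            naming_rule=naming_rule,
            content_validator=content_validator,
            retention=retention,
            metadata=dict(metadata or {}),
        )
        self.topics[topic_name] = topic
        self.ledger.append_doi(
            "topic",
            {
                "topic_name": topic_name,
                "topic_type": topic_type,
                "naming_rule": naming_rule,
                "content_validator": content_validator,
                "retention": retention,
                "metadata": topic.metadata,
            },
            actor,
        )
        if topic_type == "site":
            for site in self.sites:
                self._spawn_site_subtopic(topic, site, actor)
        return topic

    def _spawn_site_subtopic(self, parent: Topic, site: str, actor: str) -> None:
        sub_name = f"{parent.topic_name}/{site}"
        if sub_name in self.topics:
            return
        sub = Topic(
            topic_name=sub_name,
            topic_type="standard",
            naming_rule=parent.naming_rule,
            content_validator=parent.content_validator,
            retention=parent.retention,
            parent=parent.topic_name,
            site_code=site,
        )
        self.topics[sub_name] = sub
        self.ledger.append_doi(
            "topic",
            {"topic_name": sub_name, "topic_type": "standard",
             "parent": parent.topic_name, "site_code": site},
            actor,
        )

    def on_site_added(self, site: str, actor: str = "system") -> None:
        """Hook called by the study when a new trial site registers."""
        if site not in self.sites:
            self.sites.append(site)
        for topic in list(self.topics.values()):
            if topic.topic_type == "site":
                self._spawn_site_subtopic(topic, site, actor)

    def topic(self, topic_name: str) -> Topic:
        if topic_name not in self.topics:
            raise NotFoundError(f"topic {topic_name!r} not found", code="UNKNOWN_TOPIC")
        return self.topics[topic_name]

    def subscribe(self, topic_name: str, user: str) -> None:
        self.topic(topic_name).subscribers.add(user)

    def _notify_subscribers(self, topic: Topic, event: str, file_name: str,
                            actor: str) -> int:
        count = 0
        for user in sorted(topic.subscribers):
            self.ledger.append_doi(
                "notification",
                {"recipient": user, "event": event,
                 "topic": topic.topic_name, "file": file_name},
                actor,
            )
            count += 1
        return count

    # -- files -------------------------------------------------------------

    def _log_usage(self, actor: str, action: str, topic_name: str,
                   file_name: str, version: int) -> None:
        entry = self.ledger.append_doi(
            "usage-log",
            {"action": action, "topic": topic_name, "file": file_name,
             "file_version": version},
            actor,
        )
        self.usage_log.append(
            UsageLogEntry(
                actor=actor,
                action=action,
                topic_name=topic_name,
                file_name=file_name,
                version=version,
                timestamp=entry.timestamp,
            )
        )

    def upload_file(
        self,
        topic_name: str,
        file_name: str,
        data: bytes,
        actor: str,
        rfc: Optional[str] = None,
        annotation: Optional[str] = None,
    ) -> FileVersion:
        topic = self.topic(topic_name)
        if topic.topic_type == "archive":
            raise EdcError(
                f"topic {topic_name!r} is an archive (read-only)", code="READ_ONLY"
            )
        if topic.naming_rule is not None and not re.fullmatch(topic.naming_rule, file_name):
            raise EdcError(
                f"file name {file_name!r} violates naming rule {topic.naming_rule!r}",
                code="NAMING_RULE_VIOLATION",
            )
        if topic.content_validator is not None:
            error = self.validators[topic.content_validator](data)
            if error:
                raise EdcError(
                    f"content of {file_name!r} rejected: {error}",
                    code="CONTENT_RULE_VIOLATION",
                )
        digest = self._store_bytes(data)
        key = (topic_name, file_name)
        stored = self.files.get(key)
        payload = {
            "topic": topic_name,
            "file_name": file_name,
            "digest": digest,
            "size": len(data),
            "annotation": annotation,
        }
        if stored is None:
            entry = self.ledger.append_doi("file", payload, actor)
            stored = StoredFile(file_name=file_name, topic_name=topic_name,
                                doi_id=entry.doi_id)
            self.files[key] = stored
        else:
            entry = self.ledger.amend_doi(
                stored.doi_id, payload, actor,
                rfc=rfc or f"upload version {stored.current_version + 1}",
            )
        version = FileVersion(
            version=len(stored.versions) + 1,
            digest=digest,
            size=len(data),
            uploader=actor,
            timestamp=entry.timestamp,
            rfc=rfc,
            annotation=annotation,
        )
        stored.versions.append(version)
        self._log_usage(actor, "upload", topic_name, file_name, version.version)
        self._notify_subscribers(topic, "file-uploaded", file_name, actor)
        return version

    def get_file(self, topic_name: str, file_name: str) -> StoredFile:
        key = (topic_name, file_name)
        if key not in self.files:
            raise NotFoundError(f"file {file_name!r} not in topic {topic_name!r}")
        return self.files[key]

    def fetch_file(
        self,
        topic_name: str,
        file_name: str,
        actor: str,
        version: Optional[int] = None,
        mode: str = "download",
    ) -> bytes:
        if mode not in ("preview", "download"):
            raise EdcError(f"unknown fetch mode {mode!r}", code="BAD_MODE")
        stored = self.get_file(topic_name, file_name)
        v = version or stored.current_version
        matches = [fv for fv in stored.versions if fv.version == v]
        if not matches:
            raise NotFoundError(f"version {v} of {file_name!r} not found")
        data = self._load_bytes(matches[0].digest)
        if hashlib.sha256(data).hexdigest() != matches[0].digest:
            raise EdcError("stored bytes fail digest verification", code="DIGEST_MISMATCH")
        self._log_usage(actor, mode, topic_name, file_name, v)
        return data

    def delete_file(self, topic_name: str, file_name: str, actor: str, rfc: str) -> None:
        """Logical delete; all versions remain retrievable."""
        topic = self.topic(topic_name)
        if topic.topic_type == "archive":
            raise EdcError(f"topic {topic_name!r} is read-only", code="READ_ONLY")
        stored = self.get_file(topic_name, file_name)
        self.ledger.delete_doi(stored.doi_id, actor, rfc)
        last = stored.versions[-1]
        stored.versions.append(
            FileVersion(
                version=last.version + 1,
                digest=last.digest,
                size=last.size,
                uploader=actor,
                timestamp=self.ledger._now(),
                rfc=rfc,
                deleted=True,
            )
        )
        self._log_usage(actor, "delete", topic_name, file_name, stored.current_version)
        self._notify_subscribers(topic, "file-deleted", file_name, actor)

    # -- replay ------------------------------------------------------------

    @classmethod
    def rebuild(cls, ledger: Ledger, blob_dir: str | Path | None = None,
                sites: Optional[list[str]] = None) -> "DocumentRepository":
        """Rebuild topics, files and the usage log from the ledger."""
        repo = cls(ledger, blob_dir=blob_dir)
        repo.sites = list(sites or [])
        for entry in ledger.entries:
            p = entry.payload if isinstance(entry.payload, dict) else {}
            if entry.object_type == "topic":
                topic = Topic(
                    topic_name=p["topic_name"],
                    topic_type=p["topic_type"],
                    naming_rule=p.get("naming_rule"),
                    content_validator=p.get("content_validator"),
                    retention=bool(p.get("retention")),
                    metadata=dict(p.get("metadata") or {}),
                    parent=p.get("parent"),
                    site_code=p.get("site_code"),
                )
                repo.topics[topic.topic_name] = topic
            elif entry.object_type == "file" and "topic" in p:
                key = (p["topic"], p["file_name"])
                stored = repo.files.get(key)
                if stored is None:
                    stored = StoredFile(
                        file_name=p["file_name"], topic_name=p["topic"],
                        doi_id=entry.doi_id,
                    )
                    repo.files[key] = stored
                stored.versions.append(
                    FileVersion(
                        version=len(stored.versions) + 1,
                        digest=p["digest"],
                        size=p["size"],
                        uploader=entry.actor,
                        timestamp=entry.timestamp,
                        rfc=entry.rfc,
                        annotation=p.get("annotation"),
                        deleted=entry.state == "deleted",
                    )
                )
            elif entry.object_type == "usage-log":
                repo.usage_log.append(
                    UsageLogEntry(
                        actor=entry.actor,
                        action=p["action"],
                        topic_name=p["topic"],
                        file_name=p["file"],
                        version=p["file_version"],
                        timestamp=entry.timestamp,
                    )
                )
        return repo

    # -- reporting ---------------------------------------------------------

    def file_counts(self) -> tuple[int, int]:
        """(number of files, total file versions), counting upload versions."""
        files = [f for f in self.files.values()]
        n_versions = sum(
            sum(1 for v in f.versions if not v.deleted) for f in files
        )
        return len(files), n_versions
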