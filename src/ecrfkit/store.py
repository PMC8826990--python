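"""On-disk study persistence.

A study lives in one directory::

    <root>/<study_id>/
        config.json    canonical configuration
        secret         per-study HMAC key (hex)
        ledger.jsonl   the append-only ledger, one entry per line
        blobs/         content-addressed document bytes

The ledger file is the source of truth for all mutable state; loading a
study replays it (the chain is verified first).
"""

from __future__ import annotations

import json
import secrets as _secrets
from pathlib import Path

from .capture import Study
from .errors import EdcError, NotFoundError
from .ledger import Ledger
from .workbook import config_from_dict, config_to_dict


def study_dir(root: str | Path, study_id: str) -> Path:
    return Path(root) / study_id


def save_study(study: Study, root: str | Path) -> Path:
    target = study_dir(root, study.config.study_id)
    target.mkdir(parents=True, exist_ok=True)
    (target / "config.json").write_text(
        json.dumps(config_to_dict(study.config), indent=1, sort_keys=True),
        encoding="utf-8",
    )
    secret_path = target / "secret"
    if not secret_path.exists():
        secret_path.write_text(study.ledger.secret.hex(), encoding="utf-8")
    study.ledger.to_jsonl(target / "ledger.jsonl")
    return target


def create_study(config, root: str | Path, secret: bytes | None = None) -> Study:
    target = study_dir(root, config.study_id)
    if (target / "ledger.jsonl").exists():
        raise EdcError(
            f"study {config.study_id!r} already initialized at {target}",
            code="DUPLICATE",
        )
    study = Study(config, secret if secret is not None else _secrets.token_bytes(32),
                  blob_dir=target / "blobs")
    save_study(study, root)
    return study


def load_study(root: str | Path, study_id: str, verify: bool = True) -> Study:
    target = study_dir(root, study_id)
    config_path = target / "config.json"
    if not config_path.exists():
        raise NotFoundError(f"no study {study_id!r} under {root}")
    config = config_from_dict(json.loads(config_path.read_text(encoding="utf-8")))
    secret = bytes.fromhex((target / "secret").read_text(encoding="utf-8").strip())
    ledger = Ledger.from_jsonl(target / "ledger.jsonl", secret)
    if verify:
        failing = ledger.verify_chain()
        if failing is not None:
            raise EdcError(
                f"ledger verification failed at seq {failing}", code="TAMPERED"
            )
    return Study.replay(config, ledger, blob_dir=target / "blobs")
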