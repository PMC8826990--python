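"""Hash-chain ledger: digests, append-only behaviour, tamper evidence."""

import dataclasses
import hashlib
import json
import random

import pytest

from ecrfkit import EdcError, Ledger, LockedError, NotFoundError, RfcRequiredError
from ecrfkit.ledger import ZERO_DIGEST, verify_entries
from conftest import TickingClock


def independent_canonical(payload) -> bytes:
    """Second canonicalization implementation, written from the format
    description (key-sorted, compact separators, UTF-8) rather than shared
    with the ledger code."""

    def render(obj):
        if obj is None:
            return "null"
        if obj is True:
            return "true"
        if obj is False:
            return "false"
        if isinstance(obj, str):
            return json.dumps(obj, ensure_ascii=False)
        if isinstance(obj, (int, float)):
            return json.dumps(obj)
        if isinstance(obj, list):
            return "[" + ",".join(render(x) for x in obj) + "]"
        if isinstance(obj, dict):
            items = sorted(obj.items())
            return "{" + ",".join(f"{render(k)}:{render(v)}" for k, v in items) + "}"
        raise TypeError(obj)

    return render(payload).encode("utf-8")


@pytest.fixture
def ledger():
    return Ledger(b"k1", clock=TickingClock())


class TestAppendAmend:
    def test_first_entry_links_to_zero_digest(self, ledger):
        entry = ledger.append_doi("study", {"study_id": "S"}, "alice")
        assert entry.seq == 1
        assert entry.prev_digest == ZERO_DIGEST
        assert entry.version == 1

    def test_content_digest_matches_independent_implementation(self, ledger):
        payload = {"b": 1, "a": {"z": [1, 2, None], "é": "ü"}, "flag": True}
        entry = ledger.append_doi("form-record", payload, "alice")
        assert entry.content_digest == hashlib.sha256(
            independent_canonical(payload)
        ).hexdigest()

    def test_empty_actor_rejected(self, ledger):
        with pytest.raises(EdcError):
            ledger.append_doi("study", {}, "")

    def test_amend_chains_and_preserves_prior_entries(self, ledger):
        e1 = ledger.append_doi("form-record", {"values": {"A": "1"}}, "alice")
        snapshot = e1.to_json_line()
        e2 = ledger.amend_doi(e1.doi_id, {"values": {"A": "2"}}, "bob", rfc="typo")
        assert e2.version == 2
        assert e2.prev_digest == e1.chain_digest
        assert ledger.entries[0].to_json_line() == snapshot

    def test_amend_requires_rfc(self, ledger):
        e1 = ledger.append_doi("form-record", {"values": {}}, "alice")
        with pytest.raises(RfcRequiredError):
            ledger.amend_doi(e1.doi_id, {"values": {"A": "1"}}, "alice", rfc="")

    def test_amend_unknown_doi(self, ledger):
        with pytest.raises(NotFoundError):
            ledger.amend_doi("nope", {}, "alice", rfc="r")

    def test_logical_delete_keeps_history(self, ledger):
        e1 = ledger.append_doi("form-record", {"values": {"A": "1"}}, "alice")
        before = len(ledger.entries)
        ledger.delete_doi(e1.doi_id, "alice", rfc="entered in error")
        assert len(ledger.entries) == before + 1
        assert ledger.current(e1.doi_id).state == "deleted"
        assert ledger.history(e1.doi_id).version_count == 2


class TestControlMarks:
    def test_lock_blocks_amend_within_scope(self, ledger):
        e1 = ledger.append_doi("form-record", {"values": {}}, "alice")
        ledger.apply_control_mark(("doi", e1.doi_id), "lock", "monitor")
        with pytest.raises(LockedError):
            ledger.amend_doi(e1.doi_id, {"values": {"A": "1"}}, "alice", rfc="r")
        ledger.apply_control_mark(("doi", e1.doi_id), "unlock", "monitor", rfc="review done")
        ledger.amend_doi(e1.doi_id, {"values": {"A": "1"}}, "alice", rfc="r")

    def test_unlock_requires_prior_lock_and_rfc(self, ledger):
        with pytest.raises(EdcError) as exc:
            ledger.apply_control_mark(("record", "x"), "unlock", "m", rfc="r")
        assert exc.value.code == "NO_PRIOR_MARK"
        ledger.apply_control_mark(("record", "x"), "lock", "m")
        with pytest.raises(RfcRequiredError):
            ledger.apply_control_mark(("record", "x"), "unlock", "m")

    def test_sdv_mark_appears_in_history(self, ledger):
        e1 = ledger.append_doi("form-record", {"values": {}}, "alice")
        ledger.apply_control_mark(("record", e1.doi_id), "sdv", "monitor")
        view = ledger.history(e1.doi_id)
        assert len(view.control_marks) == 1
        assert view.control_marks[0].payload["kind"] == "sdv"
        assert view.control_marks[0].timestamp

    def test_sdv_clear_requires_prior_mark(self, ledger):
        with pytest.raises(EdcError):
            ledger.apply_control_mark(("record", "x"), "sdv-clear", "m")


class TestHistory:
    def test_diffs_name_exactly_changed_fields(self, ledger):
        e1 = ledger.append_doi("form-record", {"values": {"A": "1", "B": "2"}}, "alice")
        ledger.amend_doi(e1.doi_id, {"values": {"A": "1", "B": "3"}}, "bob", rfc="fix B")
        ledger.amend_doi(e1.doi_id, {"values": {"A": "9", "B": "3", "C": "7"}}, "bob",
                         rfc="fix A add C")
        view = ledger.history(e1.doi_id)
        assert view.version_count == 3
        assert [d.changed_fields for d in view.diffs] == [("B",), ("A", "C")]
        assert [d.rfc for d in view.diffs] == ["fix B", "fix A add C"]

    def test_unknown_doi(self, ledger):
        with pytest.raises(NotFoundError):
            ledger.history("missing")


def random_operations(ledger, n_ops, seed):
    rng = random.Random(seed)
    dois = []
    for _ in range(n_ops):
        op = rng.random()
        if op < 0.5 or not dois:
            entry = ledger.append_doi(
                rng.choice(["form-record", "field-value", "participant"]),
                {"values": {f"F{rng.randint(1, 9)}": str(rng.randint(0, 99))}},
                f"user{rng.randint(1, 5)}",
            )
            dois.append(entry.doi_id)
        elif op < 0.85:
            doi = rng.choice(dois)
            try:
                ledger.amend_doi(
                    doi,
                    {"values": {f"F{rng.randint(1, 9)}": str(rng.randint(0, 99))}},
                    "editor",
                    rfc="random edit",
                )
            except LockedError:
                pass
        elif op < 0.95:
            scope = ("doi", rng.choice(dois))
            if ledger.is_locked(scope):
                ledger.apply_control_mark(scope, "unlock", "monitor", rfc="r")
            else:
                ledger.apply_control_mark(scope, "lock", "monitor")
        else:
            try:
                ledger.delete_doi(rng.choice(dois), "admin", rfc="cleanup")
            except LockedError:
                pass


class TestVerification:
    def test_valid_chain_verifies_after_many_random_operations(self, ledger):
        random_operations(ledger, 1100, seed=11)  # some ops no-op on locked DOIs
        assert len(ledger.entries) >= 1000
        assert ledger.verify_chain() is None

    def test_wrong_secret_fails_at_first_entry(self, ledger):
        random_operations(ledger, 20, seed=1)
        assert ledger.verify_chain(b"other-key") == 1

    @pytest.mark.parametrize("site", ["payload", "content_digest", "prev_digest",
                                      "chain_digest", "auth_code", "seq", "timestamp",
                                      "actor", "state"])
    def test_single_field_tamper_detected_at_or_before_entry(self, ledger, site):
        random_operations(ledger, 60, seed=3)
        rng = random.Random(hash(site) % 10**6)
        for _ in range(12):
            k = rng.randrange(len(ledger.entries))
            entry = ledger.entries[k]
            if site == "payload":
                mutated = dataclasses.replace(
                    entry, payload={**entry.payload, "values": {"X": "tampered"}}
                )
            elif site == "seq":
                mutated = dataclasses.replace(entry, seq=entry.seq + 1)
            elif site == "timestamp":
                mutated = dataclasses.replace(entry, timestamp=entry.timestamp[:-1] + "9")
            else:
                value = getattr(entry, site)
                flipped = ("0" if value[0] != "0" else "1") + value[1:]
                mutated = dataclasses.replace(entry, **{site: flipped})
            entries = list(ledger.entries)
            entries[k] = mutated
            failing = verify_entries(entries, ledger.secret)
            assert failing is not None and failing <= k + 1, (site, k)

    def test_jsonl_round_trip_preserves_chain(self, ledger, tmp_path):
        random_operations(ledger, 50, seed=5)
        path = tmp_path / "ledger.jsonl"
        ledger.to_jsonl(path)
        loaded = Ledger.from_jsonl(path, b"k1")
        assert loaded.verify_chain() is None
        assert [e.to_json_line() for e in loaded.entries] == [
            e.to_json_line() for e in ledger.entries
        ]

    def test_byte_level_tamper_in_stored_file_detected(self, ledger, tmp_path):
        random_operations(ledger, 30, seed=7)
        path = tmp_path / "ledger.jsonl"
        ledger.to_jsonl(path)
        lines = path.read_text().splitlines()
        k = 12
        lines[k] = lines[k].replace('"values"', '"valuez"', 1)
        path.write_text("\n".join(lines) + "\n")
        loaded = Ledger.from_jsonl(path, b"k1")
        failing = loaded.verify_chain()
        assert failing is not None and failing <= k + 1
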