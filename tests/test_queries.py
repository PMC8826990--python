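"""Query lifecycle state machine, deduplication, metrics arithmetic."""

import random

import pytest

from ecrfkit import EdcError, IllegalTransitionError, Ledger, rate_pct
from ecrfkit.queries import _TRANSITIONS, QueryStore
from ecrfkit.validation import ValidationFinding
from conftest import GOOD_PAYLOAD, TickingClock


@pytest.fixture
def store():
    return QueryStore(Ledger(b"k", clock=TickingClock()))


def err(field, rule):
    return ValidationFinding(field, rule, "error", f"{rule} on {field}")


class TestLifecycle:
    def test_open_then_respond_then_close_keeps_conversation(self, store):
        q = store.open_query("rec-1", "dm", "please verify", field_name="AGE",
                             category="clarification")
        assert q.status == "open" and len(q.conversation) == 1
        store.update_query(q.query_id, "respond", "site-user", "confirmed 42",
                           role="site")
        store.update_query(q.query_id, "close", "dm", "resolved")
        q = store.get(q.query_id)
        assert q.status == "closed"
        assert [c.action for c in q.conversation] == ["open", "respond", "close"]
        assert q.closed_at is not None

    def test_close_without_text_rejected(self, store):
        q = store.open_query("rec-1", "dm", "check this")
        with pytest.raises(EdcError) as exc:
            store.update_query(q.query_id, "close", "dm", "")
        assert exc.value.code == "CLOSURE_REASON_REQUIRED"

    def test_reopen_emits_notification_and_returns_open(self, store):
        q = store.open_query("rec-1", "dm", "check")
        store.update_query(q.query_id, "close", "dm", "done")
        before = sum(
            1 for e in store.ledger.entries if e.object_type == "notification"
        )
        store.update_query(q.query_id, "reopen", "dm", "not actually resolved")
        assert store.get(q.query_id).status == "open"
        after = sum(1 for e in store.ledger.entries if e.object_type == "notification")
        assert after == before + 1

    @pytest.mark.parametrize(
        "setup,action",
        [
            ([], "respond"),  # answered -> respond again? start from answered below
            (["respond"], "respond"),
            (["cancel"], "close"),
            (["close"], "cancel"),
            (["close"], "respond"),
        ],
    )
    def test_illegal_transitions_rejected(self, store, setup, action):
        q = store.open_query("rec-1", "dm", "check")
        for a in setup:
            store.update_query(q.query_id, a, "u", "t", role="site")
        if not setup and action == "respond":
            store.update_query(q.query_id, "respond", "u", "t", role="site")
        with pytest.raises(IllegalTransitionError):
            store.update_query(q.query_id, action, "u", "t")

    def test_random_legal_sequences_never_reach_undefined_state(self, store):
        rng = random.Random(5)
        states = {"open", "answered", "closed", "cancelled"}
        for i in range(60):
            q = store.open_query(f"rec-{i}", "dm", "check")
            length_before = 1
            for _ in range(rng.randint(0, 8)):
                legal = [a for (s, a) in _TRANSITIONS if s == q.status]
                if not legal:
                    break
                action = rng.choice(legal)
                q = store.update_query(q.query_id, action, "u", "some text")
                assert q.status in states
                # conversation is append-only
                assert len(q.conversation) == length_before + 1
                length_before += 1

    def test_unknown_scope_checked_when_checker_installed(self):
        def checker(record_doi, field_name):
            raise EdcError("nope", code="UNKNOWN_SCOPE")

        store = QueryStore(Ledger(b"k", clock=TickingClock()), scope_checker=checker)
        with pytest.raises(EdcError) as exc:
            store.open_query("ghost", "dm", "check")
        assert exc.value.code == "UNKNOWN_SCOPE"


class TestAutoQuerySync:
    def test_dedup_across_successive_validations(self, store):
        findings = [err("AGE", "RANGE")]
        opened1, _ = store.sync_auto_queries("rec-1", findings)
        opened2, _ = store.sync_auto_queries("rec-1", findings)
        assert len(opened1) == 1 and opened2 == []
        assert store.open_count("rec-1") == 1

    def test_passing_rule_system_closes_query(self, store):
        store.sync_auto_queries("rec-1", [err("AGE", "RANGE")])
        opened, closed = store.sync_auto_queries("rec-1", [])
        assert opened == [] and len(closed) == 1
        assert closed[0].status == "closed"
        assert closed[0].conversation[-1].actor == "system"

    def test_manual_query_on_same_field_untouched(self, store):
        manual = store.open_query("rec-1", "dm", "check age", field_name="AGE")
        store.sync_auto_queries("rec-1", [err("AGE", "RANGE")])
        store.sync_auto_queries("rec-1", [])
        assert store.get(manual.query_id).status == "open"

    def test_category_stored_and_filterable(self, store):
        store.open_query("rec-1", "dm", "a", category="protocol-deviation")
        store.open_query("rec-2", "dm", "b", category="clarification")
        assert [q.record_doi for q in store.by_category("protocol-deviation")] == ["rec-1"]


class TestMetrics:
    # printed operational counts of the seven supported studies
    PUBLISHED = [
        (11644, 136876, 8.5),
        (9275, 63200, 14.7),
        (4919, 28843, 17.1),
        (7361, 61656, 11.9),
        (2601, 20623, 12.6),
        (1086, 26592, 4.1),
        (1, 26, 3.8),
    ]

    @pytest.mark.parametrize("n_queries,n_ecrfs,expected", PUBLISHED)
    def test_published_rates_reproduced_with_half_up_rounding(
        self, n_queries, n_ecrfs, expected
    ):
        assert rate_pct(n_queries, n_ecrfs) == expected

    def test_rate_edge_cases(self):
        assert rate_pct(0, 100) == 0.0
        assert rate_pct(5, 0) is None  # blank when no eCRFs
        assert rate_pct(1, 4000) == 0.0  # 0.025 -> 0.0
        assert rate_pct(1, 2000) == 0.1  # 0.05 rounds half-up

    def test_metrics_agree_with_brute_force_scan(self, store):
        rng = random.Random(9)
        for i in range(40):
            q = store.open_query(f"rec-{i}", "dm", "check")
            roll = rng.random()
            if roll < 0.3:
                store.update_query(q.query_id, "respond", "site", "done", role="site")
            elif roll < 0.6:
                store.update_query(q.query_id, "close", "dm", "ok")
            elif roll < 0.7:
                store.update_query(q.query_id, "cancel", "dm", "dup")
        m = store.query_metrics(n_ecrfs=200)
        statuses = [q.status for q in store.queries.values()]
        assert m.n_queries == len(statuses) == 40
        assert m.n_open == statuses.count("open")
        assert m.n_answered == statuses.count("answered")
        assert m.n_closed == statuses.count("closed")
        assert m.n_cancelled == statuses.count("cancelled")
        assert m.rate_pct == rate_pct(40, 200) == 20.0
        if m.n_closed:
            assert m.median_resolution_seconds > 0
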