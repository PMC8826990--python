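# Methods

This note records the design of each component, the parameters that
matter, the numerical choices, and what the synthetic fixtures do and do
not establish about real study data.

## Configuration metadata

A study is a frozen object graph: events (strictly increasing order),
eCRFs, sites and languages. Each eCRF carries versions; each version
carries revisions numbered consecutively from 1 with non-decreasing
activation times. The workbook format is six sheets (`study`, `events`,
`crfs`, `fields`, `choices`, `files`) as CSV files or one XLSX; booleans
are `Y`/blank, multi-valued cells are semicolon-separated, and an
attribute with multi-language support takes one extra column per
translation (`QUESTION.ja`), the unsuffixed column being the default
language. Choices are keyed by (CRF, field) and shared across revisions
of a CRF, as are file-attachment definitions; a configuration in which
revisions of one CRF need different choice lists should model that as a
new field name. Range specs accept both `…` and `...`; the step is
optional because ranges in practice often constrain only the interval.

Length semantics (`total,decimals`): for text, `total` bounds the
character count; for numerics, `total` bounds the count of significant
digits (sign and decimal separator excluded) and `decimals` the digits
after the separator. Date fields take no length spec. `INDENT` is
presentation metadata: validated non-negative, otherwise inert.

`validate_config` returns an ordered, deterministic finding list (code,
location, message); the capture layer refuses any configuration with an
error finding. Version resolution is a pure function of (CRF, creation
timestamp, optional user choice): the system picks the version whose
latest activated revision at that time is newest; a user choice is legal
only where the CRF allows it. Because records store their resolved
(version, revision) in the ledger, later activations never re-resolve
existing records.

## Validation engine

The skip-pattern grammar is a conjunction of comparison clauses
(`= != < <= > >= IN`), AND-only, no nesting. This keeps the logic
decidable, lets the configuration checker prove that every referenced
field precedes its dependent, and makes exhaustive oracle testing
feasible. Clause literals are typed against the referenced field:
numeric fields compare as floats, text and date fields as strings (ISO
dates order correctly lexicographically). A raw value that cannot be
coerced makes its clause false rather than raising, so entry can never
deadlock on a half-typed parent. Hiding is transitive: a field whose
condition references a hidden field is hidden.

Two sentinels keep absence unambiguous: `MISSING` (the site checked the
missing box; legal only where the field allows it; satisfies
required-ness) and `UNANSWERED` (no value, or hidden). Values supplied
for hidden fields are flagged (`HIDDEN_VALUE`) and cleared. Defaults
fill only fields the payload never touched, before visibility is
computed, so a defaulted parent drives skip logic exactly as rendered.
Step membership uses a relative tolerance of 1e-9 so that binary
representation of decimal steps (0.1) never produces false positives.
Partial dates on the lenient date picker are `YYYY` or `YYYY-MM`; the
strict picker requires a full valid `YYYY-MM-DD`; times are `HH:MM` in
00:00–23:59. All metadata-derived checks are errors; a pluggable
registry hook exists for study-specific quality rules, which are
downgraded to warnings.

Double entry compares clean (typed) values field-wise, only on fields
configured for it, so formatting differences ("72.50" vs "72.5") are not
discrepancies.

## Data ledger

Canonical payload form is key-sorted, whitespace-free JSON, UTF-8. The
chain digest covers the previous chain digest, the content digest and
the full entry header — sequence, timestamp, DOI id, object type,
version, actor, RFC, state — so attribution is as tamper-evident as the
data; an earlier design that chained only (prev, content, seq, time)
left the stored actor mutable without detection and was rejected when a
test demonstrated exactly that. Authentication is HMAC-SHA-256 with a
per-study secret; asymmetric signatures and key rotation are out of
scope. Sequence number, not timestamp, orders the chain, so clock skew
between writers is harmless. The zero digest is 64 hex zeros.

Everything operational is itself a ledger transaction: beyond the six
primary object types (study, participant, event, form-record,
field-value, file) the ledger records control marks, queries,
notifications, workflow runs, topics and usage-log entries as auxiliary
types. The payoff is replay: the JSON-Lines log is the single source of
truth, every in-memory index (per-DOI versions, lock state, query store,
document catalog) is rebuilt by replay, and index corruption is
recoverable. Locks nest participant ⊃ event ⊃ record; a lock at any
enclosing scope blocks amendments and submissions inside it. Deletion
is logical — a terminal version in state `deleted` — so entry counts
never decrease and history remains reviewable.

## Capture workflow

A record's completion is derived, never stored: complete iff it has no
error findings and every required visible field is answered (an explicit
missing mark counts as answered). The event matrix reports, per (event,
required CRF), one of five states — `missing` (no live record),
`incomplete`, `complete`, `complete-with-queries` (complete but with
open queries), `locked` — plus a progress fraction
answered-required-visible / total-required-visible and per-event open
query counts. Lock status takes precedence; incompleteness takes
precedence over query annotation. Cross-event CRFs (medication and
adverse-event logs) share one instance sequence across events, retain
their originating event, appear once in exports, and are listed as
supplemental from every event view.

Workflows are ordered steps over seven elementary actions (insert, edit,
delete, annotate, link, copy, execute) with optional conditions in the
same grammar as skip patterns, evaluated over a flat context map — one
grammar, tested once. Steps act only through the public capture
operations, so no workflow can bypass the ledger; a false condition logs
`skipped` with no ledger write; a failure halts the run; the
`async_eligible` flag is recorded but execution is sequential by design.
Execute steps name handlers registered up front; unknown handlers are
rejected at workflow registration, not at run time.

## Query management

Four states: open → answered (respond) → closed, open → closed (with a
mandatory closure note), closed → open (reopen), open → cancelled;
comments append without changing state. The conversation is append-only
and persisted as versions of the query's ledger DOI. Auto queries are
deduplicated per (record, field, rule) while open, and are closed by the
`system` actor when the rule passes after an edit — manual queries
always require human closure. Status changes emit persisted
notification records (recipient role, event, reference); no transport is
attempted.

The query rate is `100·q/n` rounded half-up to one decimal
(`decimal.Decimal`, `ROUND_HALF_UP`), blank when `n = 0`. Half-up was
chosen because it reproduces all seven published study rates from their
printed (queries, eCRFs) pairs, including the 17.054 → 17.1 case that
would also survive round-half-even and the 0.05-boundary behaviour that
would not.

## Documents and exports

Topic naming rules are anchored regular expressions; content validators
are registered named hooks (two reference validators ship: UTF-8 text,
and required-CSV-columns for tabular transfers). Site topics spawn one
sub-topic per site, including sites registered later. Archive topics
reject writes; transfer topics carry indexing metadata (source,
schema note) so the repository can front a data lake. File bytes are
content-addressed by SHA-256 outside the ledger; the ledger stores
digests, so fetches are digest-verified. Every upload, fetch and delete
appends to the usage log.

CSV export is RFC 4180 with CRLF, one table per eCRF: seven key columns
(study, site, participant, event, instance, version, revision) then
fields in the order of the newest revision, with fields present only in
older revisions appended alphabetically. JSON export nests study →
participants → events → records → items, each item carrying value,
status, last-modified time and open-query count, with optional per-item
audit history. PHI handling defaults to masking every cell of a PHI
column with `[MASKED]` (masking even empty cells deliberately leaks
nothing about answered-ness); `drop` removes the column; `include`
demands an explicit override flag. `MISSING` and the empty cell encode
checked-missing vs unanswered. Exports of an unchanged study are
byte-identical. The summary report's totals row sums every count
column and leaves the pooled rate blank.

## Fixtures and what they show

The generator builds configurations whose composition is exact, not
expected: `round(fraction × total_fields)` fields receive skip patterns
(parents are always the first field of the CRF, a required three-choice
radio), PHI flags and missing-allowed flags. The widget templates cycle
through every widget class so every edit-check rule is exercised.
Simulated entry walks fields in form order, honours skip logic against
the values actually generated, and corrupts each validated (visible)
field independently with probability `error_rate` using per-widget
corruption operators designed to violate exactly one rule (out-of-range
numeral, over-length text, unknown choice key, month-13 date,
out-of-range minutes, non-digit pin). Consequently the open auto-query
count is exactly Binomial(F, error_rate) — the 4σ acceptance band tests
the capture/query path, not overlapping rule interactions. All
randomness flows through `random.Random` (Mersenne Twister — a fixed,
versioned algorithm), so identical seeds give byte-identical workbooks
and identical ledger digests across platforms.

Defaults (3 CRFs × 10 fields, 3 events, 10 participants, 3 sites, 20 %
skip, 10 % PHI, 20 % missing-allowed, 10 % error rate) are sized so a
full simulated study runs in well under a second; the statistical
checks use 70 participants (≈5 400 validated fields) and the ledger
property suite ~1 200 operations with 200 sampled mutations. Fixtures
are structural, not epidemiological: values have no clinical
distribution, sites have no differential behaviour, and entry is
error-independent across fields. Passing tests therefore establish the
mechanics (validation, provenance, query lifecycle, export safety), not
realism of content. The built-in table of seven production studies'
printed operational counts is an input used as a worked example for the
report arithmetic; the engine does not claim to reproduce those studies'
data at desk scale.

## Known limitations

No OR/nesting in skip conditions; no cross-form or cross-visit edit
checks (registry hook only); no visit-window logic, e-signature
ceremony, or notification transport; no CDISC ODM/PDF/R export; no
distributed replication of the ledger; the CLI trusts the supplied actor
identity (identity management is infrastructure, out of scope).
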