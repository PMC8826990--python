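# ecrfkit

A desk-scale clinical data management engine: metadata-driven electronic
data capture (EDC) for case report forms (eCRFs), with a cryptographically
verifiable audit ledger, automatic data-query generation, a versioned
document repository, and standards-based export.

It is written for clinical data managers, trial methodologists and
research-informatics engineers who want the core mechanics of a
regulated EDC system — the data model, the edit-check and skip-pattern
semantics, the audit-trail guarantees, the query lifecycle, the report
arithmetic — as an inspectable, scriptable Python library rather than a
hosted web application.

## The model

**Metadata-driven capture.** A study configuration (imported from a
spreadsheet workbook or built in code) defines the schedule of events and
every eCRF as versioned, revisioned metadata: field names, prompts
(multi-language), widgets, data types (text/numeric/date), numeric ranges
`min…max:step`, length limits `total,decimals`, choice codings, required
and missing-allowed flags, PHI flags, and conditional visibility rules
(skip patterns) of the form `FIELD op literal [AND …]`. Revisions apply
prospectively: the revision active at a record's creation time governs
that record forever.

**Validation.** Submitted payloads are validated against the governing
revision: visibility first, then type coercion, range/step membership
(step tested with relative tolerance 1e-9), length, choice membership,
date/time formats, required-ness on visible fields only. Problems are
findings, never exceptions; each unresolved error finding opens exactly
one auto query per (record, field, rule), and the query is system-closed
when a later edit makes the rule pass.

**The ledger.** Every data value is a *data object instance* (DOI):
a version-controlled payload whose versions are entries in an append-only
ledger. Entry *i* stores a SHA-256 digest of its canonical payload
(key-sorted compact JSON), the chain digest of entry *i−1* (64 hex zeros
at *i = 1*), a chain digest over

```
H_i = SHA-256(H_{i-1} | d_i | seq_i | t_i | doi_i | type_i | v_i | actor_i | rfc_i | state_i)
```

and an HMAC-SHA-256 authentication code over `H_i` keyed with a
per-study secret. Amendments require a reason for change (RFC); deletes
are logical; locks (participant ⊃ event ⊃ record) block writes in scope;
verification replays every digest and reports the earliest mismatch, so
any single-byte tamper — including to the recorded actor — is detected
at or before the altered entry. All study state (records, queries,
control marks, documents, notifications, workflow runs) rebuilds from
the ledger log alone.

**Reporting.** The study summary reproduces operational counts (users,
sites, participants screened, eCRFs, record-level transactions, queries,
document volumes) with the query rate computed as
`100 · queries / eCRFs`, rounded half-up to one decimal.

## Worked example

`examples/02_capture_and_queries.py` submits a demographics record with
an out-of-range age, then corrects it:

```
findings: [('AGE', 'RANGE')]
auto queries opened: [('AGE', 'RANGE')]
matrix cell: incomplete | progress (2, 3) | open queries 1
after correction: findings = [] | system-closed: [('AGE', 'closed')]
matrix cell now: complete
```

One RANGE finding opened one auto query; the event matrix showed the
form incomplete at 2 of 3 required visible fields answered (the
pregnancy field stays hidden by its skip pattern `SEX = 2`); after the
edit — recorded in the ledger with its reason for change — the system
actor closed the query and the form reads complete.

The summary-report arithmetic reproduces the published operational
counts of the seven production studies with complete figures: for
example 11 644 queries over 136 876 eCRFs prints as a rate of 8.5, and
the totals row sums to 4 596 participants screened, 337 816 eCRFs and
36 887 queries (`examples/04_export_and_summary.py`).

The other examples cover workbook authoring and annotated eCRF rendering
(`01`), and tamper-evidence of the ledger (`03`). A thin CLI wraps the
same operations (`ecrfkit simulate | enter | matrix | query |
verify-ledger | lock | sdv | docs | export | report`).

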