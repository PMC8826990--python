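"""Demonstrate the tamper-evident audit ledger.

Runs simulated data entry, verifies the hash chain, then flips one byte
of one stored entry and shows verification pinpointing the damage at (or
before) that entry.  A wrong study secret fails at the first entry, so a
ledger cannot be silently re-signed.
"""

import dataclasses

from ecrfkit import FixtureSpec, Study, generate_study_config, simulate_entry
from ecrfkit.ledger import verify_entries

spec = FixtureSpec(seed=3, n_participants=5)
study = Study(generate_study_config(spec), b"per-study-secret")
simulate_entry(study, spec)
print(f"ledger entries: {len(study.ledger.entries)}")
print("verify (untouched):", study.ledger.verify_chain(), "(None = chain intact)")

k = 120  # tamper with the payload of entry 121
entry = study.ledger.entries[k]
entries = list(study.ledger.entries)
entries[k] = dataclasses.replace(entry, payload={**entry.payload, "values": {"X": "!"}})
print(f"verify (payload of seq {k + 1} altered):",
      verify_entries(entries, study.ledger.secret))

print("verify (wrong secret):", study.ledger.verify_chain(b"not-the-secret"))
# The altered entry is reported by its sequence number; with the wrong
# HMAC key every authentication code fails, starting at seq 1.
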