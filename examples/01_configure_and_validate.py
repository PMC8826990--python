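"""Author a study configuration workbook, validate it, and render an
annotated eCRF.

Builds a small synthetic configuration (3 eCRFs x 10 fields with skip
patterns, PHI flags and edit checks), writes it as a directory of CSV
sheets, parses it back, runs the consistency checks, and prints the
annotated form a study team would circulate for review.
"""

import tempfile
from pathlib import Path

from ecrfkit import (
    FixtureSpec,
    generate_study_config,
    parse_config_workbook,
    render_annotated_crf,
    resolve_version,
    validate_config,
    write_workbook,
)
from datetime import datetime, timezone

config = generate_study_config(FixtureSpec(seed=42))
with tempfile.TemporaryDirectory() as d:
    write_workbook(config, d)
    print("workbook sheets:", sorted(p.name for p in Path(d).iterdir()))
    parsed = parse_config_workbook(d)

findings = validate_config(parsed)
print(f"configuration findings: {len(findings)} (empty list = deployable)")

crf = parsed.crf("CRF01")
version, revision = resolve_version(crf, datetime.now(timezone.utc))
doc = render_annotated_crf(parsed, crf, version, revision)
print("\n".join(doc.splitlines()[:24]))
print("...")
# The annotated form lists, per field, the prompt, widget, type, coding,
# range/length edit checks, skip condition and PHI/required flags —
# everything a reviewer needs to sign off the form design.
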