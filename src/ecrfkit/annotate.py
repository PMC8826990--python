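"""Annotated eCRF rendering.

Produces a printable Markdown representation of one eCRF revision with
every piece of configuration a reviewer needs: item names, prompts,
coding, edit checks, skip patterns, defaults and flags.  Used during
collaborative form design and review.
"""

from __future__ import annotations

from .errors import NotFoundError
from .model import CRFDefinition, CRFRevision, CRFVersion, StudyConfig


def render_annotated_crf(
    config: StudyConfig,
    crf: CRFDefinition,
    version: CRFVersion,
    revision: CRFRevision,
    language: str | None = None,
) -> str:
    lang = language or config.default_language
    if language is not None and language not in config.languages:
        raise NotFoundError(f"language {language!r} not configured for study")

    lines: list[str] = []
    lines.append(f"# Annotated eCRF: {crf.crf_name} — {crf.crf_label}")
    lines.append("")
    lines.append(
        f"Version: {version.v_version} | Revision: {revision.revision_no} | "
        f"Activated: {revision.activated_at.isoformat()}"
    )
    flags = []
    if crf.allow_multiple_entry:
        flags.append("multiple entry")
    if crf.is_cross_events:
        flags.append("cross-event")
    if crf.allow_change_version:
        flags.append("user version choice")
    if flags:
        lines.append(f"CRF flags: {', '.join(flags)}")
    if revision.form_subtitle:
        lines.append(f"Subtitle: {revision.form_subtitle.get(lang)}")
    if revision.form_instruction:
        lines.append(f"Instructions: {revision.form_instruction.get(lang)}")
    lines.append("")

    for fs in revision.fieldsets:
        lines.append(f"## {fs.title.get(lang)}")
        if fs.description:
            lines.append(fs.description.get(lang))
        lines.append("")
        for f in fs.fields:
            lines.append(f"### {f.field_name}")
            lines.append(f"- Prompt: {f.question.get(lang)}")
            lines.append(f"- Widget: {f.widget} | Type: {f.dtype} | Order: {f.order}")
            if f.units:
                lines.append(f"- Units: {f.units.get(lang)}")
            if f.notes:
                lines.append(f"- Notes: {f.notes.get(lang)}")
            if f.choices:
                coded = "; ".join(f"{c.key} = {c.label.get(lang)}" for c in f.choices)
                lines.append(f"- Coding: {coded}")
            if f.value_range is not None:
                lines.append(f"- Range: {f.value_range.as_text()}")
            if f.length is not None:
                lines.append(f"- Length: {f.length.as_text()}")
            marks = []
            marks.append("required" if f.required else "optional")
            if f.allow_missing:
                marks.append("missing allowed")
            if f.phi:
                marks.append("PHI")
            if f.double_entry:
                marks.append("double entry")
            lines.append(f"- Flags: {', '.join(marks)}")
            if f.subquestion:
                lines.append(f"- Skip condition: show when {f.subquestion}")
            if f.default_value is not None:
                lines.append(f"- Default: {f.default_value}")
            if f.indent:
                lines.append(f"- Indent: {f.indent}")
            lines.append("")

    if revision.attachments:
        lines.append("## File attachments")
        for att in revision.attachments:
            restrict = ", ".join(att.restrictions) if att.restrictions else "any"
            lines.append(f"- {att.name}: {att.label.get(lang)} (extensions: {restrict})")
        lines.append("")
    return "\n".join(lines).rstrip() + "\n"
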