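"""Study configuration workbook I/O.

A configuration is authored as a spreadsheet workbook — either a single
XLSX file or a directory of CSV sheets (RFC 4180, UTF-8, header row) —
with six sheets::

    study    STUDY_ID, STUDY_LABEL, SITES, LANGUAGES          (one row)
    events   EVENT_CODE, LABEL, ORDER, REQUIRED_CRFS          (one row per event)
    crfs     CRF_NAME, CRF_LABEL, ALLOW_MULTIPLE_ENTRY, IS_CROSS_EVENTS,
             ALLOW_CHANGE_VERSION, LOG_MENU_FIELD, V_VERSION, REVISION,
             ACTIVATED_AT, FORM_SUBTITLE, FORM_INSTRUCTION    (one row per revision)
    fields   CRF_NAME, V_VERSION, REVISION, FIELDSET_TITLE, FIELDSET_DESCRIPTION,
             FIELD_NAME, QUESTION, ORDER, UNITS, NOTES, WIDGET, TYPE, VALUE,
             REQUIRED, ALLOW_MISSING, LENGTH, PHI, INDENT, SUBQUESTION,
             DEFAULT_VALUE, DOUBLE_ENTRY                      (one row per field)
    choices  CRF_NAME, FIELD_NAME, KEY, LABEL                 (one row per choice)
    files    CRF_NAME, NAME, LABEL, RESTRICTIONS              (one row per attachment)

Booleans are encoded Y/N with blank meaning N.  Multi-valued cells
(SITES, LANGUAGES, REQUIRED_CRFS, LOG_MENU_FIELD, RESTRICTIONS) are
semicolon-separated.  An attribute with multi-language support gains one
extra column per translation, suffixed ``.<lang>`` (e.g. ``QUESTION.ja``);
the unsuffixed column holds the default language.
"""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from .errors import ConfigParseError
from .mls import MLSText
from .model import (
    CRFDefinition,
    CRFRevision,
    CRFVersion,
    Choice,
    FieldDefinition,
    Fieldset,
    FileAttachmentDefinition,
    LengthSpec,
    RangeSpec,
    StudyConfig,
    StudyEventDef,
    parse_length_spec,
    parse_range_spec,
)

SHEETS = ("study", "events", "crfs", "fields", "choices", "files")

_REQUIRED_COLUMNS = {
    "study": ["STUDY_ID", "STUDY_LABEL", "SITES", "LANGUAGES"],
    "events": ["EVENT_CODE", "LABEL", "ORDER", "REQUIRED_CRFS"],
    "crfs": [
        "CRF_NAME",
        "CRF_LABEL",
        "ALLOW_MULTIPLE_ENTRY",
        "IS_CROSS_EVENTS",
        "ALLOW_CHANGE_VERSION",
        "LOG_MENU_FIELD",
        "V_VERSION",
        "REVISION",
        "ACTIVATED_AT",
        "FORM_SUBTITLE",
        "FORM_INSTRUCTION",
    ],
    "fields": [
        "CRF_NAME",
        "V_VERSION",
        "REVISION",
        "FIELDSET_TITLE",
        "FIELDSET_DESCRIPTION",
        "FIELD_NAME",
        "QUESTION",
        "ORDER",
        "UNITS",
        "NOTES",
        "WIDGET",
        "TYPE",
        "VALUE",
        "REQUIRED",
        "ALLOW_MISSING",
        "LENGTH",
        "PHI",
        "INDENT",
        "SUBQUESTION",
        "DEFAULT_VALUE",
        "DOUBLE_ENTRY",
    ],
    "choices": ["CRF_NAME", "FIELD_NAME", "KEY", "LABEL"],
    "files": ["CRF_NAME", "NAME", "LABEL", "RESTRICTIONS"],
}

_MLS_COLUMNS = {
    "crfs": ("FORM_SUBTITLE", "FORM_INSTRUCTION"),
    "fields": ("FIELDSET_TITLE", "FIELDSET_DESCRIPTION", "QUESTION", "UNITS", "NOTES"),
    "choices": ("LABEL",),
    "files": ("LABEL",),
}


def _parse_bool(cell: str) -> bool:
    return cell.strip().upper() in {"Y", "YES", "TRUE", "1"}


def _split_list(cell: str) -> tuple[str, ...]:
    return tuple(p.strip() for p in cell.split(";") if p.strip())


def read_sheets(source: str | Path) -> dict[str, pd.DataFrame]:
    """Read the workbook sheets from an XLSX file or a CSV directory."""
    source = Path(source)
    sheets: dict[str, pd.DataFrame] = {}
    if source.is_dir():
        for name in SHEETS:
            path = source / f"{name}.csv"
            if not path.exists():
                raise ConfigParseError(f"missing sheet {name!r}", code="MISSING_SHEET")
            sheets[name] = pd.read_csv(path, dtype=str, keep_default_na=False)
    else:
        if not source.exists():
            raise ConfigParseError(f"workbook {source} not found", code="MISSING_SHEET")
        book = pd.read_excel(source, sheet_name=None, dtype=str, engine="openpyxl")
        for name in SHEETS:
            if name not in book:
                raise ConfigParseError(f"missing sheet {name!r}", code="MISSING_SHEET")
            sheets[name] = book[name].fillna("")
    for name, df in sheets.items():
        missing = [c for c in _REQUIRED_COLUMNS[name] if c not in df.columns]
        if missing:
            raise ConfigParseError(
                f"sheet {name!r}: missing column(s) {missing}", code="MISSING_COLUMN"
            )
    return sheets


def _mls(row: Mapping[str, str], attr: str, default_lang: str,
         columns: list[str]) -> Optional[MLSText]:
    base = str(row.get(attr, "") or "")
    texts = {default_lang: base}
    prefix = f"{attr}."
    for col in columns:
        if col.startswith(prefix):
            val = str(row.get(col, "") or "")
            if val:
                texts[col[len(prefix):]] = val
    if not base and len(texts) == 1:
        return None
    return MLSText(default_lang=default_lang, texts=texts)


def parse_config_workbook(source: str | Path) -> StudyConfig:
    """Parse and link a full study configuration from a workbook."""
    sheets = read_sheets(source)

    study_df = sheets["study"]
    if len(study_df) != 1:
        raise ConfigParseError(
            f"sheet 'study': expected exactly 1 row, found {len(study_df)}"
        )
    srow = study_df.iloc[0]
    languages = _split_list(str(srow["LANGUAGES"])) or ("en",)
    default_lang = languages[0]

    events = []
    for i, row in sheets["events"].iterrows():
        try:
            order = int(str(row["ORDER"]))
        except ValueError:
            raise ConfigParseError(f"sheet 'events' row {i + 2}: non-integer ORDER")
        events.append(
            StudyEventDef(
                event_code=str(row["EVENT_CODE"]),
                label=str(row["LABEL"]),
                order=order,
                required_crfs=_split_list(str(row["REQUIRED_CRFS"])),
            )
        )

    # choices keyed by (CRF_NAME, FIELD_NAME), shared across revisions
    choice_cols = list(sheets["choices"].columns)
    choices_by_key: dict[tuple[str, str], list[Choice]] = {}
    for i, row in sheets["choices"].iterrows():
        label = _mls(row, "LABEL", default_lang, choice_cols) or MLSText.of(
            str(row["KEY"]), default_lang
        )
        choices_by_key.setdefault(
            (str(row["CRF_NAME"]), str(row["FIELD_NAME"])), []
        ).append(Choice(key=str(row["KEY"]), label=label))

    file_cols = list(sheets["files"].columns)
    files_by_crf: dict[str, list[FileAttachmentDefinition]] = {}
    for i, row in sheets["files"].iterrows():
        label = _mls(row, "LABEL", default_lang, file_cols) or MLSText.of(
            str(row["NAME"]), default_lang
        )
        files_by_crf.setdefault(str(row["CRF_NAME"]), []).append(
            FileAttachmentDefinition(
                name=str(row["NAME"]),
                label=label,
                restrictions=_split_list(str(row["RESTRICTIONS"])),
            )
        )

    field_cols = list(sheets["fields"].columns)
    fields_by_rev: dict[tuple[str, str, int], list[tuple[int, pd.Series]]] = {}
    for i, row in sheets["fields"].iterrows():
        try:
            rev_no = int(str(row["REVISION"]))
        except ValueError:
            raise ConfigParseError(f"sheet 'fields' row {i + 2}: non-integer REVISION")
        key = (str(row["CRF_NAME"]), str(row["V_VERSION"]), rev_no)
        fields_by_rev.setdefault(key, []).append((i, row))

    crf_cols = list(sheets["crfs"].columns)
    crf_order: list[str] = []
    crf_rows: dict[str, list[tuple[int, pd.Series]]] = {}
    for i, row in sheets["crfs"].iterrows():
        name = str(row["CRF_NAME"])
        if name not in crf_rows:
            crf_order.append(name)
            crf_rows[name] = []
        crf_rows[name].append((i, row))

    crfs = []
    for name in crf_order:
        rows = crf_rows[name]
        first = rows[0][1]
        version_order: list[str] = []
        revisions_by_version: dict[str, list[CRFRevision]] = {}
        for i, row in rows:
            v_name = str(row["V_VERSION"])
            if v_name not in revisions_by_version:
                version_order.append(v_name)
                revisions_by_version[v_name] = []
            try:
                rev_no = int(str(row["REVISION"]))
            except ValueError:
                raise ConfigParseError(f"sheet 'crfs' row {i + 2}: non-integer REVISION")
            activated_raw = str(row["ACTIVATED_AT"]).strip()
            try:
                activated = datetime.fromisoformat(activated_raw.replace("Z", "+00:00"))
            except ValueError:
                raise ConfigParseError(
                    f"sheet 'crfs' row {i + 2}: bad ACTIVATED_AT {activated_raw!r}"
                )
            if activated.tzinfo is None:
                activated = activated.replace(tzinfo=timezone.utc)
            fieldsets = _build_fieldsets(
                fields_by_rev.get((name, v_name, rev_no), []),
                default_lang,
                field_cols,
                choices_by_key,
                name,
            )
            revisions_by_version[v_name].append(
                CRFRevision(
                    revision_no=rev_no,
                    fieldsets=fieldsets,
                    activated_at=activated,
                    form_subtitle=_mls(row, "FORM_SUBTITLE", default_lang, crf_cols),
                    form_instruction=_mls(row, "FORM_INSTRUCTION", default_lang, crf_cols),
                    attachments=tuple(files_by_crf.get(name, [])),
                )
            )
        versions = tuple(
            CRFVersion(v_version=v, revisions=tuple(revisions_by_version[v]))
            for v in version_order
        )
        crfs.append(
            CRFDefinition(
                crf_name=name,
                crf_label=str(first["CRF_LABEL"]),
                versions=versions,
                allow_multiple_entry=_parse_bool(str(first["ALLOW_MULTIPLE_ENTRY"])),
                is_cross_events=_parse_bool(str(first["IS_CROSS_EVENTS"])),
                allow_change_version=_parse_bool(str(first["ALLOW_CHANGE_VERSION"])),
                log_menu_fields=_split_list(str(first["LOG_MENU_FIELD"])),
            )
        )

    return StudyConfig(
        study_id=str(srow["STUDY_ID"]),
        study_label=str(srow["STUDY_LABEL"]),
        events=tuple(events),
        crfs=tuple(crfs),
        sites=_split_list(str(srow["SITES"])),
        languages=languages,
    )


def _build_fieldsets(rows, default_lang, field_cols, choices_by_key, crf_name):
    fieldsets: list[Fieldset] = []
    current_title: Optional[MLSText] = None
    current_desc: Optional[MLSText] = None
    current_fields: list[FieldDefinition] = []

    def flush():
        nonlocal current_fields
        if current_fields:
            fieldsets.append(
                Fieldset(
                    title=current_title or MLSText.of("Fields", default_lang),
                    description=current_desc,
                    fields=tuple(current_fields),
                )
            )
            current_fields = []

    for i, row in rows:
        title = _mls(row, "FIELDSET_TITLE", default_lang, field_cols)
        if title is not None and (
            current_title is None or title.texts != current_title.texts
        ):
            flush()
            current_title = title
            current_desc = _mls(row, "FIELDSET_DESCRIPTION", default_lang, field_cols)
        loc = f"sheet 'fields' row {i + 2}"
        dtype = str(row["TYPE"]).strip()
        widget = str(row["WIDGET"]).strip()
        value_range: Optional[RangeSpec] = None
        if str(row["VALUE"]).strip():
            try:
                value_range = parse_range_spec(str(row["VALUE"]))
            except ConfigParseError as exc:
                raise ConfigParseError(f"{loc}: {exc}")
        length: Optional[LengthSpec] = None
        if str(row["LENGTH"]).strip():
            try:
                length = parse_length_spec(str(row["LENGTH"]), dtype)
            except ConfigParseError as exc:
                raise ConfigParseError(f"{loc}: {exc}")
        try:
            order = int(str(row["ORDER"]))
            indent = int(str(row["INDENT"])) if str(row["INDENT"]).strip() else 0
        except ValueError:
            raise ConfigParseError(f"{loc}: non-integer ORDER/INDENT")
        question = _mls(row, "QUESTION", default_lang, field_cols) or MLSText.of(
            str(row["FIELD_NAME"]), default_lang
        )
        try:
            current_fields.append(
                FieldDefinition(
                    field_name=str(row["FIELD_NAME"]),
                    question=question,
                    order=order,
                    widget=widget,
                    dtype=dtype,
                    units=_mls(row, "UNITS", default_lang, field_cols),
                    notes=_mls(row, "NOTES", default_lang, field_cols),
                    value_range=value_range,
                    required=_parse_bool(str(row["REQUIRED"])),
                    allow_missing=_parse_bool(str(row["ALLOW_MISSING"])),
                    length=length,
                    phi=_parse_bool(str(row["PHI"])),
                    indent=indent,
                    subquestion=str(row["SUBQUESTION"]).strip() or None,
                    default_value=str(row["DEFAULT_VALUE"]).strip() or None,
                    double_entry=_parse_bool(str(row["DOUBLE_ENTRY"])),
                    choices=tuple(
                        choices_by_key.get((crf_name, str(row["FIELD_NAME"])), [])
                    ),
                )
            )
        except ConfigParseError as exc:
            raise ConfigParseError(f"{loc}: {exc}")
    flush()
    return tuple(fieldsets)


# ---------------------------------------------------------------------------
# writing


def _bool_cell(value: bool) -> str:
    return "Y" if value else ""


def _mls_cells(mls: Optional[MLSText], attr: str, default_lang: str,
               extra_langs: tuple[str, ...]) -> dict[str, str]:
    cells = {attr: ""}
    for lang in extra_langs:
        cells[f"{attr}.{lang}"] = ""
    if mls is not None:
        cells[attr] = mls.get(default_lang)
        for lang in extra_langs:
            if lang in mls.texts:
                cells[f"{attr}.{lang}"] = mls.texts[lang]
    return cells


def config_to_frames(config: StudyConfig) -> dict[str, pd.DataFrame]:
    default_lang = config.default_language
    extra = tuple(config.languages[1:])

    study = pd.DataFrame(
        [
            {
                "STUDY_ID": config.study_id,
                "STUDY_LABEL": config.study_label,
                "SITES": ";".join(config.sites),
                "LANGUAGES": ";".join(config.languages),
            }
        ]
    )
    events = pd.DataFrame(
        [
            {
                "EVENT_CODE": e.event_code,
                "LABEL": e.label,
                "ORDER": str(e.order),
                "REQUIRED_CRFS": ";".join(e.required_crfs),
            }
            for e in config.events
        ],
        columns=_REQUIRED_COLUMNS["events"],
    )

    crf_rows, field_rows, choice_rows, file_rows = [], [], [], []
    for crf in config.crfs:
        first_rev = crf.versions[0].revisions[0] if crf.versions else None
        if first_rev is not None:
            for att in first_rev.attachments:
                row = {"CRF_NAME": crf.crf_name, "NAME": att.name}
                row.update(_mls_cells(att.label, "LABEL", default_lang, extra))
                row["RESTRICTIONS"] = ";".join(att.restrictions)
                file_rows.append(row)
        seen_choice_fields: set[str] = set()
        for version in crf.versions:
            for revision in version.revisions:
                row = {
                    "CRF_NAME": crf.crf_name,
                    "CRF_LABEL": crf.crf_label,
                    "ALLOW_MULTIPLE_ENTRY": _bool_cell(crf.allow_multiple_entry),
                    "IS_CROSS_EVENTS": _bool_cell(crf.is_cross_events),
                    "ALLOW_CHANGE_VERSION": _bool_cell(crf.allow_change_version),
                    "LOG_MENU_FIELD": ";".join(crf.log_menu_fields),
                    "V_VERSION": version.v_version,
                    "REVISION": str(revision.revision_no),
                    "ACTIVATED_AT": revision.activated_at.isoformat(),
                }
                row.update(
                    _mls_cells(revision.form_subtitle, "FORM_SUBTITLE", default_lang, extra)
                )
                row.update(
                    _mls_cells(
                        revision.form_instruction, "FORM_INSTRUCTION", default_lang, extra
                    )
                )
                crf_rows.append(row)
                for fs in revision.fieldsets:
                    for idx, f in enumerate(fs.fields):
                        frow = {
                            "CRF_NAME": crf.crf_name,
                            "V_VERSION": version.v_version,
                            "REVISION": str(revision.revision_no),
                        }
                        frow.update(
                            _mls_cells(
                                fs.title if idx == 0 else None,
                                "FIELDSET_TITLE",
                                default_lang,
                                extra,
                            )
                        )
                        frow.update(
                            _mls_cells(
                                fs.description if idx == 0 else None,
                                "FIELDSET_DESCRIPTION",
                                default_lang,
                                extra,
                            )
                        )
                        frow["FIELD_NAME"] = f.field_name
                        frow.update(_mls_cells(f.question, "QUESTION", default_lang, extra))
                        frow["ORDER"] = str(f.order)
                        frow.update(_mls_cells(f.units, "UNITS", default_lang, extra))
                        frow.update(_mls_cells(f.notes, "NOTES", default_lang, extra))
                        frow["WIDGET"] = f.widget
                        frow["TYPE"] = f.dtype
                        frow["VALUE"] = f.value_range.as_text() if f.value_range else ""
                        frow["REQUIRED"] = _bool_cell(f.required)
                        frow["ALLOW_MISSING"] = _bool_cell(f.allow_missing)
                        frow["LENGTH"] = f.length.as_text() if f.length else ""
                        frow["PHI"] = _bool_cell(f.phi)
                        frow["INDENT"] = str(f.indent) if f.indent else ""
                        frow["SUBQUESTION"] = f.subquestion or ""
                        frow["DEFAULT_VALUE"] = f.default_value or ""
                        frow["DOUBLE_ENTRY"] = _bool_cell(f.double_entry)
                        field_rows.append(frow)
                        if f.choices and f.field_name not in seen_choice_fields:
                            seen_choice_fields.add(f.field_name)
                            for choice in f.choices:
                                crow = {
                                    "CRF_NAME": crf.crf_name,
                                    "FIELD_NAME": f.field_name,
                                    "KEY": choice.key,
                                }
                                crow.update(
                                    _mls_cells(choice.label, "LABEL", default_lang, extra)
                                )
                                choice_rows.append(crow)

    def frame(rows: list[dict], sheet: str) -> pd.DataFrame:
        cols = list(_REQUIRED_COLUMNS[sheet])
        for attr in _MLS_COLUMNS.get(sheet, ()):
            at = cols.index(attr)
            for j, lang in enumerate(extra, start=1):
                cols.insert(at + j, f"{attr}.{lang}")
        return pd.DataFrame(rows, columns=cols).fillna("")

    return {
        "study": study,
        "events": events,
        "crfs": frame(crf_rows, "crfs"),
        "fields": frame(field_rows, "fields"),
        "choices": frame(choice_rows, "choices"),
        "files": frame(file_rows, "files"),
    }


def write_workbook(config: StudyConfig, dest: str | Path) -> Path:
    """Write a configuration as an XLSX file (``.xlsx`` suffix) or CSV dir."""
    dest = Path(dest)
    frames = config_to_frames(config)
    if dest.suffix.lower() == ".xlsx":
        with pd.ExcelWriter(dest, engine="openpyxl") as writer:
            for name in SHEETS:
                frames[name].to_excel(writer, sheet_name=name, index=False)
    else:
        dest.mkdir(parents=True, exist_ok=True)
        for name in SHEETS:
            frames[name].to_csv(dest / f"{name}.csv", index=False, lineterminator="\n")
    return dest


# ---------------------------------------------------------------------------
# canonical JSON serialization


def config_to_dict(config: StudyConfig) -> dict:
    def mls(x: Optional[MLSText]):
        return x.to_dict() if x is not None else None

    return {
        "study_id": config.study_id,
        "study_label": config.study_label,
        "languages": list(config.languages),
        "sites": list(config.sites),
        "events": [
            {
                "event_code": e.event_code,
                "label": e.label,
                "order": e.order,
                "required_crfs": list(e.required_crfs),
            }
            for e in config.events
        ],
        "crfs": [
            {
                "crf_name": c.crf_name,
                "crf_label": c.crf_label,
                "allow_multiple_entry": c.allow_multiple_entry,
                "is_cross_events": c.is_cross_events,
                "allow_change_version": c.allow_change_version,
                "log_menu_fields": list(c.log_menu_fields),
                "versions": [
                    {
                        "v_version": v.v_version,
                        "revisions": [
                            {
                                "revision_no": r.revision_no,
                                "activated_at": r.activated_at.isoformat(),
                                "form_subtitle": mls(r.form_subtitle),
                                "form_instruction": mls(r.form_instruction),
                                "attachments": [
                                    {
                                        "name": a.name,
                                        "label": mls(a.label),
                                        "restrictions": list(a.restrictions),
                                    }
                                    for a in r.attachments
                                ],
                                "fieldsets": [
                                    {
                                        "title": mls(fs.title),
                                        "description": mls(fs.description),
                                        "fields": [
                                            {
                                                "field_name": f.field_name,
                                                "question": mls(f.question),
                                                "order": f.order,
                                                "widget": f.widget,
                                                "dtype": f.dtype,
                                                "units": mls(f.units),
                                                "notes": mls(f.notes),
                                                "value_range": (
                                                    {
                                                        "min": f.value_range.min,
                                                        "max": f.value_range.max,
                                                        "step": f.value_range.step,
                                                    }
                                                    if f.value_range
                                                    else None
                                                ),
                                                "required": f.required,
                                                "allow_missing": f.allow_missing,
                                                "length": (
                                                    {
                                                        "total": f.length.total,
                                                        "decimals": f.length.decimals,
                                                    }
                                                    if f.length
                                                    else None
                                                ),
                                                "phi": f.phi,
                                                "indent": f.indent,
                                                "subquestion": f.subquestion,
                                                "default_value": f.default_value,
                                                "double_entry": f.double_entry,
                                                "choices": [
                                                    {"key": ch.key, "label": mls(ch.label)}
                                                    for ch in f.choices
                                                ],
                                            }
                                            for f in fs.fields
                                        ],
                                    }
                                    for fs in r.fieldsets
                                ],
                            }
                            for r in v.revisions
                        ],
                    }
                    for v in c.versions
                ],
            }
            for c in config.crfs
        ],
    }


def config_from_dict(d: dict) -> StudyConfig:
    def mls(x) -> Optional[MLSText]:
        return MLSText.from_dict(x) if x else None

    crfs = []
    for c in d["crfs"]:
        versions = []
        for v in c["versions"]:
            revisions = []
            for r in v["revisions"]:
                fieldsets = []
                for fs in r["fieldsets"]:
                    fields = []
                    for f in fs["fields"]:
                        fields.append(
                            FieldDefinition(
                                field_name=f["field_name"],
                                question=mls(f["question"]),
                                order=f["order"],
                                widget=f["widget"],
                                dtype=f["dtype"],
                                units=mls(f["units"]),
                                notes=mls(f["notes"]),
                                value_range=(
                                    RangeSpec(**f["value_range"])
                                    if f["value_range"]
                                    else None
                                ),
                                required=f["required"],
                                allow_missing=f["allow_missing"],
                                length=LengthSpec(**f["length"]) if f["length"] else None,
                                phi=f["phi"],
                                indent=f["indent"],
                                subquestion=f["subquestion"],
                                default_value=f["default_value"],
                                double_entry=f["double_entry"],
                                choices=tuple(
                                    Choice(key=ch["key"], label=mls(ch["label"]))
                                    for ch in f["choices"]
                                ),
                            )
                        )
                    fieldsets.append(
                        Fieldset(
                            title=mls(fs["title"]),
                            description=mls(fs["description"]),
                            fields=tuple(fields),
                        )
                    )
                revisions.append(
                    CRFRevision(
                        revision_no=r["revision_no"],
                        activated_at=datetime.fromisoformat(r["activated_at"]),
                        form_subtitle=mls(r["form_subtitle"]),
                        form_instruction=mls(r["form_instruction"]),
                        attachments=tuple(
                            FileAttachmentDefinition(
                                name=a["name"],
                                label=mls(a["label"]),
                                restrictions=tuple(a["restrictions"]),
                            )
                            for a in r["attachments"]
                        ),
                        fieldsets=tuple(fieldsets),
                    )
                )
            versions.append(CRFVersion(v_version=v["v_version"], revisions=tuple(revisions)))
        crfs.append(
            CRFDefinition(
                crf_name=c["crf_name"],
                crf_label=c["crf_label"],
                versions=tuple(versions),
                allow_multiple_entry=c["allow_multiple_entry"],
                is_cross_events=c["is_cross_events"],
                allow_change_version=c["allow_change_version"],
                log_menu_fields=tuple(c["log_menu_fields"]),
            )
        )
    return StudyConfig(
        study_id=d["study_id"],
        study_label=d["study_label"],
        events=tuple(
            StudyEventDef(
                event_code=e["event_code"],
                label=e["label"],
                order=e["order"],
                required_crfs=tuple(e["required_crfs"]),
            )
            for e in d["events"]
        ),
        crfs=tuple(crfs),
        sites=tuple(d["sites"]),
        languages=tuple(d["languages"]),
    )


def config_to_json(config: StudyConfig) -> str:
    """Canonical JSON form: key-sorted, compact, UTF-8-safe."""
    return json.dumps(
        config_to_dict(config), sort_keys=True, separators=(",", ":"), ensure_ascii=False
    )
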