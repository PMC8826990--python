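"""Error hierarchy.

Every operational error carries a short machine-readable ``code`` (e.g.
``LOCKED``, ``RFC_REQUIRED``) so callers and the CLI can branch on it
without string-matching messages.
"""

from __future__ import annotations


class EdcError(Exception):
    """Base class for all operational errors raised by the package."""

    code: str = "EDC_ERROR"

    def __init__(self, message: str, *, code: str | None = None):
        super().__init__(message)
        if code is not None:
            self.code = code

    def __str__(self) -> str:  # pragma: no cover - trivial
        return f"{self.code}: {super().__str__()}"


class ConfigParseError(EdcError):
    """Malformed study configuration input (workbook, range/length spec)."""

    code = "CONFIG_PARSE"


class NotFoundError(EdcError):
    code = "NOT_FOUND"


class DuplicateError(EdcError):
    code = "DUPLICATE"


class LockedError(EdcError):
    code = "LOCKED"


class RfcRequiredError(EdcError):
    """A reason for change is mandatory for amendments, deletes and unlocks."""

    code = "RFC_REQUIRED"


class IllegalTransitionError(EdcError):
    code = "ILLEGAL_TRANSITION"
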