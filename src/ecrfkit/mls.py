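"""Multi-language text support (MLS).

Prompts, labels and instructions in an eCRF configuration may carry
translations.  An :class:`MLSText` maps language codes to strings; a
request for an absent language falls back to the default language, which
is always present.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping


@dataclass(frozen=True)
class MLSText:
    default_lang: str
    texts: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.default_lang not in self.texts:
            raise ValueError(
                f"default language {self.default_lang!r} missing from texts"
            )
        object.__setattr__(self, "texts", dict(self.texts))

    @classmethod
    def of(cls, text: str, lang: str = "en", **translations: str) -> "MLSText":
        return cls(default_lang=lang, texts={lang: text, **translations})

    def get(self, lang: str | None = None) -> str:
        """Text in ``lang``, falling back to the default language."""
        if lang is None:
            return self.texts[self.default_lang]
        return self.texts.get(lang, self.texts[self.default_lang])

    @property
    def languages(self) -> list[str]:
        return sorted(self.texts)

    def to_dict(self) -> dict:
        return {"default": self.default_lang, "texts": dict(sorted(self.texts.items()))}

    @classmethod
    def from_dict(cls, d: dict) -> "MLSText":
        return cls(default_lang=d["default"], texts=d["texts"])
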