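"""Keyword dictionaries and qualifier trigger lexicons.

The detection pipeline is driven entirely by editable CSV lexicons:

* a keyword file with columns ``pattern,modality`` where ``pattern`` is a
  regular-expression fragment matched case- and accent-insensitively with
  word boundaries (spaces in the pattern match any whitespace run);
* a trigger file with columns ``qualifier,trigger,direction,window`` listing,
  for each of the five qualifiers (negation, family, history, hypothesis,
  reported speech), the phrases that mark a mention as qualified when found
  within ``window`` tokens on the stated side (``pre``, ``post`` or ``both``)
  of the mention, with no intervening sentence boundary or adversative
  conjunction.

Two parallel banks ship with the package: an English-like one (default) and
a minimal French one mirroring the same span/qualifier geometry.  Both are
placeholders with documented provenance, not a clinically validated
terminology.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from ._text import fold
from .types import QUALIFIERS, RISK_FACTORS

#: closed set of suicide-attempt modality labels
MODALITIES = (
    "jump-from-height",
    "intentional-drug-overdose",
    "phlebotomy",
    "hanging",
    "firearm",
    "drowning",
    "other",
)

#: adversative conjunctions terminating a qualifier scope (folded forms)
ADVERSATIVES = frozenset({"but", "however", "although", "mais", "cependant", "toutefois"})


def _compile(pattern: str) -> re.Pattern[str]:
    folded = fold(pattern)
    flexible = re.sub(r" +", r"\\s+", folded)
    return re.compile(rf"(?<!\w)(?:{flexible})(?!\w)")


@dataclass(frozen=True)
class KeywordEntry:
    pattern: str
    modality: str
    regex: re.Pattern[str]


@dataclass(frozen=True)
class Trigger:
    qualifier: str
    phrase: str
    direction: str  # "pre" | "post" | "both"
    window: int
    tokens: tuple[str, ...]


@dataclass
class KeywordDictionary:
    """Keyword entries plus per-qualifier trigger lexicons."""

    keywords: list[KeywordEntry]
    triggers: dict[str, list[Trigger]] = field(default_factory=dict)
    name: str = "custom"

    def __post_init__(self) -> None:
        if not self.keywords:
            raise ValueError("keyword dictionary must not be empty")
        for entry in self.keywords:
            if not entry.pattern.strip():
                raise ValueError("empty keyword surface form")
        for qualifier in self.triggers:
            if qualifier not in QUALIFIERS:
                raise ValueError(f"unknown qualifier {qualifier!r}")

    @classmethod
    def from_rows(cls,
                  keyword_rows: list[tuple[str, str]],
                  trigger_rows: list[tuple[str, str, str, int]] | None = None,
                  name: str = "custom") -> "KeywordDictionary":
        keywords = [
            KeywordEntry(pattern=p, modality=m, regex=_compile(p))
            for p, m in keyword_rows
        ]
        triggers: dict[str, list[Trigger]] = {q: [] for q in QUALIFIERS}
        for qualifier, phrase, direction, window in trigger_rows or []:
            if direction not in ("pre", "post", "both"):
                raise ValueError(f"bad trigger direction {direction!r}")
            triggers.setdefault(qualifier, []).append(
                Trigger(
                    qualifier=qualifier,
                    phrase=phrase,
                    direction=direction,
                    window=int(window),
                    tokens=tuple(re.findall(r"\w+", fold(phrase))),
                )
            )
        return cls(keywords=keywords, triggers=triggers, name=name)

    @classmethod
    def from_csv(cls,
                 keyword_csv: str | Path,
                 trigger_csv: str | Path | None = None,
                 name: str | None = None) -> "KeywordDictionary":
        keyword_rows = _read_keyword_csv(keyword_csv)
        trigger_rows = _read_trigger_csv(trigger_csv) if trigger_csv else []
        return cls.from_rows(keyword_rows, trigger_rows,
                             name=name or Path(keyword_csv).stem)


def _read_keyword_csv(path: str | Path) -> list[tuple[str, str]]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        return [(row["pattern"], row["modality"]) for row in reader]


def _read_trigger_csv(path: str | Path) -> list[tuple[str, str, str, int]]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        return [
            (row["qualifier"], row["trigger"], row["direction"], int(row["window"]))
            for row in reader
        ]


def _data_path(filename: str) -> Path:
    return Path(str(resources.files("sasurv").joinpath("data", filename)))


def load_builtin(lang: str = "en") -> KeywordDictionary:
    """Load the shipped suicide-attempt dictionary for *lang* ('en' or 'fr')."""
    if lang not in ("en", "fr"):
        raise ValueError(f"no builtin lexicon for language {lang!r}")
    return KeywordDictionary.from_csv(
        _data_path(f"sa_keywords_{lang}.csv"),
        _data_path(f"qualifier_triggers_{lang}.csv"),
        name=f"sa-{lang}",
    )


def load_risk_factor_lexicons(lang: str = "en") -> dict[str, KeywordDictionary]:
    """Per-factor dictionaries sharing the language's qualifier triggers."""
    if lang not in ("en", "fr"):
        raise ValueError(f"no builtin lexicon for language {lang!r}")
    trigger_rows = _read_trigger_csv(_data_path(f"qualifier_triggers_{lang}.csv"))
    lexicons: dict[str, KeywordDictionary] = {}
    for factor in RISK_FACTORS:
        keyword_rows = _read_keyword_csv(_data_path(f"rf_{factor}_{lang}.csv"))
        lexicons[factor] = KeywordDictionary.from_rows(
            keyword_rows, trigger_rows, name=f"{factor}-{lang}"
        )
    return lexicons
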