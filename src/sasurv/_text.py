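"""Low-level text utilities: accent folding and tokenisation.

Clinical French (and clinical English) text is matched after case and accent
folding.  Folding is strictly one character to one character so that every
offset in the folded string is also an offset in the original string; spans
reported by the matcher can therefore be sliced directly out of the original
text.  Multi-character decompositions (``œ`` → ``oe``) are deliberately left
unfolded to preserve that property.
"""

from __future__ import annotations

import re
import unicodedata
from functools import lru_cache

_WORD_RE = re.compile(r"\w+", re.UNICODE)

#: characters that end a qualifier scope when they occur between two tokens
SENTENCE_BREAK_CHARS = frozenset(".!?;\n")


@lru_cache(maxsize=4096)
def _fold_char(ch: str) -> str:
    decomposed = unicodedata.normalize("NFKD", ch)
    base = "".join(c for c in decomposed if not unicodedata.combining(c))
    return base.lower() if len(base) == 1 else ch.lower()


def fold(text: str) -> str:
    """Case- and accent-fold *text*, preserving its length."""
    folded = "".join(_fold_char(ch) for ch in text)
    assert len(folded) == len(text)
    return folded


def tokenize(text: str) -> list[tuple[int, int, str]]:
    """Split on word characters; returns ``(start, end, folded_token)``."""
    folded = fold(text)
    return [(m.start(), m.end(), m.group()) for m in _WORD_RE.finditer(folded)]


def has_sentence_break(text: str, start: int, end: int) -> bool:
    """True if any sentence-terminating character occurs in text[start:end]."""
    return any(ch in SENTENCE_BREAK_CHARS for ch in text[start:end])
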