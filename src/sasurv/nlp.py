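"""Two-stage rule-based detection of suicide-attempt hospitalisations.

Stage 1 (*screening*) flags every stay whose notes — of any type — contain at
least one dictionary keyword.  Stage 2 (*classification*) runs only on the
last-edited discharge summary of each screened stay: keyword matches become
mention annotations, each mention is qualified (negation, family, patient
history, hypothesis, reported speech) by trigger scoping, and the stay is
classified as suicide-attempt-caused iff at least one mention survives with
no qualifier — or, when a pluggable mention classifier is supplied, iff that
classifier validates at least one mention.

Matching is case- and accent-insensitive with word boundaries; spans always
refer to the original text.  Qualifier scoping looks for trigger phrases
within a fixed token window on the trigger's declared side of the mention and
is blocked by sentence boundaries and adversative conjunctions.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from typing import Callable, Iterable, Sequence

from ._text import fold, has_sentence_break, tokenize
from .lexicon import ADVERSATIVES, KeywordDictionary
from .types import MentionAnnotation, NoteRecord, QUALIFIERS, StayClassification

logger = logging.getLogger(__name__)

#: signature of a pluggable mention classifier: (note text, mention) -> valid?
MentionClassifier = Callable[[str, MentionAnnotation], bool]

RULE_CLASSIFIER_ID = "rule-based"


def select_discharge_summary(notes: Sequence[NoteRecord]) -> NoteRecord | None:
    """Last-edited discharge summary of one stay; ties broken by note_id."""
    summaries = [n for n in notes if n.note_type == "discharge_summary"]
    if not summaries:
        return None
    return max(summaries, key=lambda n: (n.edited_dt, n.note_id))


def screen_stays(notes: Iterable[NoteRecord],
                 dictionary: KeywordDictionary) -> set[str]:
    """Stay ids whose notes (any type) contain at least one keyword."""
    screened: set[str] = set()
    for note in notes:
        if note.stay_id in screened or not note.text:
            continue
        folded = fold(note.text)
        if any(entry.regex.search(folded) for entry in dictionary.keywords):
            screened.add(note.stay_id)
    return screened


def extract_mentions(text: str,
                     dictionary: KeywordDictionary) -> list[MentionAnnotation]:
    """Non-overlapping keyword matches, longest-match-wins on overlap."""
    if not text:
        return []
    folded = fold(text)
    candidates: list[tuple[int, int, str]] = []
    for entry in dictionary.keywords:
        for m in entry.regex.finditer(folded):
            candidates.append((m.start(), m.end(), entry.modality))
    # longest first; ties by position then modality for determinism
    candidates.sort(key=lambda c: (-(c[1] - c[0]), c[0], c[2]))
    kept: list[tuple[int, int, str]] = []
    for start, end, modality in candidates:
        if all(end <= ks or start >= ke for ks, ke, _ in kept):
            kept.append((start, end, modality))
    kept.sort()
    return [
        MentionAnnotation(start=s, end=e, surface=text[s:e], modality=mod)
        for s, e, mod in kept
    ]


def _scoped_tokens(tokens: list[tuple[int, int, str]],
                   text: str,
                   span: tuple[int, int],
                   direction: str,
                   window: int) -> list[str]:
    """Tokens within *window* of the span on one side, in text order,
    truncated at the first sentence break or adversative conjunction."""
    starts = [t[0] for t in tokens]
    if direction == "pre":
        hi = bisect_left(starts, span[0])
        picked: list[str] = []
        boundary = span[0]
        for i in range(hi - 1, max(hi - 1 - window, -1), -1):
            s, e, tok = tokens[i]
            if has_sentence_break(text, e, boundary) or tok in ADVERSATIVES:
                break
            picked.append(tok)
            boundary = s
        picked.reverse()
        return picked
    lo = bisect_right(starts, span[1] - 1)
    while lo < len(tokens) and tokens[lo][0] < span[1]:
        lo += 1
    picked = []
    boundary = span[1]
    for i in range(lo, min(lo + window, len(tokens))):
        s, e, tok = tokens[i]
        if has_sentence_break(text, boundary, s) or tok in ADVERSATIVES:
            break
        picked.append(tok)
        boundary = e
    return picked


def _contains_phrase(window_tokens: list[str], phrase: tuple[str, ...]) -> bool:
    k = len(phrase)
    if k == 0 or k > len(window_tokens):
        return False
    return any(
        tuple(window_tokens[i:i + k]) == phrase
        for i in range(len(window_tokens) - k + 1)
    )


def qualify_mention(text: str,
                    mention: MentionAnnotation,
                    dictionary: KeywordDictionary) -> MentionAnnotation:
    """Set the five qualifier flags of *mention* in place and return it."""
    if not (0 <= mention.start < mention.end <= len(text)):
        raise ValueError("mention span outside text")
    tokens = tokenize(text)
    span = (mention.start, mention.end)
    cache: dict[tuple[str, int], list[str]] = {}

    def window(direction: str, size: int) -> list[str]:
        key = (direction, size)
        if key not in cache:
            cache[key] = _scoped_tokens(tokens, text, span, direction, size)
        return cache[key]

    for qualifier in QUALIFIERS:
        hit = False
        for trig in dictionary.triggers.get(qualifier, []):
            directions = ("pre", "post") if trig.direction == "both" else (trig.direction,)
            for direction in directions:
                if _contains_phrase(window(direction, trig.window), trig.tokens):
                    hit = True
                    break
            if hit:
                break
        setattr(mention, qualifier, hit)
    return mention


def annotate_summary(text: str,
                     dictionary: KeywordDictionary) -> list[MentionAnnotation]:
    """Extract and qualify every mention of one discharge summary."""
    return [qualify_mention(text, m, dictionary) for m in extract_mentions(text, dictionary)]


def classify_stay(stay_id: str,
                  notes: Sequence[NoteRecord],
                  dictionary: KeywordDictionary,
                  classifier: MentionClassifier | None = None,
                  screened: bool | None = None) -> StayClassification:
    """Classify one stay from its last-edited discharge summary.

    With ``classifier=None`` the built-in rule policy applies: a mention is
    valid iff none of the five qualifiers fired.  A user-supplied callable
    replaces that verdict mention by mention (the hybrid-architecture hook).
    """
    if screened is None:
        screened = bool(screen_stays(notes, dictionary))
    summary = select_discharge_summary(notes)
    if summary is None:
        if screened:
            logger.info("stay %s screened but unclassifiable: no discharge summary", stay_id)
        return StayClassification(
            stay_id=stay_id, screened=screened, sa_caused=False,
            classifier_id=RULE_CLASSIFIER_ID if classifier is None else "custom",
            unclassifiable=True,
        )
    mentions = annotate_summary(summary.text, dictionary)
    for m in mentions:
        m.note_id = summary.note_id
    if classifier is None:
        sa_caused = any(m.valid for m in mentions)
        classifier_id = RULE_CLASSIFIER_ID
    else:
        sa_caused = any(classifier(summary.text, m) for m in mentions)
        classifier_id = getattr(classifier, "classifier_id", "custom")
    return StayClassification(
        stay_id=stay_id,
        screened=screened or bool(mentions),
        sa_caused=sa_caused,
        mentions=mentions,
        classifier_id=classifier_id,
    )
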