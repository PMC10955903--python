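"""Keyword screening, mention extraction and qualifier scoping."""

import datetime as dt
import re
import unicodedata

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sasurv.lexicon import ADVERSATIVES, KeywordDictionary
from sasurv.nlp import (classify_stay, extract_mentions, qualify_mention,
                        screen_stays, select_discharge_summary)
from sasurv.types import NoteRecord


def note(text, stay_id="S1", note_type="discharge_summary",
         note_id="N1", day=5):
    return NoteRecord(note_id=note_id, stay_id=stay_id, note_type=note_type,
                      edited_dt=dt.datetime(2020, 1, day), text=text)


# ---------------------------------------------------------------------------
# independent brute-force oracle for qualifier scoping
# ---------------------------------------------------------------------------

def _oracle_fold(text):
    out = []
    for ch in text:
        d = unicodedata.normalize("NFKD", ch)
        base = "".join(c for c in d if not unicodedata.combining(c))
        out.append(base.lower() if len(base) == 1 else ch.lower())
    return "".join(out)


def oracle_qualify(text, span, dictionary):
    """Token-by-token scan, structured differently from the implementation:
    cut the text at the nearest sentence break on each side of the mention,
    drop everything beyond the last adversative, window, then look for the
    trigger token sequence."""
    folded = _oracle_fold(text)
    toks = [(m.start(), m.end(), m.group()) for m in re.finditer(r"\w+", folded)]
    breaks = set(".!?;\n")

    def side_tokens(side):
        if side == "pre":
            cut = max((i + 1 for i, ch in enumerate(folded[:span[0]])
                       if ch in breaks), default=0)
            seq = [t for t in toks if t[0] >= cut and t[1] <= span[0]]
        else:
            rel = next((i for i, ch in enumerate(folded[span[1]:])
                        if ch in breaks), None)
            cut = len(folded) if rel is None else span[1] + rel
            seq = [t for t in toks if t[0] >= span[1] and t[1] <= cut]
        adv = [i for i, t in enumerate(seq) if t[2] in ADVERSATIVES]
        if adv:
            seq = seq[adv[-1] + 1:] if side == "pre" else seq[:adv[0]]
        return [t[2] for t in seq]

    flags = {}
    for qualifier, triggers in dictionary.triggers.items():
        hit = False
        for trig in triggers:
            sides = ("pre", "post") if trig.direction == "both" else (trig.direction,)
            for side in sides:
                toks_side = side_tokens(side)
                windowed = toks_side[-trig.window:] if side == "pre" \
                    else toks_side[:trig.window]
                k = len(trig.tokens)
                if any(tuple(windowed[i:i + k]) == trig.tokens
                       for i in range(len(windowed) - k + 1)):
                    hit = True
                    break
            if hit:
                break
        flags[qualifier] = hit
    return flags


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------

class TestScreening:
    def test_match_in_non_discharge_note_screens_stay(self, en_dict):
        notes = [
            note("Generic summary without findings.", note_id="N1"),
            note("Seen after a suicide attempt last night.", note_id="N2",
                 note_type="other"),
        ]
        assert screen_stays(notes, en_dict) == {"S1"}

    def test_no_keyword_not_screened(self, en_dict):
        assert screen_stays([note("Routine visit for a fracture.")], en_dict) == set()

    def test_empty_text_skipped(self, en_dict):
        n = note("x", note_type="other")
        object.__setattr__(n, "text", "")
        assert screen_stays([n], en_dict) == set()

    def test_word_boundary_blocks_embedded_keyword(self):
        d = KeywordDictionary.from_rows([("overdose", "intentional-drug-overdose")])
        assert screen_stays([note("The patient overdosed badly.")], d) == set()
        assert screen_stays([note("An overdose was treated.")], d) == {"S1"}

    def test_accent_and_case_folding(self, fr_dict):
        text = "INTOXICATION MEDICAMENTEUSE VOLONTAIRE confirmée."
        assert screen_stays([note(text)], fr_dict) == {"S1"}


# ---------------------------------------------------------------------------
# mention extraction
# ---------------------------------------------------------------------------

class TestExtractMentions:
    def test_single_keyword_span(self, en_dict):
        text = "Observed suicide attempt yesterday."
        (m,) = extract_mentions(text, en_dict)
        assert (m.start, m.end) == (9, 24)
        assert text[m.start:m.end] == m.surface == "suicide attempt"
        assert m.modality == "other"

    def test_longest_match_wins_on_overlap(self):
        d = KeywordDictionary.from_rows([
            ("drug overdose", "other"),
            ("intentional drug overdose", "intentional-drug-overdose"),
        ])
        text = "Admitted for intentional drug overdose."
        (m,) = extract_mentions(text, d)
        assert m.surface == "intentional drug overdose"
        assert m.modality == "intentional-drug-overdose"

    def test_empty_text(self, en_dict):
        assert extract_mentions("", en_dict) == []

    def test_multiple_nonoverlapping(self, en_dict):
        text = ("A suicide attempt after an intentional drug overdose.")
        surfaces = [m.surface for m in extract_mentions(text, en_dict)]
        assert surfaces == ["suicide attempt", "intentional drug overdose"]

    @settings(max_examples=50, deadline=None)
    @given(data=st.data())
    def test_span_integrity_on_random_corpora(self, data, en_dict):
        """text[start:end] == surface for every annotation."""
        fillers = ["care", "ward", "Review", "stable", "éé", "night.", "but"]
        keywords = ["suicide attempt", "attempted hanging", "intentional drowning"]
        words = data.draw(st.lists(
            st.sampled_from(fillers + keywords), min_size=0, max_size=30))
        text = " ".join(words)
        for m in extract_mentions(text, en_dict):
            assert text[m.start:m.end] == m.surface


# ---------------------------------------------------------------------------
# qualifier scoping
# ---------------------------------------------------------------------------

class TestQualify:
    @pytest.mark.parametrize("text,expected", [
        ("There was no suicide attempt.", {"negation"}),
        ("History of suicide attempt noted.", {"history"}),
        ("Her mother survived a suicide attempt.", {"family"}),
        ("A possible suicide attempt could not be excluded.", {"hypothesis"}),
        ("The patient reports a suicide attempt.", {"reported_speech"}),
        ("Admission for suicide attempt yesterday.", set()),
        # terminator between trigger and mention resets the scope
        ("There was no fracture. A suicide attempt was confirmed.", set()),
        # adversative conjunction blocks the scope
        ("No injury but a suicide attempt was confirmed.", set()),
    ])
    def test_trigger_geometry(self, en_dict, text, expected):
        (m,) = extract_mentions(text, en_dict)
        qualify_mention(text, m, en_dict)
        fired = {q for q, v in m.qualifier_flags.items() if v}
        assert fired == expected
        assert m.valid == (not expected)

    def test_pre_only_trigger_ignored_after_mention(self, en_dict):
        # "no" is pre-only: after the mention it must not fire
        text = "A suicide attempt with no injury."
        (m,) = extract_mentions(text, en_dict)
        qualify_mention(text, m, en_dict)
        assert not m.negation and m.valid

    def test_both_direction_trigger_fires_after_mention(self, en_dict):
        text = "A suicide attempt by her mother was discussed."
        (m,) = extract_mentions(text, en_dict)
        qualify_mention(text, m, en_dict)
        assert m.family and not m.valid

    def test_trigger_outside_window_ignored(self, en_dict):
        filler = " ".join(["word"] * 9)
        text = f"No {filler} suicide attempt happened."
        (m,) = extract_mentions(text, en_dict)
        qualify_mention(text, m, en_dict)
        assert not m.negation

    def test_span_outside_text_raises(self, en_dict):
        from sasurv.types import MentionAnnotation
        bad = MentionAnnotation(start=5, end=50, surface="x", modality="other")
        with pytest.raises(ValueError):
            qualify_mention("short", bad, en_dict)

    @pytest.mark.parametrize("lang", ["en", "fr"])
    def test_agrees_with_brute_force_oracle(self, lang, en_dict, fr_dict):
        """Rendered corpora: implementation == independent token-scan oracle."""
        import numpy as np
        from sasurv.synthetic import NoteFeatures, render_note
        from sasurv.templates import CONTEXTS, SA_SURFACES
        dictionary = en_dict if lang == "en" else fr_dict
        rng = np.random.default_rng(5)
        for context in CONTEXTS:
            for modality in SA_SURFACES[lang]:
                for _ in range(3):
                    text = render_note(
                        NoteFeatures(sa_context=context, sa_modality=modality),
                        language=lang, seed=rng)
                    for m in extract_mentions(text, dictionary):
                        qualify_mention(text, m, dictionary)
                        assert m.qualifier_flags == oracle_qualify(
                            text, (m.start, m.end), dictionary), text

    @settings(max_examples=80, deadline=None)
    @given(data=st.data())
    def test_oracle_agreement_on_random_token_soup(self, data, en_dict):
        vocab = ["no", "mother", "history", "of", "possible", "reports",
                 "ward", "care", "but", "night.", "the", "previous",
                 "years", "ago", "stable;"]
        pre = data.draw(st.lists(st.sampled_from(vocab), max_size=12))
        post = data.draw(st.lists(st.sampled_from(vocab), max_size=12))
        text = " ".join(pre + ["suicide attempt"] + post)
        (m, *_) = extract_mentions(text, en_dict)
        qualify_mention(text, m, en_dict)
        assert m.qualifier_flags == oracle_qualify(text, (m.start, m.end), en_dict)

    def test_monotonicity_adding_trigger_never_validates(self, en_dict):
        """Inserting a qualifier trigger inside the scope can only invalidate."""
        base = "Routine note. A suicide attempt was confirmed today."
        variants = [
            base.replace("A suicide", "no suicide"),
            base.replace("A suicide", "possible suicide"),
            base.replace("A suicide", "her mother had a suicide"),
        ]
        (m0,) = extract_mentions(base, en_dict)
        qualify_mention(base, m0, en_dict)
        assert m0.valid
        for text in variants:
            (m,) = extract_mentions(text, en_dict)
            qualify_mention(text, m, en_dict)
            assert not m.valid, text


# ---------------------------------------------------------------------------
# summary selection and stay classification
# ---------------------------------------------------------------------------

class TestClassifyStay:
    def test_last_edited_summary_selected(self):
        notes = [note("draft", note_id="A", day=3), note("final", note_id="B", day=5)]
        assert select_discharge_summary(notes).note_id == "B"

    def test_tie_broken_by_note_id(self):
        notes = [note("one", note_id="B", day=3), note("two", note_id="A", day=3)]
        assert select_discharge_summary(notes).note_id == "B"

    def test_only_other_notes_gives_none(self):
        assert select_discharge_summary(
            [note("x", note_type="other")]) is None

    def test_affirmed_mention_classifies_sa(self, en_dict):
        cls = classify_stay(
            "S1", [note("The clinical examination confirmed a suicide attempt.")],
            en_dict)
        assert cls.sa_caused and cls.screened
        assert cls.classifier_id == "rule-based"

    def test_only_qualified_mentions_not_sa(self, en_dict):
        text = ("There was no suicide attempt. "
                "Her mother survived a suicide attempt.")
        cls = classify_stay("S1", [note(text)], en_dict)
        assert cls.screened and not cls.sa_caused

    def test_one_valid_mention_suffices(self, en_dict):
        text = ("There was no suicide attempt before. "
                "Admission for suicide attempt yesterday.")
        cls = classify_stay("S1", [note(text)], en_dict)
        assert cls.sa_caused

    def test_no_summary_unclassifiable(self, en_dict):
        cls = classify_stay(
            "S1", [note("after a suicide attempt", note_type="other")], en_dict)
        assert cls.screened and not cls.sa_caused and cls.unclassifiable

    def test_classification_uses_last_edited_summary_only(self, en_dict):
        notes = [
            note("Admission for suicide attempt yesterday.", note_id="A", day=3),
            note("Stable. Nothing to report today.", note_id="B", day=6),
        ]
        cls = classify_stay("S1", notes, en_dict)
        assert not cls.sa_caused  # the later summary holds no valid mention

    def test_pluggable_classifier_overrides_rule(self, en_dict):
        text = "There was no suicide attempt."
        always_valid = lambda t, m: True
        cls = classify_stay("S1", [note(text)], en_dict, classifier=always_valid)
        assert cls.sa_caused and cls.classifier_id == "custom"
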