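"""Rule-based detection of suicide-attempt risk factors in discharge summaries.

Five factors are screened for in the same summary used for stay
classification: social isolation, domestic violence, sexual violence,
physical violence, and personal suicide-attempt history.  Each factor has
its own keyword lexicon but shares the qualifier trigger lexicon of the
language bank: a factor is flagged iff at least one of its mentions carries
no qualifier.  The one exception is suicide-attempt history, for which the
*history* qualifier is ignored — the factor is by definition historical, so
phrases like "previous suicide attempt in 2015" must still count.
"""

from __future__ import annotations

from .lexicon import KeywordDictionary
from .nlp import annotate_summary
from .types import RISK_FACTORS, MentionAnnotation, RiskFactorFlags


def _factor_valid(mention: MentionAnnotation, factor: str) -> bool:
    flags = mention.qualifier_flags
    if factor == "sa_history":
        flags = {q: v for q, v in flags.items() if q != "history"}
    return not any(flags.values())


def detect_risk_factors(summary_text: str,
                        lexicons: dict[str, KeywordDictionary]) -> RiskFactorFlags:
    """Flag each risk factor found affirmed in *summary_text*."""
    unknown = set(lexicons) - set(RISK_FACTORS)
    if unknown:
        raise ValueError(f"unknown risk factors: {sorted(unknown)}")
    flags = RiskFactorFlags()
    if not summary_text:
        return flags
    for factor, lexicon in lexicons.items():
        mentions = annotate_summary(summary_text, lexicon)
        if any(_factor_valid(m, factor) for m in mentions):
            setattr(flags, factor, True)
    return flags
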