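"""Core record types shared across the pipeline.

These are deliberately plain dataclasses: the pipeline moves them in and out
of pandas frames at module boundaries, but the unit contracts (invariants,
qualifier flags, censoring rules) are easiest to state on single records.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field

QUALIFIERS = ("negation", "family", "history", "hypothesis", "reported_speech")

RISK_FACTORS = (
    "social_isolation",
    "domestic_violence",
    "sexual_violence",
    "physical_violence",
    "sa_history",
)

AGE_BANDS = ("8-17", "18-25", "26-65", "66+")

SEXES = ("male", "female")


def age_band(age: int) -> str | None:
    """Closed age bands used for stratification; None below the 8-year floor."""
    if age < 8:
        return None
    if age <= 17:
        return "8-17"
    if age <= 25:
        return "18-25"
    if age <= 65:
        return "26-65"
    return "66+"


@dataclass(frozen=True)
class StayRecord:
    """One hospitalisation stay with its administrative data and claim codes."""

    stay_id: str
    patient_id: str
    hospital_id: str
    admission_dt: dt.datetime
    discharge_dt: dt.datetime | None
    age_at_admission: int
    sex: str
    death_during_stay: bool
    icd10_codes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.discharge_dt is not None and self.discharge_dt < self.admission_dt:
            raise ValueError(f"stay {self.stay_id}: discharge before admission")
        if self.death_during_stay and self.discharge_dt is None:
            raise ValueError(f"stay {self.stay_id}: death implies a terminated stay")
        if self.age_at_admission < 0:
            raise ValueError(f"stay {self.stay_id}: negative age")
        if self.sex not in SEXES:
            raise ValueError(f"stay {self.stay_id}: unknown sex {self.sex!r}")


@dataclass(frozen=True)
class NoteRecord:
    """One clinical document attached to a stay."""

    note_id: str
    stay_id: str
    note_type: str  # "discharge_summary" | "other"
    edited_dt: dt.datetime
    text: str

    def __post_init__(self) -> None:
        if self.note_type == "discharge_summary" and not self.text:
            raise ValueError(f"note {self.note_id}: empty discharge summary")


@dataclass
class MentionAnnotation:
    """A matched keyword span with its qualification status.

    Spans are 0-based half-open character offsets into the *original* note
    text, so ``text[start:end] == surface`` always holds.
    """

    start: int
    end: int
    surface: str
    modality: str
    note_id: str | None = None
    negation: bool = False
    family: bool = False
    history: bool = False
    hypothesis: bool = False
    reported_speech: bool = False

    @property
    def qualifier_flags(self) -> dict[str, bool]:
        return {q: getattr(self, q) for q in QUALIFIERS}

    @property
    def valid(self) -> bool:
        """A mention is a valid case assertion iff no qualifier applies."""
        return not any(self.qualifier_flags.values())


@dataclass
class StayClassification:
    stay_id: str
    screened: bool
    sa_caused: bool
    mentions: list[MentionAnnotation] = field(default_factory=list)
    classifier_id: str = "rule-based"
    unclassifiable: bool = False  # no discharge summary available

    def __post_init__(self) -> None:
        if self.sa_caused and not self.screened:
            raise ValueError("sa_caused implies screened")


@dataclass
class RiskFactorFlags:
    social_isolation: bool = False
    domestic_violence: bool = False
    sexual_violence: bool = False
    physical_violence: bool = False
    sa_history: bool = False

    def as_dict(self) -> dict[str, bool]:
        return dataclasses.asdict(self)


@dataclass
class CohortEntry:
    """A retained suicide-attempt stay with its stratum labels."""

    stay_id: str
    patient_id: str
    hospital_id: str
    admission_dt: dt.datetime
    month_index: int  # months since the study start month
    sex: str
    age_band: str
    length_of_stay: float  # whole days; lower bound when censored
    censored: bool
    death: bool
    risk_factors: RiskFactorFlags = field(default_factory=RiskFactorFlags)
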