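"""Synthetic multi-hospital EHR generator.

Produces stay tables, clinical notes and a ground-truth table with the
statistical structure the downstream analysis assumes:

* per-stratum monthly counts of true suicide-attempt (SA) stays follow the
  segmented, seasonally-adjusted mean model (level + trend + post-breakpoint
  trend change + calendar-month effects) under a configurable noise model;
* each true SA stay receives a discharge summary embedding an affirmed SA
  keyword, plus risk-factor sentences drawn at configurable pre/post
  prevalences; background (non-SA) stays are added at a configurable ratio,
  a fraction of which contain SA keywords in non-affirmed contexts
  (negation, family, history, hypothesis, reported speech) to exercise the
  qualifier rules;
* per-hospital-month discharge-summary completeness, claim-code sensitivity
  and deliberate within-15-day duplicate stays are all configurable, so the
  completeness adjustment, the claims-only classifier and the deduplication
  rule can each be audited against ground truth.

Everything is driven by one root seed; identical configurations produce
byte-identical corpora.
"""

from __future__ import annotations

import datetime as dt
import logging
import warnings
from calendar import monthrange
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from . import templates as tpl
from .series import (DEFAULT_BREAKPOINT, DEFAULT_EXTRACTION_DATE,
                     DEFAULT_STUDY_END, DEFAULT_STUDY_START, MonthlySeries,
                     its_mean, month_index, n_study_months)
from .types import AGE_BANDS, RISK_FACTORS, NoteRecord, StayRecord

logger = logging.getLogger(__name__)

AGE_RANGES = {"8-17": (8, 17), "18-25": (18, 25), "26-65": (26, 65), "66+": (66, 95)}

#: ICD-10 intentional self-harm block used for synthetic claim codes
SELF_HARM_CODES = tuple(f"X{c}" for c in range(60, 85))
BACKGROUND_CODES = ("F329", "S7200", "J189", "K358", "I639", "O800", "M545", "E119")


class StratumParams(BaseModel):
    """Segmented-model parameters generating one sex x age-band series."""

    sex: str
    age_band: str
    level: float
    trend: float = 0.0
    trend_variation: float = 0.0
    sigma: float = 0.0
    seasonal: dict[int, float] = Field(default_factory=dict)

    @field_validator("age_band")
    @classmethod
    def _band(cls, v: str) -> str:
        if v not in AGE_BANDS:
            raise ValueError(f"unknown age band {v!r}")
        return v

    @property
    def label(self) -> str:
        return f"{self.sex}_{self.age_band}"


def reference_strata() -> list[StratumParams]:
    """Default per-stratum parameters of the reference surveillance analysis.

    Noise scale: 6 counts/month for the two 8-17 strata (visibly
    overdispersed youth series), Poisson-like sqrt(level) elsewhere.
    """
    rows = [
        ("male", "8-17", 6.0, 0.1, 0.1),
        ("male", "18-25", 6.5, 0.1, 0.1),
        ("male", "26-65", 39.7, 0.3, 0.3),
        ("male", "66+", 10.2, -0.1, 0.3),
        ("female", "8-17", 23.2, 0.1, 1.8),
        ("female", "18-25", 13.5, 0.2, 1.1),
        ("female", "26-65", 44.8, 0.7, -0.2),
        ("female", "66+", 14.0, 0.1, 0.1),
    ]
    return [
        StratumParams(
            sex=sex, age_band=band, level=level, trend=trend,
            trend_variation=tv,
            sigma=6.0 if band == "8-17" else round(level ** 0.5, 2),
        )
        for sex, band, level, trend, tv in rows
    ]


def _default_rf_prevalence() -> dict[str, tuple[float, float]]:
    # (pre, post) reporting prevalences among SA stays
    return {
        "social_isolation": (0.06, 0.08),
        "domestic_violence": (0.06, 0.08),
        "sexual_violence": (0.04, 0.07),
        "physical_violence": (0.02, 0.03),
        "sa_history": (0.36, 0.40),
    }


def _default_context_rates() -> dict[str, float]:
    return {q: 0.2 for q in
            ("negation", "family", "history", "hypothesis", "reported_speech")}


class SimulationConfig(BaseModel):
    """Full description of one synthetic corpus."""

    n_hospitals: int = 15
    study_start: dt.date = DEFAULT_STUDY_START
    study_end: dt.date = DEFAULT_STUDY_END
    breakpoint_date: dt.date = DEFAULT_BREAKPOINT
    extraction_date: dt.date = DEFAULT_EXTRACTION_DATE
    strata: list[StratumParams] = Field(default_factory=reference_strata)
    noise: str = "gaussian"  # "none" | "gaussian" | "poisson"
    background_sa_ratio: float = 2.7
    confounder_fraction: float = 0.05
    qualifier_context_rates: dict[str, float] = Field(
        default_factory=_default_context_rates)
    risk_factor_prevalence: dict[str, tuple[float, float]] = Field(
        default_factory=_default_rf_prevalence)
    completeness: float = 0.98
    completeness_overrides: dict[str, float] = Field(default_factory=dict)
    echo_stay_prob: float = 0.04
    new_patient_prob: float = 0.85
    claim_sensitivity: float = 0.85
    claim_fp_rate: float = 0.002
    other_note_prob: float = 0.8
    draft_summary_prob: float = 0.1
    los_median_pre: float = 6.0
    los_median_post: float = 5.0
    los_sigma: float = 0.8
    death_prob_pre: float = 0.015
    death_prob_post: float = 0.010
    language: str = "en"
    seed: int = 0

    @field_validator("noise")
    @classmethod
    def _noise(cls, v: str) -> str:
        if v not in ("none", "gaussian", "poisson"):
            raise ValueError(f"unknown noise model {v!r}")
        return v

    @field_validator("language")
    @classmethod
    def _lang(cls, v: str) -> str:
        if v not in tpl.SA_TEMPLATES:
            raise ValueError(f"no template bank for language {v!r}")
        return v

    @model_validator(mode="after")
    def _probabilities(self) -> "SimulationConfig":
        probs = {
            "confounder_fraction": self.confounder_fraction,
            "completeness": self.completeness,
            "echo_stay_prob": self.echo_stay_prob,
            "new_patient_prob": self.new_patient_prob,
            "claim_sensitivity": self.claim_sensitivity,
            "claim_fp_rate": self.claim_fp_rate,
            "other_note_prob": self.other_note_prob,
            "draft_summary_prob": self.draft_summary_prob,
            "death_prob_pre": self.death_prob_pre,
            "death_prob_post": self.death_prob_post,
            **{f"context[{k}]": v for k, v in self.qualifier_context_rates.items()},
            **{f"completeness[{k}]": v for k, v in self.completeness_overrides.items()},
        }
        for factor, (pre, post) in self.risk_factor_prevalence.items():
            if factor not in RISK_FACTORS:
                raise ValueError(f"unknown risk factor {factor!r}")
            probs[f"rf[{factor}] pre"] = pre
            probs[f"rf[{factor}] post"] = post
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} = {p} outside [0, 1]")
        if self.study_end <= self.study_start:
            raise ValueError("study_end must follow study_start")
        if not self.study_start < self.breakpoint_date <= self.study_end:
            raise ValueError("breakpoint must lie inside the study window")
        return self

    @property
    def n_months(self) -> int:
        return n_study_months(self.study_start, self.study_end)

    @property
    def breakpoint_index(self) -> int:
        return month_index(self.breakpoint_date, self.study_start)

    def hospital_ids(self) -> list[str]:
        return [f"H{i:02d}" for i in range(1, self.n_hospitals + 1)]

    def month_completeness(self, hospital_id: str, t: int) -> float:
        return self.completeness_overrides.get(f"{hospital_id}:{t}", self.completeness)


# ---------------------------------------------------------------------------
# monthly series
# ---------------------------------------------------------------------------

def generate_monthly_series(level: float,
                            trend: float,
                            trend_variation: float,
                            n_months: int,
                            breakpoint_index: int,
                            seasonal: dict[int, float] | None = None,
                            noise: str = "none",
                            sigma: float = 0.0,
                            seed: int | np.random.Generator | None = None,
                            stratum: str = "overall",
                            start: dt.date = DEFAULT_STUDY_START) -> MonthlySeries:
    """Monthly counts from the segmented seasonal mean under a noise model.

    ``noise="none"`` returns the exact (possibly non-integer) mean;
    ``"gaussian"`` adds N(0, sigma) and rounds to the nearest nonnegative
    integer; ``"poisson"`` draws Poisson counts, truncating negative means
    at 0 with a warning.
    """
    mu = its_mean(n_months, level, trend, trend_variation, breakpoint_index,
                  seasonal, start_month_of_year=start.month)
    if noise == "none":
        counts = mu
    else:
        rng = seed if isinstance(seed, np.random.Generator) \
            else np.random.default_rng(seed)
        if noise == "gaussian":
            counts = np.maximum(np.rint(mu + rng.normal(0.0, sigma, n_months)), 0.0)
        elif noise == "poisson":
            if (mu < 0).any():
                warnings.warn("negative mean months truncated to 0 in poisson mode")
            counts = rng.poisson(np.maximum(mu, 0.0)).astype(float)
        else:
            raise ValueError(f"unknown noise model {noise!r}")
    return MonthlySeries(counts=counts, stratum=stratum,
                         breakpoint_index=breakpoint_index, start=start)


# ---------------------------------------------------------------------------
# note rendering
# ---------------------------------------------------------------------------

@dataclass
class NoteFeatures:
    """Truth flags a rendered summary must realise."""

    sa_context: str | None = None  # None: no SA keyword at all
    sa_modality: str = "other"
    risk_factors: list[str] = field(default_factory=list)


def render_note(features: NoteFeatures,
                language: str = "en",
                seed: int | np.random.Generator | None = None) -> str:
    """Templated clinical-style summary realising *features*.

    Each requested mention appears exactly once, inside the requested
    qualification context; unknown context keys raise.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    if language not in tpl.SA_TEMPLATES:
        raise ValueError(f"no template bank for language {language!r}")

    def pick(options: list[str]) -> str:
        return options[int(rng.integers(len(options)))]

    parts = [pick(tpl.OPENINGS[language])]
    if features.sa_context is not None:
        if features.sa_context not in tpl.CONTEXTS:
            raise ValueError(f"unknown qualifier context {features.sa_context!r}")
        surfaces = tpl.SA_SURFACES[language].get(features.sa_modality)
        if not surfaces:
            raise ValueError(f"no {language!r} surface for modality "
                             f"{features.sa_modality!r}")
        template = pick(tpl.SA_TEMPLATES[language][features.sa_context])
        parts.append(template.format(kw=pick(surfaces)))
    else:
        parts.append(pick(tpl.BACKGROUND_BODY[language]))
    for factor in features.risk_factors:
        if factor not in RISK_FACTORS:
            raise ValueError(f"unknown risk factor {factor!r}")
        template = pick(tpl.RF_TEMPLATES[language][factor])
        parts.append(template.format(kw=tpl.RF_SURFACES[language][factor]))
    parts.append(pick(tpl.CLOSINGS[language]))
    return " ".join(parts)


# ---------------------------------------------------------------------------
# full corpus
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCorpus:
    stays: list[StayRecord]
    notes: list[NoteRecord]
    truth: pd.DataFrame
    config: SimulationConfig


def _random_datetime_in_month(rng: np.random.Generator,
                              start: dt.date, t: int) -> dt.datetime:
    year = start.year + (start.month - 1 + t) // 12
    month = (start.month - 1 + t) % 12 + 1
    day = int(rng.integers(1, monthrange(year, month)[1] + 1))
    return dt.datetime(year, month, day,
                       int(rng.integers(24)), int(rng.integers(60)))


class _IdMaker:
    def __init__(self, prefix: str) -> None:
        self.prefix = prefix
        self.n = 0

    def __call__(self) -> str:
        self.n += 1
        return f"{self.prefix}{self.n:07d}"


def generate_cohort(config: SimulationConfig,
                    seed: int | None = None) -> SyntheticCorpus:
    """Generate stays, notes and ground truth for one configuration.

    The returned truth table has one row per stay: true SA status, stratum,
    admission month index, the qualifier context used for any embedded SA
    keyword, risk-factor flags, completeness outcome and a marker for
    deliberate within-15-day duplicate ("echo") stays, which are extra stays
    on top of the configured series so that deduplicated counts match it.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lang = config.language
    start, n_months, bp = config.study_start, config.n_months, config.breakpoint_index
    hospitals = config.hospital_ids()
    stay_ids, patient_ids, note_ids = _IdMaker("S"), _IdMaker("P"), _IdMaker("N")
    modalities = list(tpl.SA_SURFACES[lang])
    contexts = list(config.qualifier_context_rates)
    context_probs = np.array([config.qualifier_context_rates[c] for c in contexts])
    if context_probs.sum() > 0:
        context_probs = context_probs / context_probs.sum()

    stays: list[StayRecord] = []
    notes: list[NoteRecord] = []
    truth_rows: list[dict] = []
    extraction = dt.datetime.combine(config.extraction_date, dt.time(0, 0))

    def make_stay(admission: dt.datetime, *, patient_id: str, sex: str, age: int,
                  stratum: str, true_sa: bool, sa_context: str | None,
                  echo: bool) -> None:
        t = month_index(admission.date(), start)
        post = admission.date() >= config.breakpoint_date
        hospital = hospitals[int(rng.integers(len(hospitals)))]
        # length of stay / outcome
        median = config.los_median_post if post else config.los_median_pre
        los_days = float(rng.lognormal(np.log(median), config.los_sigma))
        discharge: dt.datetime | None = admission + dt.timedelta(days=max(los_days, 0.04))
        death = False
        if discharge > extraction:
            discharge = None  # censored at extraction
        elif true_sa:
            death = bool(rng.random() <
                         (config.death_prob_post if post else config.death_prob_pre))
        # claim codes
        codes: set[str] = set()
        if true_sa:
            if rng.random() < config.claim_sensitivity:
                codes.add(SELF_HARM_CODES[int(rng.integers(len(SELF_HARM_CODES)))])
        elif rng.random() < config.claim_fp_rate:
            codes.add(SELF_HARM_CODES[int(rng.integers(len(SELF_HARM_CODES)))])
        codes.add(BACKGROUND_CODES[int(rng.integers(len(BACKGROUND_CODES)))])
        stay_id = stay_ids()
        stays.append(StayRecord(
            stay_id=stay_id, patient_id=patient_id, hospital_id=hospital,
            admission_dt=admission, discharge_dt=discharge,
            age_at_admission=age, sex=sex, death_during_stay=death,
            icd10_codes=frozenset(codes),
        ))
        # risk factors (reported only for true SA stays)
        rf = {f: False for f in RISK_FACTORS}
        if true_sa:
            for factor, (pre_p, post_p) in config.risk_factor_prevalence.items():
                rf[factor] = bool(rng.random() < (post_p if post else pre_p))
        modality = modalities[int(rng.integers(len(modalities)))] \
            if sa_context is not None else "other"
        # notes
        has_summary = bool(rng.random() < config.month_completeness(hospital, t))
        note_end = discharge if discharge is not None else extraction
        if has_summary:
            if rng.random() < config.draft_summary_prob:
                notes.append(NoteRecord(
                    note_id=note_ids(), stay_id=stay_id,
                    note_type="discharge_summary",
                    edited_dt=admission + dt.timedelta(hours=1),
                    text=tpl.DRAFT_SUMMARY[lang],
                ))
            features = NoteFeatures(
                sa_context=sa_context, sa_modality=modality,
                risk_factors=[f for f in RISK_FACTORS if rf[f]],
            )
            notes.append(NoteRecord(
                note_id=note_ids(), stay_id=stay_id,
                note_type="discharge_summary", edited_dt=note_end,
                text=render_note(features, language=lang, seed=rng),
            ))
        if rng.random() < config.other_note_prob:
            text = tpl.ADMISSION_NOTE_SA[lang] if true_sa \
                else tpl.ADMISSION_NOTE_PLAIN[lang]
            notes.append(NoteRecord(
                note_id=note_ids(), stay_id=stay_id, note_type="other",
                edited_dt=admission + dt.timedelta(minutes=30), text=text))
        truth_rows.append({
            "stay_id": stay_id, "patient_id": patient_id, "hospital_id": hospital,
            "true_sa": true_sa, "stratum": stratum, "month_index": t,
            "sex": sex, "age": age, "period": "post" if post else "pre",
            "sa_context": sa_context or "", "has_summary": has_summary,
            "echo": echo, "death": death,
            "censored": discharge is None,
            **{f"rf_{f}": rf[f] for f in RISK_FACTORS},
        })

    # --- true SA stays, stratum by stratum ---------------------------------
    sa_totals_per_month = np.zeros(n_months)
    for stratum in config.strata:
        series = generate_monthly_series(
            stratum.level, stratum.trend, stratum.trend_variation,
            n_months, bp, stratum.seasonal, noise=config.noise,
            sigma=stratum.sigma, seed=rng, stratum=stratum.label, start=start,
        )
        sa_totals_per_month += series.counts
        lo, hi = AGE_RANGES[stratum.age_band]
        patient_history: dict[str, list[dt.datetime]] = {}
        pool: list[str] = []
        for t in range(n_months):
            for _ in range(int(round(series.counts[t]))):
                admission = _random_datetime_in_month(rng, start, t)
                patient_id = None
                if pool and rng.random() > config.new_patient_prob:
                    # reuse only when well clear of the 15-day dedup window,
                    # so deduplication never removes an intended event
                    pid = pool[int(rng.integers(len(pool)))]
                    if all(abs((admission - a).days) >= 17
                           for a in patient_history[pid]):
                        patient_id = pid
                if patient_id is None:
                    patient_id = patient_ids()
                age = int(rng.integers(lo, hi + 1))
                make_stay(admission, patient_id=patient_id, sex=stratum.sex,
                          age=age, stratum=stratum.label, true_sa=True,
                          sa_context="affirmed", echo=False)
                if patient_id not in patient_history:
                    patient_history[patient_id] = []
                    pool.append(patient_id)
                patient_history[patient_id].append(admission)
                if rng.random() < config.echo_stay_prob:
                    echo_adm = admission + dt.timedelta(
                        days=int(rng.integers(1, 15)), hours=int(rng.integers(24)))
                    if echo_adm.date() <= config.study_end:
                        make_stay(echo_adm, patient_id=patient_id,
                                  sex=stratum.sex, age=age,
                                  stratum=stratum.label, true_sa=True,
                                  sa_context="affirmed", echo=True)
                        patient_history[patient_id].append(echo_adm)

    # --- background stays --------------------------------------------------
    for t in range(n_months):
        n_bg = int(round(config.background_sa_ratio * sa_totals_per_month[t]))
        for _ in range(n_bg):
            admission = _random_datetime_in_month(rng, start, t)
            sex = "female" if rng.random() < 0.5 else "male"
            age = int(rng.integers(0, 96))
            sa_context = None
            if contexts and rng.random() < config.confounder_fraction:
                sa_context = contexts[int(rng.choice(len(contexts), p=context_probs))]
            make_stay(admission, patient_id=patient_ids(), sex=sex, age=age,
                      stratum="background", true_sa=False,
                      sa_context=sa_context, echo=False)

    truth = pd.DataFrame(truth_rows)
    logger.info("generated %d stays (%d true SA), %d notes",
                len(stays), int(truth["true_sa"].sum()), len(notes))
    return SyntheticCorpus(stays=stays, notes=notes, truth=truth, config=config)
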