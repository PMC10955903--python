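"""Cohort construction: inclusion rules, deduplication, monthly counts.

Retained stays are those classified as suicide-attempt-caused, with patient
age >= 8 at admission and admission inside the study window.  Within-patient
repeat stays are collapsed: a stay is dropped when its admission falls
within 15 days of the most recent *retained* stay of the same patient
(chain semantics, admission-to-admission; an admission-to-discharge variant
is available behind a flag).  Events are assigned to their admission month.
"""

from __future__ import annotations

import datetime as dt
import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .series import (DEFAULT_BREAKPOINT, DEFAULT_EXTRACTION_DATE,
                     DEFAULT_STUDY_END, DEFAULT_STUDY_START, MonthlySeries,
                     month_index, n_study_months)
from .types import (CohortEntry, RiskFactorFlags, StayClassification,
                    StayRecord, age_band)

logger = logging.getLogger(__name__)

MIN_AGE = 8
DEDUP_WINDOW_DAYS = 15


def build_cohort(stays: Sequence[StayRecord],
                 classifications: Mapping[str, StayClassification],
                 risk_factors: Mapping[str, RiskFactorFlags] | None = None,
                 study_start: dt.date = DEFAULT_STUDY_START,
                 study_end: dt.date = DEFAULT_STUDY_END,
                 extraction_date: dt.date = DEFAULT_EXTRACTION_DATE,
                 min_age: int = MIN_AGE) -> list[CohortEntry]:
    """Apply inclusion rules and compute (possibly censored) lengths of stay.

    Length of stay is discharge - admission in whole days; stays not
    terminated at extraction contribute extraction - admission as a
    censored lower bound.
    """
    risk_factors = risk_factors or {}
    entries: list[CohortEntry] = []
    for stay in stays:
        cls = classifications.get(stay.stay_id)
        if cls is None:
            raise KeyError(f"no classification for stay {stay.stay_id}")
        if stay.admission_dt.date() > extraction_date:
            raise ValueError(
                f"stay {stay.stay_id} admitted after extraction date")
        if not cls.sa_caused:
            continue
        if stay.age_at_admission < min_age:
            continue
        if not study_start <= stay.admission_dt.date() <= study_end:
            continue
        if stay.discharge_dt is not None:
            los = (stay.discharge_dt - stay.admission_dt).days
            censored = False
        else:
            los = (dt.datetime.combine(extraction_date, dt.time.min)
                   - stay.admission_dt).days
            censored = True
        entries.append(CohortEntry(
            stay_id=stay.stay_id,
            patient_id=stay.patient_id,
            hospital_id=stay.hospital_id,
            admission_dt=stay.admission_dt,
            month_index=month_index(stay.admission_dt.date(), study_start),
            sex=stay.sex,
            age_band=age_band(stay.age_at_admission),
            length_of_stay=float(max(los, 0)),
            censored=censored,
            death=stay.death_during_stay,
            risk_factors=risk_factors.get(stay.stay_id, RiskFactorFlags()),
        ))
    logger.info("cohort: %d retained of %d stays", len(entries), len(stays))
    return entries


def deduplicate(entries: Iterable[CohortEntry],
                window_days: int = DEDUP_WINDOW_DAYS,
                anchor: str = "admission") -> list[CohortEntry]:
    """Collapse within-patient repeats inside the dedup window.

    ``anchor="admission"`` (default) measures the gap admission-to-admission;
    ``anchor="discharge"`` measures it from the previous retained stay's
    discharge (censored stays then block the whole window).  The first
    occurrence of a chain is always retained, and each dropped stay is
    compared against the most recent retained one, so the operation is
    idempotent.
    """
    if anchor not in ("admission", "discharge"):
        raise ValueError(f"unknown dedup anchor {anchor!r}")
    ordered = sorted(entries, key=lambda e: (e.patient_id, e.admission_dt, e.stay_id))
    kept: list[CohortEntry] = []
    last_kept: CohortEntry | None = None
    for entry in ordered:
        if last_kept is not None and entry.patient_id == last_kept.patient_id:
            if anchor == "admission":
                ref = last_kept.admission_dt
            else:
                ref = last_kept.admission_dt + dt.timedelta(
                    days=last_kept.length_of_stay)
            if (entry.admission_dt - ref).days <= window_days:
                continue
        kept.append(entry)
        last_kept = entry
    kept.sort(key=lambda e: (e.admission_dt, e.stay_id))
    return kept


def _stratum_of(entry: CohortEntry, strata: str) -> str | None:
    if strata == "overall":
        return "overall"
    if strata == "sex_age":
        return f"{entry.sex}_{entry.age_band}"
    if strata == "sex":
        return entry.sex
    if strata == "hospital":
        return entry.hospital_id
    raise ValueError(f"unknown stratification {strata!r}")


def monthly_counts(entries: Sequence[CohortEntry],
                   strata: str = "overall",
                   study_start: dt.date = DEFAULT_STUDY_START,
                   study_end: dt.date = DEFAULT_STUDY_END,
                   breakpoint_date: dt.date = DEFAULT_BREAKPOINT,
                   ) -> list[MonthlySeries]:
    """Zero-filled monthly series per stratum (admission-month convention).

    Stratifications: ``overall``, ``sex``, ``sex_age`` or ``hospital``.
    The per-stratum series always sum month-wise to the overall series.
    """
    n_months = n_study_months(study_start, study_end)
    bp = month_index(breakpoint_date, study_start)
    counts: dict[str, np.ndarray] = {}
    for entry in entries:
        label = _stratum_of(entry, strata)
        if label not in counts:
            counts[label] = np.zeros(n_months)
        if not 0 <= entry.month_index < n_months:
            raise ValueError(
                f"stay {entry.stay_id}: month index {entry.month_index} "
                f"outside the study window")
        counts[label][entry.month_index] += 1
    return [
        MonthlySeries(counts=c, stratum=label, breakpoint_index=bp,
                      start=study_start)
        for label, c in sorted(counts.items())
    ]


def cohort_frame(entries: Sequence[CohortEntry]) -> pd.DataFrame:
    """Flat table view of a cohort (one row per retained stay)."""
    rows = []
    for e in entries:
        row = {
            "stay_id": e.stay_id, "patient_id": e.patient_id,
            "hospital_id": e.hospital_id, "admission_dt": e.admission_dt,
            "month_index": e.month_index, "sex": e.sex, "age_band": e.age_band,
            "length_of_stay": e.length_of_stay, "censored": e.censored,
            "death": e.death,
        }
        row.update(e.risk_factors.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)
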