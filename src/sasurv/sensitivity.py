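"""Sensitivity analyses around the main surveillance result.

Four variants probe the robustness of the post-breakpoint trend change:

1. a claims-only stay classifier using ICD-10 intentional self-harm codes
   (default block X60-X84) instead of the NLP pipeline;
2. the rule-only mention classifier (already the default policy of
   ``nlp.classify_stay``; the hook exists for hybrid classifiers);
3. a completeness adjustment dividing each monthly count by the fraction of
   that month's stays possessing a discharge summary;
4. independent per-hospital fits of the segmented model.
"""

from __future__ import annotations

import datetime as dt
import logging
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import monthly_counts
from .its import MIN_MONTHS, ITSFit, fit_its
from .series import (DEFAULT_STUDY_START, MonthlySeries, month_index,
                     n_study_months)
from .types import CohortEntry, NoteRecord, StayRecord

logger = logging.getLogger(__name__)

_CODE_RE = re.compile(r"^[A-Z][0-9]{2}")


def default_self_harm_prefixes() -> frozenset[str]:
    """ICD-10 intentional self-harm block X60-X84."""
    return frozenset(f"X{c}" for c in range(60, 85))


def normalise_code(code: str) -> str:
    return code.strip().upper().replace(".", "")


def classify_stay_claims(stay: StayRecord,
                         code_prefixes: Iterable[str] | None = None) -> bool:
    """Claims-only classification: any diagnosis code in the self-harm block."""
    prefixes = tuple(code_prefixes) if code_prefixes is not None \
        else tuple(default_self_harm_prefixes())
    for raw in stay.icd10_codes:
        code = normalise_code(raw)
        if not _CODE_RE.match(code):
            logger.warning("stay %s: malformed ICD-10 code %r skipped",
                           stay.stay_id, raw)
            continue
        if code.startswith(prefixes):
            return True
    return False


def measure_completeness(stays: Sequence[StayRecord],
                         notes: Sequence[NoteRecord],
                         study_start: dt.date = DEFAULT_STUDY_START,
                         n_months: int | None = None,
                         per_hospital: bool = False) -> pd.DataFrame:
    """Fraction of stays per month (or hospital-month) with >= 1 discharge
    summary, measured from the corpus itself."""
    if n_months is None:
        n_months = n_study_months(study_start)
    with_summary = {n.stay_id for n in notes if n.note_type == "discharge_summary"}
    rows = []
    for stay in stays:
        t = month_index(stay.admission_dt.date(), study_start)
        if not 0 <= t < n_months:
            continue
        rows.append({
            "month_index": t,
            "hospital_id": stay.hospital_id if per_hospital else "all",
            "has_summary": stay.stay_id in with_summary,
        })
    frame = pd.DataFrame(rows)
    out = (frame.groupby(["hospital_id", "month_index"])["has_summary"]
           .mean().rename("completeness").reset_index())
    return out


def completeness_adjust(series: MonthlySeries,
                        completeness: np.ndarray | Sequence[float]) -> MonthlySeries:
    """Divide each monthly count by that month's summary completeness.

    The adjusted series is real-valued and may be refitted directly.
    Months with completeness 0 are uninformative and raise.
    """
    comp = np.asarray(completeness, dtype=float)
    if comp.shape != series.counts.shape:
        raise ValueError("completeness must align with the series")
    if (comp <= 0).any() or (comp > 1).any():
        bad = np.where((comp <= 0) | (comp > 1))[0]
        raise ValueError(f"completeness outside (0, 1] at months {bad.tolist()}")
    return MonthlySeries(counts=series.counts / comp,
                         stratum=f"{series.stratum}_completeness_adjusted",
                         breakpoint_index=series.breakpoint_index,
                         start=series.start)


@dataclass
class PerHospitalResult:
    fits: dict[str, ITSFit]
    skipped: list[str]

    def significant_hospitals(self) -> list[str]:
        """Hospitals whose trend-variation CI excludes zero."""
        out = []
        for hid, fit in self.fits.items():
            lo, hi = fit.conf_int["alpha2"]
            if lo > 0 or hi < 0:
                out.append(hid)
        return out


def per_hospital_analysis(entries: Sequence[CohortEntry],
                          study_start: dt.date = DEFAULT_STUDY_START,
                          **kwargs) -> PerHospitalResult:
    """Fit the segmented model independently for each hospital's series."""
    fits: dict[str, ITSFit] = {}
    skipped: list[str] = []
    for series in monthly_counts(entries, strata="hospital",
                                 study_start=study_start, **kwargs):
        if len(series) < MIN_MONTHS:
            logger.warning("hospital %s skipped: only %d months",
                           series.stratum, len(series))
            skipped.append(series.stratum)
            continue
        fits[series.stratum] = fit_its(series)
    return PerHospitalResult(fits=fits, skipped=skipped)
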