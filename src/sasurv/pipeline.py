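"""End-to-end orchestration: simulate -> detect -> cohort -> analyse.

Each stage is a plain function over in-memory objects; ``run_pipeline``
chains them, logs the record counts that mirror the surveillance flow
(eligible stays, screened, classified, post-dedup) and writes every
artefact with a content-hash manifest so identical config+seed runs are
verifiably identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as sio
from .cohort import build_cohort, cohort_frame, deduplicate, monthly_counts
from .its import fit_its, residual_diagnostics
from .lexicon import load_builtin, load_risk_factor_lexicons
from .nlp import classify_stay, screen_stays, select_discharge_summary
from .risk_factors import detect_risk_factors
from .sensitivity import (classify_stay_claims, completeness_adjust,
                          measure_completeness, per_hospital_analysis)
from .stats import km_logrank, prevalence_ratio
from .synthetic import SimulationConfig, generate_cohort
from .types import (RISK_FACTORS, CohortEntry, NoteRecord, RiskFactorFlags,
                    StayClassification, StayRecord)

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    config: SimulationConfig
    stays: list[StayRecord]
    notes: list[NoteRecord]
    truth: pd.DataFrame
    classifications: dict[str, StayClassification]
    risk_factors: dict[str, RiskFactorFlags]
    cohort: list[CohortEntry]
    counts: list
    fits: dict
    stats: dict
    sensitivity: dict
    stage_counts: dict[str, int] = field(default_factory=dict)


def detect_stage(stays: Sequence[StayRecord],
                 notes: Sequence[NoteRecord],
                 language: str = "en",
                 ) -> tuple[dict[str, StayClassification], dict[str, RiskFactorFlags]]:
    """Screening, stay classification and risk-factor detection."""
    dictionary = load_builtin(language)
    rf_lexicons = load_risk_factor_lexicons(language)
    notes_by_stay: dict[str, list[NoteRecord]] = {}
    for note in notes:
        notes_by_stay.setdefault(note.stay_id, []).append(note)
    screened = screen_stays(notes, dictionary)
    classifications: dict[str, StayClassification] = {}
    flags: dict[str, RiskFactorFlags] = {}
    for stay in stays:
        stay_notes = notes_by_stay.get(stay.stay_id, [])
        if stay.stay_id not in screened:
            classifications[stay.stay_id] = StayClassification(
                stay_id=stay.stay_id, screened=False, sa_caused=False)
            continue
        cls = classify_stay(stay.stay_id, stay_notes, dictionary,
                            screened=True)
        classifications[stay.stay_id] = cls
        if cls.sa_caused:
            summary = select_discharge_summary(stay_notes)
            flags[stay.stay_id] = detect_risk_factors(summary.text, rf_lexicons)
    return classifications, flags


def _prevalence_table(cohort: Sequence[CohortEntry],
                      breakpoint_index: int) -> list:
    comparisons = []
    frame = cohort_frame(cohort)
    if frame.empty:
        return comparisons
    pre = frame[frame.month_index < breakpoint_index]
    post = frame[frame.month_index >= breakpoint_index]
    groups = [("overall", pre, post),
              ("male", pre[pre.sex == "male"], post[post.sex == "male"]),
              ("female", pre[pre.sex == "female"], post[post.sex == "female"])]
    for factor in RISK_FACTORS:
        for group, g_pre, g_post in groups:
            if len(g_pre) == 0 or len(g_post) == 0:
                continue
            comparisons.append(prevalence_ratio(
                int(g_pre[factor].sum()), len(g_pre),
                int(g_post[factor].sum()), len(g_post),
                factor=factor, group=group))
    return comparisons


def _survival_comparisons(cohort: Sequence[CohortEntry],
                          breakpoint_index: int) -> dict:
    frame = cohort_frame(cohort)
    out: dict = {}
    if frame.empty:
        return out
    frame = frame.assign(
        period=np.where(frame.month_index < breakpoint_index, "pre", "post"),
        duration=np.maximum(frame.length_of_stay, 0.5),
    )
    groups_los = {
        period: (sub.duration.to_numpy(), (~sub.censored).to_numpy())
        for period, sub in frame.groupby("period")
    }
    if len(groups_los) == 2:
        res = km_logrank(groups_los)
        out["length_of_stay"] = {"p_value": res.p_value,
                                 "statistic": res.logrank_statistic}
        groups_death = {
            period: (sub.duration.to_numpy(), sub.death.to_numpy())
            for period, sub in frame.groupby("period")
        }
        res_d = km_logrank(groups_death)
        out["death"] = {"p_value": res_d.p_value,
                        "statistic": res_d.logrank_statistic}
    return out


def run_pipeline(config: SimulationConfig,
                 out_dir: str | Path | None = None,
                 seed: int | None = None) -> PipelineResult:
    """Run every stage on one synthetic corpus; optionally write artefacts."""
    corpus = generate_cohort(config, seed=seed)
    stays, notes, truth = corpus.stays, corpus.notes, corpus.truth
    stage_counts = {"eligible_stays": len(stays)}

    classifications, rf_flags = detect_stage(stays, notes, config.language)
    stage_counts["screened"] = sum(c.screened for c in classifications.values())
    stage_counts["classified_sa"] = sum(
        c.sa_caused for c in classifications.values())

    cohort = build_cohort(stays, classifications, rf_flags,
                          study_start=config.study_start,
                          study_end=config.study_end,
                          extraction_date=config.extraction_date)
    cohort = deduplicate(cohort)
    stage_counts["post_dedup"] = len(cohort)
    logger.info("stage counts: %s", stage_counts)

    bp = config.breakpoint_index
    kw = dict(study_start=config.study_start, study_end=config.study_end,
              breakpoint_date=config.breakpoint_date)
    counts = (monthly_counts(cohort, "overall", **kw)
              + monthly_counts(cohort, "sex_age", **kw))
    fits = {}
    for series in counts:
        try:
            fit = fit_its(series)
        except ValueError as exc:  # e.g. empty stratum
            logger.warning("skipping fit for %s: %s", series.stratum, exc)
            continue
        diag = residual_diagnostics(fit)
        fits[series.stratum] = {"fit": fit, "durbin_watson": diag.durbin_watson}

    stats = {
        "prevalence": _prevalence_table(cohort, bp),
        "survival": _survival_comparisons(cohort, bp),
    }

    # sensitivity analyses
    claims_cls = {
        s.stay_id: StayClassification(
            stay_id=s.stay_id, screened=True,
            sa_caused=classify_stay_claims(s), classifier_id="claims-only")
        for s in stays
    }
    claims_cohort = deduplicate(build_cohort(
        stays, claims_cls, {}, study_start=config.study_start,
        study_end=config.study_end, extraction_date=config.extraction_date))
    claims_series = monthly_counts(claims_cohort, "overall", **kw)
    completeness = measure_completeness(
        stays, notes, study_start=config.study_start,
        n_months=config.n_months)
    comp_by_month = (completeness.set_index("month_index")["completeness"]
                     .reindex(range(config.n_months)).fillna(1.0).to_numpy())
    overall = next(s for s in counts if s.stratum == "overall")
    adjusted = completeness_adjust(overall, comp_by_month)
    sensitivity = {
        "claims_only": {"fit": fit_its(claims_series[0]) if claims_series else None,
                        "n": len(claims_cohort)},
        "completeness_adjusted": {"fit": fit_its(adjusted)},
        "per_hospital": per_hospital_analysis(cohort, **kw),
    }

    result = PipelineResult(
        config=config, stays=stays, notes=notes, truth=truth,
        classifications=classifications, risk_factors=rf_flags,
        cohort=cohort, counts=counts, fits=fits, stats=stats,
        sensitivity=sensitivity, stage_counts=stage_counts,
    )
    if out_dir is not None:
        write_artefacts(result, Path(out_dir))
    return result


def write_artefacts(result: PipelineResult, out_dir: Path) -> dict:
    """Write every stage artefact plus a content-hash manifest."""
    out_dir.mkdir(parents=True, exist_ok=True)
    sio.write_config_yaml(result.config, out_dir / "config.yaml")
    sio.write_stays_csv(result.stays, out_dir / "stays.csv")
    sio.write_notes_jsonl(result.notes, out_dir / "notes.jsonl")
    result.truth.to_csv(out_dir / "truth.csv", index=False)
    cohort_frame(result.cohort).to_csv(out_dir / "cohort.csv", index=False)
    sio.write_monthly_counts_csv(result.counts, out_dir / "monthly_counts.csv")
    fits_payload = {
        label: dict(entry["fit"].to_dict(), durbin_watson=entry["durbin_watson"])
        for label, entry in result.fits.items()
    }
    (out_dir / "its_fits.json").write_text(
        json.dumps(fits_payload, indent=2), encoding="utf-8")
    pd.DataFrame([c.to_row() for c in result.stats["prevalence"]]).to_csv(
        out_dir / "prevalence_ratios.csv", index=False)
    (out_dir / "survival.json").write_text(
        json.dumps(result.stats["survival"], indent=2), encoding="utf-8")
    per_hosp = result.sensitivity["per_hospital"]
    sens_payload = {
        "claims_only": {
            "n": result.sensitivity["claims_only"]["n"],
            "fit": (result.sensitivity["claims_only"]["fit"].to_dict()
                    if result.sensitivity["claims_only"]["fit"] else None),
        },
        "completeness_adjusted":
            result.sensitivity["completeness_adjusted"]["fit"].to_dict(),
        "per_hospital": {
            "significant_alpha2": per_hosp.significant_hospitals(),
            "fits": {h: f.to_dict() for h, f in per_hosp.fits.items()},
            "skipped": per_hosp.skipped,
        },
        "stage_counts": result.stage_counts,
    }
    (out_dir / "sensitivity_report.json").write_text(
        json.dumps(sens_payload, indent=2), encoding="utf-8")
    manifest = {
        "stage_counts": result.stage_counts,
        "files": {
            p.name: sio.sha256_of(p)
            for p in sorted(out_dir.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2), encoding="utf-8")
    return manifest
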