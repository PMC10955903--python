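#!/usr/bin/env python
"""Probe the robustness of the trend-variation estimate four ways.

(i) claims-only classification from ICD-10 self-harm codes (X60-X84);
(ii) the rule-only mention classifier (the main pipeline's default policy,
reported for completeness); (iii) completeness adjustment of the monthly
counts; (iv) independent per-hospital fits.  Writes
sensitivity_report.json under results/demo/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from sasurv import io as sio
from sasurv.cohort import build_cohort, deduplicate, monthly_counts
from sasurv.its import fit_its
from sasurv.sensitivity import (classify_stay_claims, completeness_adjust,
                                measure_completeness, per_hospital_analysis)
from sasurv.series import MonthlySeries, n_study_months
from sasurv.types import StayClassification

OUT = Path(__file__).resolve().parent.parent / "results" / "demo"


def main() -> None:
    stays = sio.read_stays_csv(OUT / "stays.csv")
    notes = sio.read_notes_jsonl(OUT / "notes.jsonl")
    counts = pd.read_csv(OUT / "monthly_counts.csv")
    report = {}

    # (i) claims-only classifier
    claims_cls = {
        s.stay_id: StayClassification(
            stay_id=s.stay_id, screened=True,
            sa_caused=classify_stay_claims(s), classifier_id="claims-only")
        for s in stays}
    claims_cohort = deduplicate(build_cohort(stays, claims_cls, {}))
    claims_fit = fit_its(monthly_counts(claims_cohort, "overall")[0])
    lo, hi = claims_fit.conf_int["alpha2"]
    print(f"(i)   claims-only: {len(claims_cohort)} stays, trend variation "
          f"{claims_fit.alpha2:.2f} (95%CI {lo:.2f}-{hi:.2f})")
    report["claims_only"] = {"n": len(claims_cohort),
                             "fit": claims_fit.to_dict()}

    # (ii) rule-only classifier = the main pipeline policy
    main_fits = json.loads((OUT / "its_fits.json").read_text())
    report["rule_only"] = {
        "note": "identical to the main analysis: the default mention "
                "classifier is the rule-based policy",
        "alpha2": main_fits["overall"]["params"]["alpha2"],
    }
    print(f"(ii)  rule-only classifier is the main analysis "
          f"(trend variation {report['rule_only']['alpha2']:.2f})")

    # (iii) completeness adjustment
    overall_tab = counts[counts.stratum == "overall"].sort_values("month_index")
    overall = MonthlySeries(counts=overall_tab["count"].to_numpy())
    comp = (measure_completeness(stays, notes, n_months=n_study_months())
            .set_index("month_index")["completeness"]
            .reindex(range(len(overall))).fillna(1.0).to_numpy())
    adj_fit = fit_its(completeness_adjust(overall, comp))
    lo, hi = adj_fit.conf_int["alpha2"]
    print(f"(iii) completeness-adjusted (mean completeness {comp.mean():.3f}): "
          f"trend variation {adj_fit.alpha2:.2f} (95%CI {lo:.2f}-{hi:.2f})")
    report["completeness_adjusted"] = {"mean_completeness": float(comp.mean()),
                                       "fit": adj_fit.to_dict()}

    # (iv) per-hospital fits from the stored per-hospital series
    hosp_fits = {}
    for stratum, sub in counts[counts.stratum.str.startswith("H")].groupby("stratum"):
        series = MonthlySeries(
            counts=sub.sort_values("month_index")["count"].to_numpy(),
            stratum=stratum)
        hosp_fits[stratum] = fit_its(series)
    significant = [h for h, f in hosp_fits.items()
                   if f.conf_int["alpha2"][0] > 0 or f.conf_int["alpha2"][1] < 0]
    print(f"(iv)  per-hospital: slope-change CI excludes zero in "
          f"{len(significant)} of {len(hosp_fits)} hospitals")
    report["per_hospital"] = {
        "significant_alpha2": significant,
        "fits": {h: f.to_dict() for h, f in hosp_fits.items()},
    }

    (OUT / "sensitivity_report.json").write_text(json.dumps(report, indent=2))
    print(f"wrote sensitivity report to {OUT}")


if __name__ == "__main__":
    main()
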