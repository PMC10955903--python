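#!/usr/bin/env python
"""Build the analysis cohort and the stratified monthly count series.

Applies the inclusion rules (SA-classified, age >= 8, admission inside the
study window), collapses within-patient repeats inside 15 days, and writes
cohort.csv plus zero-filled monthly_counts.csv (overall, sex x age band and
per-hospital strata) under results/demo/.
"""

import json
from pathlib import Path

import pandas as pd

from sasurv import io as sio
from sasurv.cohort import build_cohort, cohort_frame, deduplicate, monthly_counts
from sasurv.types import RiskFactorFlags, StayClassification

OUT = Path(__file__).resolve().parent.parent / "results" / "demo"


def load_classifications():
    classifications, flags = {}, {}
    with open(OUT / "classifications.jsonl", encoding="utf-8") as fh:
        for line in fh:
            obj = json.loads(line)
            classifications[obj["stay_id"]] = StayClassification(
                stay_id=obj["stay_id"], screened=obj["screened"],
                sa_caused=obj["sa_caused"], classifier_id=obj["classifier_id"])
            if obj["risk_factors"]:
                flags[obj["stay_id"]] = RiskFactorFlags(**obj["risk_factors"])
    return classifications, flags


def main() -> None:
    stays = sio.read_stays_csv(OUT / "stays.csv")
    classifications, flags = load_classifications()

    included = build_cohort(stays, classifications, flags)
    cohort = deduplicate(included)
    cohort_frame(cohort).to_csv(OUT / "cohort.csv", index=False)

    series = (monthly_counts(cohort, "overall")
              + monthly_counts(cohort, "sex_age")
              + monthly_counts(cohort, "hospital"))
    sio.write_monthly_counts_csv(series, OUT / "monthly_counts.csv")

    frame = cohort_frame(cohort)
    pre = (frame.month_index < 31).sum()
    post = (frame.month_index >= 31).sum()
    print(f"included {len(included)} SA stays; {len(cohort)} after the "
          f"15-day deduplication ({len(included) - len(cohort)} collapsed)")
    print(f"pre-breakpoint {pre} ({100 * pre / len(cohort):.1f}%), "
          f"post-breakpoint {post} ({100 * post / len(cohort):.1f}%)")
    female = (frame.sex == "female").sum()
    print(f"female share: {100 * female / len(cohort):.1f}%")
    print(f"wrote cohort and monthly counts to {OUT}")


if __name__ == "__main__":
    main()
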