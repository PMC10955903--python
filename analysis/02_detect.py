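#!/usr/bin/env python
"""Run the two-stage NLP detection over the corpus and validate it.

Screens every note for suicide-attempt keywords, classifies each screened
stay from its last-edited discharge summary, detects the five risk factors,
and scores the classifier against the generator's truth table (PPV with a
Wilson 95% CI, as one would score a chart review).  Writes
classifications.jsonl and validation.json under results/demo/.
"""

import json
from pathlib import Path

import pandas as pd

from sasurv import io as sio
from sasurv.pipeline import detect_stage
from sasurv.stats import evaluate_ppv

OUT = Path(__file__).resolve().parent.parent / "results" / "demo"


def main() -> None:
    stays = sio.read_stays_csv(OUT / "stays.csv")
    notes = sio.read_notes_jsonl(OUT / "notes.jsonl")
    truth = pd.read_csv(OUT / "truth.csv").set_index("stay_id")

    classifications, rf_flags = detect_stage(stays, notes)
    with open(OUT / "classifications.jsonl", "w", encoding="utf-8") as fh:
        for cls in classifications.values():
            fh.write(json.dumps({
                "stay_id": cls.stay_id, "screened": cls.screened,
                "sa_caused": cls.sa_caused, "classifier_id": cls.classifier_id,
                "risk_factors": (rf_flags[cls.stay_id].as_dict()
                                 if cls.stay_id in rf_flags else None),
            }) + "\n")

    n_screened = sum(c.screened for c in classifications.values())
    positives = [sid for sid, c in classifications.items() if c.sa_caused]
    tp = int(truth.loc[positives, "true_sa"].sum())
    fn = int(truth.true_sa.sum()) - tp
    ppv = evaluate_ppv(tp, len(positives))
    print(f"screened {n_screened} of {len(stays)} stays; "
          f"classified {len(positives)} as SA-caused")
    print(f"against truth: PPV {ppv.ppv:.4f} "
          f"(Wilson 95% CI {ppv.ci[0]:.4f}-{ppv.ci[1]:.4f}); "
          f"{fn} missed (all lacking a discharge summary)")

    validation = {
        "n_stays": len(stays), "screened": n_screened,
        "classified_sa": len(positives), "true_positives": tp,
        "false_negatives": fn,
        "ppv": ppv.ppv, "ppv_ci": list(ppv.ci),
    }
    (OUT / "validation.json").write_text(json.dumps(validation, indent=2))
    print(f"wrote classifications and validation to {OUT}")


if __name__ == "__main__":
    main()
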