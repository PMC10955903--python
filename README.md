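# sasurv — suicide-attempt hospitalisation surveillance from EHR text

`sasurv` is a reusable pipeline for a public-mental-health surveillance
question: did the monthly number of hospitalisations caused by suicide
attempts (SA) accelerate after a crisis, and did the risk factors reported
in clinical notes shift with it?  It targets the setting where the answer
must be read out of multi-hospital electronic health records — millions of
free-text notes plus administrative and claims data — with rule-based
clinical NLP, and where the epidemiological analysis is a seasonally
adjusted interrupted time series.

Real clinical data warehouses of this kind are access-restricted, so the
package ships a synthetic multi-hospital EHR generator with the same
statistical structure, and every stage of the pipeline is tested against
that generator's ground truth.

## What it computes

* **Detection** (`sasurv.nlp`, `sasurv.risk_factors`): keyword screening of
  all notes; mention extraction + qualification (negation, family member,
  patient history, hypothesis, reported speech) on the last-edited
  discharge summary; a stay is SA-caused iff ≥ 1 unqualified mention
  remains.  Risk factors (social isolation, domestic/sexual/physical
  violence, personal SA history) are detected the same way, with SA history
  exempt from the history qualifier.  The mention classifier is pluggable.
* **Cohort** (`sasurv.cohort`): age ≥ 8, admission inside the study window,
  15-day within-patient deduplication, censored length of stay, zero-filled
  monthly count series per stratum.
* **Interrupted time series** (`sasurv.its`): OLS fit of

      N_T = α0 + α1·T + α2·(T − T̃)·1{T ≥ T̃} + Σ_m β_m·1{month(T) = m} + e_T

  with T a running month counter, breakpoint T̃ = March 2020, calendar-month
  adjustment, and 95% CIs of ± 1.96·SE.  α2 is the post-breakpoint change
  in slope (counts/month per month).
* **Statistics** (`sasurv.stats`): pre/post prevalence ratios with
  log-normal CIs and Fisher exact tests, Wilson intervals for PPV,
  positive/negative specific agreement, Kaplan–Meier + log-rank for length
  of stay and death.
* **Sensitivity** (`sasurv.sensitivity`): claims-only classification
  (ICD-10 X60–X84), rule-only classification, completeness adjustment of
  monthly counts, per-hospital fits.
* **Synthetic EHR** (`sasurv.synthetic`): configurable multi-hospital
  corpus — per-stratum segmented-trend series, templated discharge
  summaries embedding keywords under chosen qualification contexts,
  per-hospital-month completeness, claim-code sensitivity, deliberate
  within-15-day duplicates — with a full truth table.

See `docs/methods.md` for the model details and design choices.

## Worked example

The numbered scripts under `analysis/` run the whole study on the reference
synthetic corpus (15 hospitals, August 2017 – June 2022, ~50k stays) and
write their tables under `results/demo/`:

```sh
python analysis/01_simulate.py
python analysis/02_detect.py
python analysis/03_cohort.py
python analysis/04_fit_trends.py
python analysis/05_risk_factors_survival.py
python analysis/06_sensitivity.py
```

Output of the run at the default seed:

```
corpus: 49745 stays in 15 hospitals, 93379 notes
true SA stays: 13836 (27.8% of stays); 537 deliberate within-15-day duplicates
screened 15580 of 49745 stays; classified 13559 as SA-caused
against truth: PPV 1.0000 (Wilson 95% CI 0.9997-1.0000); 277 missed (all lacking a discharge summary)
included 13559 SA stays; 13041 after the 15-day deduplication (518 collapsed)
pre-breakpoint 5493 (42.1%), post-breakpoint 7548 (57.9%)
female share: 64.3%
   female_8-17: trend variation   1.63 (95%CI   1.24 to   2.01)*
       overall: trend variation   4.30 (95%CI   3.52 to   5.07)*
   sexual_violence: 0.04 -> 0.07, PR 1.58 (95%CI 1.36-1.83), p=5.1e-10
log-rank (length_of_stay): statistic 147.65, p=5.7e-34
(i)   claims-only: 11513 stays, trend variation 3.83 (95%CI 3.17-4.48)
(iii) completeness-adjusted (mean completeness 0.980): trend variation 4.37 (95%CI 3.59-5.15)
```

Reading this: the detector recovers the planted SA stays exactly (its only
misses are stays the generator left without a discharge summary); the
fitted slope change on the overall series is positive with a CI far from
zero (the generating strata sum to 3.6, and one realisation's estimate of
4.30 sits within its own CI of that truth); the girls-aged-8–17 stratum
carries the largest per-stratum change (truth 1.8); and the planted
post-breakpoint rise in reported sexual violence (0.04 → 0.07, true ratio
1.75) is picked up with a prevalence-ratio CI excluding 1.  The same
pipeline is exposed as a CLI (`sasurv simulate|detect|all ...`) for running
against stay/note tables produced elsewhere.

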