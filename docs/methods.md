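# Methods

`sasurv` implements a hospital-surveillance analysis of suicidality: detect
suicide-attempt (SA) hospitalisations and their reported risk factors in
clinical free text, assemble a monthly event series, and test whether the
series' slope changed after a fixed breakpoint (the COVID-19 outbreak,
March 2020).  Because the clinical data warehouses this kind of system runs
on are access-restricted, the package ships a synthetic multi-hospital EHR
generator that reproduces the statistical structure the analysis assumes;
every stage is validated against the generator's ground truth.

## Detection model

Detection is two-stage:

1. **Screening.**  Every note of every stay, regardless of type, is matched
   against a keyword dictionary of SA surface forms grouped by modality
   (jump from height, intentional drug overdose, phlebotomy, hanging,
   firearm, drowning, other).  Matching is case- and accent-insensitive with
   word boundaries; patterns are regular-expression fragments so
   orthographic variants can be folded into one entry.  A stay is screened
   iff any note contains any keyword.
2. **Classification.**  Only the last-edited discharge summary of a screened
   stay is considered (ties broken by note id).  Keyword matches become
   mention annotations (non-overlapping, longest-match-wins; spans index the
   original text, so `text[start:end]` always equals the matched surface).
   Each mention is then *qualified* against five trigger lexicons: negation,
   relative to a family member, relative to the patient's history,
   hypothesis, and reported speech.  A trigger fires when its token sequence
   occurs within a scope window of 8 tokens on its declared side of the
   mention (pre-only for negation/hypothesis/reported speech, pre-or-post
   for family/history), with no intervening sentence boundary
   (`. ! ? ; \n`) or adversative conjunction (but/however/although and
   French equivalents).  A mention with no qualifier is *valid*; a stay is
   SA-caused iff at least one mention is valid.

The mention verdict is pluggable: `classify_stay` accepts any callable
`(text, mention) -> bool`, so a learned classifier can replace the rule
policy without touching the rest of the pipeline.  The default — and the
only classifier shipped — is the rule policy above.

Accent folding is strictly one character to one character (é→e, ç→c);
ligatures with multi-character decompositions (œ) are left unfolded so that
folded-text offsets are valid offsets into the original note.

Risk factors (social isolation, domestic violence, sexual violence,
physical violence, personal SA history) are detected in the same summary
with per-factor keyword lexicons sharing the qualifier machinery.  The SA
history factor ignores the *history* qualifier: the factor is historical by
definition, so "previous suicide attempt in 2015" must count.  Negation,
family, hypothesis and reported speech still invalidate it.

The shipped lexicons (two parallel banks, an English-like default and a
minimal French one exercising identical span/qualifier geometry) are
editable CSVs and are deliberately small: they are a documented,
reproducible stand-in for a clinically curated terminology, and every
performance claim in the test suite is made against synthetic ground truth,
never against real-world figures.

## Cohort rules

A stay enters the cohort iff it is classified SA-caused, the patient was at
least 8 years old at admission, and admission falls inside the study window
(August 2017 – June 2022 in the reference configuration; the window's
nominal end of "June 31st" is normalised to June 30).  Length of stay is
discharge − admission in whole days; stays not terminated at the extraction
date (2022-07-04) contribute a censored lower bound.  Repeat SA stays of
one patient within 15 days are collapsed to the first occurrence, with
chain semantics: each candidate is compared with the most recent *retained*
stay of that patient, measured admission-to-admission, which makes the
operation idempotent.  (The wording "within a period of 15 days" is
ambiguous; an admission-to-discharge variant sits behind
`deduplicate(..., anchor="discharge")`.)  Events are assigned to the month
of admission, since the admission is the event caused by the attempt.
Age bands are closed: [8,17], [18,25], [26,65], [66,∞).

## Interrupted time-series model

Monthly counts `N_T` (T = months since the study start) are fitted by
ordinary least squares to

    N_T = a0 + a1*T + a2*max(T - Tb, 0) + sum_m b_m * 1{month(T) = m} + e_T

with Tb fixed at March 2020 (T = 31).  `a1` is the long-term trend in
counts/month, `a2` the post-breakpoint trend variation (post slope =
a1 + a2); the slope-change regressor is zero at the breakpoint month
itself.  An intercept plus all 12 month indicators is rank-deficient, so
the series' first calendar month (August) is the reference and is absorbed
into `a0`; `a1` and `a2` are invariant to that choice, and `a0` is the
level at T = 0 in the reference month.  95% CIs are estimate ± 1.96·SE with
classical OLS standard errors; Newey–West (HAC) errors are available behind
`fit_its(..., robust="HAC")` for sensitivity.  Fitting requires at least 26
months (14 parameters).  `residual_diagnostics` reports the residual
series, the Durbin–Watson statistic and the lag-1 autocorrelation without
taking any automatic decision.

## Epidemiological statistics

* **Prevalence ratio** (post vs pre prevalence of a risk factor among SA
  stays): PR = (a2/n2)/(a1/n1) with log-normal CI
  `exp(ln PR ± z·sqrt(1/a2 − 1/n2 + 1/a1 − 1/n1))`; association tested by
  the two-sided Fisher exact test under the probability-mass convention
  (tables with hypergeometric probability ≤ the observed one).  Zero
  pre-period positives leave the ratio undefined (returned as absent with a
  warning); a zero margin gives p = 1 by convention.
* **PPV validation**: Wilson score 95% intervals on chart-review samples.
* **Inter-annotator agreement**: positive/negative specific agreement,
  2a/(2a+b+c) and 2d/(2d+b+c), with unobservable components returned as
  absent.
* **Length of stay and death**: Kaplan–Meier curves with censoring at
  extraction, compared by the log-rank test (chi-square, groups − 1 df).

All tests are two-sided at the 0.05 level; no multiplicity correction is
applied, matching the analysis design this package reproduces.

## Synthetic data generator

`generate_cohort` draws, for each sex × age-band stratum, a monthly count
series from the segmented seasonal mean under a chosen noise model, then
materialises each count as a hospital stay with notes:

* **Noise.**  Default is Gaussian with per-stratum scale, rounded to the
  nearest nonnegative integer — the fitting model is OLS, so Gaussian
  errors make the recovery studies exact in expectation.  A Poisson option
  exists for realism (negative means truncated at zero with a warning).
* **Stratum parameters.**  Defaults are the reference surveillance values:
  levels 6.0/6.5/39.7/10.2 (male 8–17/18–25/26–65/66+) and
  23.2/13.5/44.8/14.0 (female), trends 0.1/0.1/0.3/−0.1 and
  0.1/0.2/0.7/0.1, trend variations 0.1/0.1/0.3/0.3 and 1.8/1.1/−0.2/0.1,
  breakpoint at month 31 of 59.  The residual noise scale of the real
  series is unknown and is a free parameter: the defaults are 6
  counts/month for the two 8–17 strata and sqrt(level) elsewhere.  Note the
  printed overall trend-variation CI halfwidth (≈1.6) implies a residual SD
  near 26, larger than the conventional σ = 15 used for the overall-series
  recovery studies; where a test depends on hospital-level power (the
  power-dilution check) the hospital noise is set to 6 counts/month so the
  pooled SD (≈23) is consistent with that implied uncertainty.
* **Notes.**  Each stay receives a discharge summary with probability equal
  to the per-hospital-month completeness (default 0.98), assembled from a
  template bank keyed by qualification context; every requested mention
  appears exactly once inside its requested context.  True SA stays embed
  an affirmed SA keyword plus risk-factor sentences drawn at the configured
  pre/post prevalences (defaults: isolation 0.06→0.08, domestic 0.06→0.08,
  sexual 0.04→0.07, physical 0.02→0.03, SA history 0.36→0.40).  Background
  stays (default 2.7 per SA stay, yielding a ~50k-stay desk-scale corpus;
  the field-realistic ratio would be ~200:1) carry filler text, except a
  configurable fraction (default 5%) embedding an SA keyword under a
  non-affirmed context to exercise the qualifier rules.  10% of summaries
  are preceded by an earlier-edited draft to exercise last-edited
  selection, and 80% of stays get an admission note (of type "other") so
  screening genuinely runs on multi-note stays.
* **Claim codes.**  True SA stays receive an ICD-10 X60–X84 code with
  probability 0.85; background stays with probability 0.002 — so the
  claims-only and NLP classifiers disagree on an auditable subset.
* **Dedup targets.**  4% of SA events spawn a deliberate duplicate stay of
  the same patient 1–14 days later; the intended post-dedup counts equal
  the drawn series because patient reuse otherwise keeps admissions ≥17
  days apart.  15% of SA events reuse an existing patient, giving roughly
  1.2 stays per individual.
* **Outcomes.**  Length of stay is log-normal (median 6 days pre, 5 post,
  σ_log = 0.8); in-stay death probability 1.5% pre, 1.0% post.

Everything is drawn from one `numpy` generator seeded by the config, so
identical configurations are byte-identical.  What the generator does *not*
emulate: realistic clinical prose (templates are geometric, not
linguistic), out-of-lexicon spelling variation, section structure,
inter-hospital heterogeneity in coding or completeness practice, and
calendar effects beyond the additive month terms.  Passing round-trip tests
therefore demonstrates the internal consistency of the pipeline — that the
rules recover exactly what the generator planted — not field performance on
real notes, which can only be estimated by chart review.

## Problem sizes used by the checks

The replicate recovery studies fit 200 series of 59 months per
parameterisation (Monte-Carlo error of the mean ≈ 0.03 counts/month/month
for the overall setting).  The reference end-to-end corpus is ~50k stays /
~93k notes, chosen so the whole simulate→detect→cohort→fit chain stays
comfortably within a desk-scale run while keeping every monthly count in a
regime where the OLS normal approximation is sound.  The log-rank type-I
check uses 1,500 null replicates with a 3σ binomial band; the Wilson
coverage check uses 10,000 binomial draws.

## Known limitations

* The lexicons and templates are co-designed; detection metrics on this
  corpus are upper bounds by construction.
* The claims-code block X60–X84 is a conventional choice for intentional
  self-harm; real claims practice varies by site.
* OLS with ±1.96·SE ignores residual autocorrelation; the HAC option is a
  partial remedy, and count models (Poisson/negative binomial GLM) are
  deliberately out of scope.
* Stay-classification consults the discharge summary only; a config switch
  (`screened` override) exists but no alternative document policy ships.
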