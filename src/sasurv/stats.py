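"""Contingency, validation and survival statistics for the surveillance study.

* prevalence ratios between the pre- and post-breakpoint periods with
  log-normal (independent-samples) 95% CIs and two-sided Fisher exact tests;
* Wilson score intervals for positive predictive values from chart review;
* positive/negative specific agreement for inter-annotator comparison;
* Kaplan–Meier curves and log-rank tests for (censored) length of stay.

Conventions: all tests are two-sided; the Fisher two-sided p-value follows
the probability-mass convention (sum of hypergeometric probabilities not
exceeding the observed table's); no multiplicity correction is applied.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

logger = logging.getLogger(__name__)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table of nonnegative counts.

    A table with a zero margin carries no information; p = 1.0 by convention.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of nonnegative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        logger.info("degenerate 2x2 table with a zero margin: p = 1.0")
        return 1.0
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


@dataclass
class PrevalenceComparison:
    factor: str
    group: str
    a1: int
    n1: int
    a2: int
    n2: int
    prevalence_pre: float
    prevalence_post: float
    pr: float | None
    ci: tuple[float, float] | None
    fisher_p: float

    def to_row(self) -> dict:
        return {
            "factor": self.factor, "group": self.group,
            "pre_positives": self.a1, "pre_total": self.n1,
            "post_positives": self.a2, "post_total": self.n2,
            "prevalence_pre": self.prevalence_pre,
            "prevalence_post": self.prevalence_post,
            "prevalence_ratio": self.pr,
            "ci_low": self.ci[0] if self.ci else None,
            "ci_high": self.ci[1] if self.ci else None,
            "fisher_p": self.fisher_p,
        }


def prevalence_ratio(a1: int, n1: int, a2: int, n2: int,
                     conf: float = 0.95,
                     factor: str = "", group: str = "") -> PrevalenceComparison:
    """Post/pre prevalence ratio with log-normal CI and Fisher exact p.

    PR = (a2/n2)/(a1/n1); CI = exp(ln PR ± z·sqrt(1/a2 − 1/n2 + 1/a1 − 1/n1)).
    When a1 = 0 the ratio is undefined and returned as None with a warning.
    """
    for a, n in ((a1, n1), (a2, n2)):
        if not (0 <= a <= n) or n < 1:
            raise ValueError("need 0 <= positives <= total, total >= 1")
    p1, p2 = a1 / n1, a2 / n2
    fisher_p = fisher_exact_2x2([[a2, n2 - a2], [a1, n1 - a1]])
    if a1 == 0:
        logger.warning("prevalence ratio undefined: no pre-period positives")
        return PrevalenceComparison(factor, group, a1, n1, a2, n2, p1, p2,
                                    None, None, fisher_p)
    pr = p2 / p1
    ci = None
    if a2 > 0:
        z = sps.norm.ppf(0.5 + conf / 2)
        se = math.sqrt(1 / a2 - 1 / n2 + 1 / a1 - 1 / n1)
        ci = (pr * math.exp(-z * se), pr * math.exp(z * se))
    return PrevalenceComparison(factor, group, a1, n1, a2, n2, p1, p2,
                                pr, ci, fisher_p)


@dataclass
class PPVEvaluation:
    n_annotated: int
    true_positives: int
    ppv: float
    ci: tuple[float, float]


def wilson_interval(successes: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    lo, hi = proportion_confint(successes, n, alpha=1 - conf, method="wilson")
    return float(lo), float(hi)


def evaluate_ppv(true_positives: int, n_annotated: int,
                 conf: float = 0.95) -> PPVEvaluation:
    """PPV of a detector from a chart-review sample, with Wilson CI."""
    ci = wilson_interval(true_positives, n_annotated, conf)
    return PPVEvaluation(n_annotated, true_positives,
                         true_positives / n_annotated, ci)


def specific_agreement(a: int, b: int, c: int, d: int
                       ) -> tuple[float | None, float | None]:
    """Positive and negative specific agreement between two annotators.

    ``a`` = both positive, ``d`` = both negative, ``b``/``c`` discordant.
    PA = 2a/(2a+b+c), NA = 2d/(2d+b+c); a component whose denominator is 0
    is unobservable and returned as None.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be nonnegative")
    pa = 2 * a / (2 * a + b + c) if 2 * a + b + c > 0 else None
    na = 2 * d / (2 * d + b + c) if 2 * d + b + c > 0 else None
    return pa, na


@dataclass
class SurvivalComparison:
    groups: list[str]
    curves: dict[str, pd.DataFrame]  # columns: time, survival, at_risk
    logrank_statistic: float
    p_value: float


def km_logrank(groups: dict[str, tuple[np.ndarray, np.ndarray]]
               ) -> SurvivalComparison:
    """Kaplan–Meier curves and a log-rank test across >= 2 groups.

    *groups* maps a label to ``(durations_in_days, event_observed)``;
    censored subjects carry ``event_observed = False``.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    curves: dict[str, pd.DataFrame] = {}
    all_dur, all_evt, all_lab = [], [], []
    for label, (durations, events) in groups.items():
        durations = np.asarray(durations, dtype=float)
        events = np.asarray(events, dtype=bool)
        if durations.size == 0:
            raise ValueError(f"group {label!r} has no subjects")
        if (durations <= 0).any():
            raise ValueError(f"group {label!r} has non-positive durations")
        kmf = KaplanMeierFitter()
        kmf.fit(durations, event_observed=events, label=label)
        table = kmf.event_table
        curves[label] = pd.DataFrame({
            "time": kmf.survival_function_.index.to_numpy(),
            "survival": kmf.survival_function_[label].to_numpy(),
            "at_risk": table["at_risk"].reindex(
                kmf.survival_function_.index, method="ffill").to_numpy(),
        })
        all_dur.append(durations)
        all_evt.append(events)
        all_lab.extend([label] * durations.size)
    events = np.concatenate(all_evt)
    if not events.any():
        # no events anywhere: curves stay at 1 and the test is vacuous
        stat, p = 0.0, 1.0
    else:
        res = multivariate_logrank_test(
            np.concatenate(all_dur), np.array(all_lab), events
        )
        stat, p = float(res.test_statistic), float(res.p_value)
    return SurvivalComparison(
        groups=list(groups),
        curves=curves,
        logrank_statistic=stat,
        p_value=p,
    )
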