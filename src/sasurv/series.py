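"""Monthly event-count series, anchored on a calendar start month.

The analysis indexes months with a running counter T (T=0 is the first study
month, August 2017 in the reference configuration) and places the breakpoint
at the pandemic outbreak month (March 2020, T=31 in that configuration).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np

#: reference study window
DEFAULT_STUDY_START = dt.date(2017, 8, 1)
DEFAULT_STUDY_END = dt.date(2022, 6, 30)
DEFAULT_BREAKPOINT = dt.date(2020, 3, 1)
DEFAULT_EXTRACTION_DATE = dt.date(2022, 7, 4)


def month_index(date: dt.date, start: dt.date = DEFAULT_STUDY_START) -> int:
    """Running counter of calendar months since *start* (start month = 0)."""
    return (date.year - start.year) * 12 + (date.month - start.month)


def n_study_months(start: dt.date = DEFAULT_STUDY_START,
                   end: dt.date = DEFAULT_STUDY_END) -> int:
    return month_index(end, start) + 1


@dataclass
class MonthlySeries:
    """Zero-filled, contiguous monthly counts for one stratum."""

    counts: np.ndarray
    stratum: str = "overall"
    breakpoint_index: int = month_index(DEFAULT_BREAKPOINT)
    start: dt.date = DEFAULT_STUDY_START

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if not 0 < self.breakpoint_index < len(self.counts):
            raise ValueError(
                f"breakpoint index {self.breakpoint_index} outside series of "
                f"length {len(self.counts)}"
            )

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def start_month_of_year(self) -> int:
        return self.start.month

    def month_of_year(self) -> np.ndarray:
        """Calendar month (1..12) of every index."""
        return (self.start.month - 1 + np.arange(len(self))) % 12 + 1

    def calendar_labels(self) -> list[str]:
        return [
            f"{self.start.year + (self.start.month - 1 + t) // 12}-"
            f"{(self.start.month - 1 + t) % 12 + 1:02d}"
            for t in range(len(self))
        ]


def its_mean(n_months: int,
             level: float,
             trend: float,
             trend_variation: float,
             breakpoint_index: int,
             seasonal: dict[int, float] | None = None,
             start_month_of_year: int = 8) -> np.ndarray:
    """Closed-form mean of the segmented, seasonally-adjusted count model.

    mu_T = level + trend*T + trend_variation*max(T - Tb, 0)
           + seasonal[month_of_year(T)]

    The slope-change term contributes 0 at the breakpoint month itself and
    (T - Tb) afterwards, so the post-period slope is trend + trend_variation.
    """
    if n_months < 2:
        raise ValueError("need at least two months")
    if not 0 <= breakpoint_index < n_months:
        raise ValueError(f"breakpoint index {breakpoint_index} outside [0, {n_months})")
    t = np.arange(n_months, dtype=float)
    mu = level + trend * t + trend_variation * np.maximum(t - breakpoint_index, 0.0)
    if seasonal:
        months = (start_month_of_year - 1 + np.arange(n_months)) % 12 + 1
        mu += np.array([seasonal.get(int(m), 0.0) for m in months])
    return mu
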