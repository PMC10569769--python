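"""Workload unfairness metric and summary statistics.

A cancer specialty is served by ``m >= 2`` navigators.  In a given week each
navigator ``j`` carries a workload ``L_j`` (an encounter count, or a predicted
count — the metric applies to both).  The *fair share* is the workload each
navigator would carry if the week's total were split evenly, and the
*unfairness* of the week is the mean absolute deviation of the actual loads
from that fair share:

    fair = (1/m) * sum_j L_j
    unfairness = (1/m) * sum_j |L_j - fair|

Unfairness is zero iff all navigators carry equal load, is invariant under
relabelling of navigators, and scales linearly with the loads.

Weekly unfairness series are summarised as mean, sample SD and a 95%
confidence interval of the form ``mean +/- 1.98 * sd / sqrt(n)``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

__all__ = [
    "WeeklyLoadVector",
    "SeriesSummary",
    "fair_share",
    "unfairness",
    "summarize_series",
]

#: Multiplier for the 95% confidence half-width, applied as mult * sd / sqrt(n).
CI_MULTIPLIER = 1.98


@dataclass(frozen=True)
class WeeklyLoadVector:
    """Per-navigator workload totals for one specialty in one week."""

    specialty_id: str
    week_index: int
    loads: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "loads", tuple(float(x) for x in self.loads))
        if len(self.loads) < 2:
            raise ValueError(
                f"specialty {self.specialty_id!r}: need >= 2 navigators, got {len(self.loads)}"
            )
        if self.week_index < 0:
            raise ValueError("week_index must be >= 0")
        if any(x < 0 for x in self.loads):
            raise ValueError("workloads cannot be negative")


@dataclass(frozen=True)
class SeriesSummary:
    """Mean / SD / 95% CI summary of a weekly unfairness series."""

    mean: float
    sd: float
    n: int
    ci_low: float
    ci_high: float

    def to_dict(self) -> dict:
        return asdict(self)


def _as_loads(loads) -> np.ndarray:
    if isinstance(loads, WeeklyLoadVector):
        arr = np.asarray(loads.loads, dtype=float)
    else:
        arr = np.asarray(list(loads), dtype=float)
    if arr.size == 0:
        raise ValueError("empty load vector: malformed specialty")
    if np.any(arr < 0):
        raise ValueError("workloads cannot be negative")
    return arr


def fair_share(loads) -> float:
    """Equal split of the week's total workload among the navigators."""
    arr = _as_loads(loads)
    return float(arr.mean())


def unfairness(loads) -> float:
    """Mean absolute deviation of per-navigator loads from the fair share.

    Accepts a :class:`WeeklyLoadVector` or any sequence of non-negative
    numbers (length = navigator count).
    """
    arr = _as_loads(loads)
    return float(np.abs(arr - arr.mean()).mean())


def summarize_series(values: Sequence[float]) -> SeriesSummary:
    """Summarise a series of weekly values as mean, sample SD, and 95% CI.

    The CI is ``mean +/- 1.98 * sd / sqrt(n)`` with the sample (n-1
    denominator) SD.  Requires ``n >= 2``.
    """
    arr = np.asarray(list(values), dtype=float)
    n = arr.size
    if n < 2:
        raise ValueError(f"need at least 2 values to summarise, got {n}")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    half = CI_MULTIPLIER * sd / np.sqrt(n)
    return SeriesSummary(mean=mean, sd=sd, n=int(n), ci_low=mean - half, ci_high=mean + half)
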