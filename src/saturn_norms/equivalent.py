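"""Equivalent Scores: a five-level ordinal recoding (ES 0-4) of adjusted scores.

ES 0 collects scores at or beyond the outer tolerance limit (the
pathological range), ES 4 scores better than the sample median, and ES 1-3
split the distance in between on a normal-deviate scale.  The cumulative
rank of each boundary in worst-to-best order is fixed by the sample size
alone:

    c0 = outer tolerance rank                      (ES0 | ES1 boundary)
    c1 = round_half_up(n * Phi(-1.22))             (ES1 | ES2)
    c2 = round_half_up(n * Phi(-0.61))             (ES2 | ES3)
    c3 = floor(n / 2)                              (ES3 | ES4, the median)
    c4 = n

with Phi the standard normal CDF.  The two interior z-constants were chosen
to reproduce the cumulative frequencies (10, 36, 88, 161, 323) that the
reference normative tables print at n = 323; they are an inference from
those tables, not an independently published formula.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

from ._util import round_half_up
from .core import Polarity
from .tolerance import tolerance_ranks, worst_to_best

__all__ = [
    "EquivalentScoreTable",
    "CeilingEffectError",
    "ESPartitionError",
    "es_rank_thresholds",
    "build_es_table",
    "assign_es",
]

_Z_ES1 = -1.22
_Z_ES2 = -0.61


class ESPartitionError(ValueError):
    """The sample is too small for five strictly increasing boundary ranks."""


class CeilingEffectError(ValueError):
    """Too many tied scores at the boundaries (ceiling); classify with
    tolerance limits only."""


@dataclass(frozen=True)
class EquivalentScoreTable:
    measure_id: str
    polarity: Polarity
    n: int
    #: order-statistic values at ranks c0..c3, worst-to-best; None if ceiling
    boundaries: Optional[tuple[float, float, float, float]]
    cumulative_ranks: Optional[tuple[int, int, int, int, int]]
    densities: Optional[tuple[int, int, int, int, int]]
    ceiling: bool = False

    def __post_init__(self) -> None:
        if self.ceiling:
            return
        if self.boundaries is None or self.cumulative_ranks is None:
            raise ValueError("non-ceiling table must carry boundaries and ranks")
        c = self.cumulative_ranks
        if any(a >= b for a, b in zip(c, c[1:])) or c[-1] != self.n:
            raise ValueError("cumulative ranks must strictly increase to n")
        if self.densities is None or sum(self.densities) != self.n:
            raise ValueError("densities must sum to n")
        b = np.asarray(self.boundaries)
        mono = np.all(np.diff(b) >= 0) if self.polarity is Polarity.HIGHER_BETTER else np.all(np.diff(b) <= 0)
        if not mono:
            raise ValueError("boundaries must be monotone in worst-to-best direction")


def es_rank_thresholds(
    n: int, coverage: float = 0.05, confidence: float = 0.95
) -> tuple[int, int, int, int, int]:
    """Cumulative boundary ranks (c0..c4) of the five ES levels at size n."""
    outer, _inner = tolerance_ranks(n, coverage, confidence)
    c1 = int(round_half_up(n * norm.cdf(_Z_ES1)))
    c2 = int(round_half_up(n * norm.cdf(_Z_ES2)))
    c3 = n // 2
    ranks = (outer, c1, c2, c3, n)
    if any(a >= b for a, b in zip(ranks, ranks[1:])):
        raise ESPartitionError(
            f"ES partition infeasible at n={n}: ranks {ranks} not strictly increasing"
        )
    return ranks


def _ceiling(boundaries: Sequence[float]) -> bool:
    """Ceiling rule: three or more consecutive boundary order statistics
    equal (two adjacent equal pairs).  A single tied pair can occur on a
    healthy bounded score and still leaves four distinguishable levels."""
    b = list(boundaries)
    return any(b[i] == b[i + 1] == b[i + 2] for i in range(len(b) - 2))


def build_es_table(
    adjusted_scores: Sequence[float],
    polarity: Polarity,
    thresholds: tuple[int, int, int, int, int],
    measure_id: str = "",
) -> EquivalentScoreTable:
    """Order-statistic boundaries and per-level densities for a sample.

    Boundary values belong to the worse ES (intervals are closed on the
    worse side): for accuracy ES0 is "score <= outer-limit value", for times
    "score >= outer-limit value".  With heavy ties at the top of a bounded
    score the partition degrades to a ceiling-flagged table carrying no ES
    levels; tolerance limits remain usable.
    """
    ordered = worst_to_best(adjusted_scores, polarity)
    n = len(ordered)
    if n != thresholds[-1]:
        raise ValueError(f"{n} scores but thresholds computed for n={thresholds[-1]}")
    boundaries = tuple(float(ordered[c - 1]) for c in thresholds[:4])
    if _ceiling(boundaries):
        return EquivalentScoreTable(
            measure_id=measure_id,
            polarity=polarity,
            n=n,
            boundaries=None,
            cumulative_ranks=None,
            densities=None,
            ceiling=True,
        )
    densities = tuple(
        b - a for a, b in zip((0,) + tuple(thresholds[:4]), thresholds)
    )
    return EquivalentScoreTable(
        measure_id=measure_id,
        polarity=polarity,
        n=n,
        boundaries=boundaries,  # type: ignore[arg-type]
        cumulative_ranks=tuple(thresholds),  # type: ignore[arg-type]
        densities=densities,  # type: ignore[arg-type]
    )


def assign_es(adjusted: float, table: EquivalentScoreTable) -> int:
    """ES level (0-4) of an adjusted score; boundary values take the worse ES."""
    if table.ceiling:
        raise CeilingEffectError(
            f"{table.measure_id or 'measure'}: ES table degraded by ceiling effect; "
            "classify against tolerance limits instead"
        )
    assert table.boundaries is not None
    for level, boundary in enumerate(table.boundaries):
        at_or_worse = (
            adjusted <= boundary
            if table.polarity is Polarity.HIGHER_BETTER
            else adjusted >= boundary
        )
        if at_or_worse:
            return level
    return 4
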