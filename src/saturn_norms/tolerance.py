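"""Exact non-parametric (binomial) one-sided tolerance limits.

For a normative sample of size n, the *outer* tolerance limit is the order
statistic (counted from the worst score) that bounds the population's
``coverage`` tail (default the worst 5%) from below with at least
``confidence`` (default 95%): an examinee at or beyond it is confidently in
the pathological range, so its value is the clinical cut-off.  The *inner*
limit is the order statistic that bounds the same tail from above: scores
beyond it are confidently normal.  Scores between the two limits are
borderline.

Ranks depend only on (n, coverage, confidence).  If the r-th worst
observation is the outer limit, the claim "at least confidence probability
that the population coverage-quantile exceeds it" reads, through the
binomial distribution of how many sample points fall in the tail,

    outer rank = largest r >= 1 with  P[Binomial(n, coverage) >= r] >= confidence
    inner rank = smallest r     with  P[Binomial(n, coverage) <= r - 1] >= confidence

Both tails are summed exactly by an incremental product of binomial terms;
no normal approximation is involved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import Polarity

__all__ = [
    "ToleranceLimits",
    "SampleTooSmallError",
    "tolerance_ranks",
    "tolerance_values",
    "min_n_for_outer_limit",
    "binomial_cdf",
]


class SampleTooSmallError(ValueError):
    """No rank can bound the coverage tail at the requested confidence."""

    def __init__(self, n: int, coverage: float, confidence: float, minimal_n: int):
        self.minimal_n = minimal_n
        super().__init__(
            f"sample too small for outer tolerance limit: n={n} "
            f"(need n >= {minimal_n} at coverage={coverage}, confidence={confidence})"
        )


@dataclass(frozen=True)
class ToleranceLimits:
    n: int
    coverage: float
    confidence: float
    outer_rank: int
    inner_rank: int
    outer_value: float
    inner_value: float
    polarity: Polarity

    def __post_init__(self) -> None:
        if not (1 <= self.outer_rank < self.inner_rank <= self.n):
            raise ValueError(
                f"require outer_rank < inner_rank <= n, got "
                f"{self.outer_rank}, {self.inner_rank}, {self.n}"
            )
        worse_first = (
            self.outer_value <= self.inner_value
            if self.polarity is Polarity.HIGHER_BETTER
            else self.outer_value >= self.inner_value
        )
        if not worse_first:
            raise ValueError("outer value must be at least as bad as inner value")


def binomial_cdf(k: int, n: int, p: float) -> float:
    """P[Binomial(n, p) <= k] by incremental term summation.

    Terms are built multiplicatively from the log-space starting mass
    (1-p)^n, which stays finite for any n met in norming work.
    """
    if k < 0:
        return 0.0
    if k >= n:
        return 1.0
    term = math.exp(n * math.log1p(-p))  # P[X = 0]
    total = term
    ratio = p / (1.0 - p)
    for j in range(k):
        term *= (n - j) / (j + 1) * ratio
        total += term
    return min(total, 1.0)


def min_n_for_outer_limit(coverage: float, confidence: float) -> int:
    """Smallest n for which even the worst observation is a valid outer
    limit: 1 - (1-coverage)^n >= confidence."""
    return math.ceil(math.log1p(-confidence) / math.log1p(-coverage))


def tolerance_ranks(
    n: int, coverage: float = 0.05, confidence: float = 0.95
) -> tuple[int, int]:
    """Outer and inner tolerance-limit ranks in worst-to-best order (1-based).

    Raises
    ------
    SampleTooSmallError
        If no rank satisfies the outer condition (n below the feasibility
        threshold, 59 at the default 5%/95%).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 < coverage < 1.0 and 0.0 < confidence < 1.0):
        raise ValueError("coverage and confidence must lie in (0, 1)")

    # P[X >= r] = 1 - F(r-1) is non-increasing in r; P[X <= r-1] non-decreasing.
    if 1.0 - binomial_cdf(0, n, coverage) < confidence:
        raise SampleTooSmallError(
            n, coverage, confidence, min_n_for_outer_limit(coverage, confidence)
        )
    outer = 1
    r = 2
    while r <= n and 1.0 - binomial_cdf(r - 1, n, coverage) >= confidence:
        outer = r
        r += 1
    inner = outer + 1
    while binomial_cdf(inner - 1, n, coverage) < confidence:
        inner += 1
    return outer, inner


def worst_to_best(scores: Sequence[float], polarity: Polarity) -> np.ndarray:
    """Scores sorted from clinically worst to best (ascending for accuracy,
    descending for times)."""
    arr = np.asarray(scores, dtype=float)
    if np.isnan(arr).any():
        raise ValueError("scores contain missing values")
    arr = np.sort(arr)
    if polarity is Polarity.LOWER_BETTER:
        arr = arr[::-1]
    return arr


def tolerance_values(
    adjusted_scores: Sequence[float],
    ranks: tuple[int, int],
    polarity: Polarity,
    *,
    coverage: float = 0.05,
    confidence: float = 0.95,
) -> ToleranceLimits:
    """Attach adjusted-score values to precomputed tolerance ranks.

    The outer (inner) value is the order statistic at the outer (inner) rank
    in worst-to-best order.  Tied values are reported as the order statistic
    at the position, with no interpolation.
    """
    outer_rank, inner_rank = ranks
    ordered = worst_to_best(adjusted_scores, polarity)
    n = len(ordered)
    if inner_rank > n:
        raise ValueError(
            f"score list of length {n} cannot host inner rank {inner_rank}"
        )
    return ToleranceLimits(
        n=n,
        coverage=coverage,
        confidence=confidence,
        outer_rank=outer_rank,
        inner_rank=inner_rank,
        outer_value=float(ordered[outer_rank - 1]),
        inner_value=float(ordered[inner_rank - 1]),
        polarity=polarity,
    )
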