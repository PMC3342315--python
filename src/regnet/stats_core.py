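"""Statistical kernel shared by all pipeline stages.

Hypergeometric upper tails for gene-set overlaps, one-sided Fisher's exact
test, odds ratios with a zero-cell policy, Pearson's chi-square for 2x2
tables, Benjamini-Hochberg FDR adjustment, and two-sided normal tail
probabilities.  Everything here is a thin, validated layer over scipy so
that every stage tests "at least as extreme" the same way.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats


class DegenerateTableError(ValueError):
    """A 2x2 table has a zero margin and the requested statistic is undefined."""


@dataclass(frozen=True)
class OverlapQuery:
    """Overlap of a K-set and an n-set drawn from an N-universe.

    ``overlap_k`` items are shared; the hypergeometric reference distribution
    is X ~ Hypergeom(N, K, n).
    """

    overlap_k: int
    set_a_size_K: int
    set_b_size_n: int
    universe_N: int

    def __post_init__(self) -> None:
        k, K, n, N = self.overlap_k, self.set_a_size_K, self.set_b_size_n, self.universe_N
        if min(k, K, n, N) < 0:
            raise ValueError("counts must be non-negative")
        if K > N or n > N:
            raise ValueError(f"set sizes K={K}, n={n} exceed universe N={N}")
        if k > min(K, n):
            raise ValueError(f"overlap k={k} exceeds min(K, n)={min(K, n)}")
        if k < max(0, K + n - N):
            raise ValueError(f"overlap k={k} below forced minimum {max(0, K + n - N)}")


@dataclass(frozen=True)
class Table2x2:
    """2x2 contingency table; ``a`` counts both events, ``d`` neither."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.total == 0:
            raise ValueError("table is empty")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class AdjustedPValues:
    """Raw p-values and their BH-adjusted counterparts, in input order."""

    raw: tuple[float, ...]
    adjusted: tuple[float, ...]


def hypergeom_upper_tail(q: OverlapQuery) -> float:
    """Inclusive upper tail P(X >= k) for X ~ Hypergeom(N, K, n).

    The inclusive convention matches R's ``phyper(k - 1, K, N - K, n,
    lower.tail = FALSE)`` and is the probability of observing the same
    number or more overlapping genes by random sampling from the universe.
    """
    p = float(stats.hypergeom.sf(q.overlap_k - 1, q.universe_N, q.set_a_size_K, q.set_b_size_n))
    return min(p, 1.0)


def fisher_one_sided(t: Table2x2) -> float:
    """One-sided Fisher's exact p for positive association (a-cell upper tail).

    Identical to the hypergeometric upper tail of the a-cell given the
    table's margins.
    """
    q = OverlapQuery(
        overlap_k=t.a,
        set_a_size_K=t.a + t.b,
        set_b_size_n=t.a + t.c,
        universe_N=t.total,
    )
    return hypergeom_upper_tail(q)


def odds_ratio(
    t: Table2x2, zero_cell_policy: Literal["haldane", "strict"] = "haldane"
) -> tuple[float, bool]:
    """(a*d)/(b*c), with Haldane-Anscombe +0.5 applied when any cell is zero.

    Returns ``(ratio, corrected)``; ``corrected`` is True when the +0.5
    adjustment was applied.  With ``zero_cell_policy="strict"`` a zero in
    ``b`` or ``c`` raises instead.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if min(a, b, c, d) == 0:
        if zero_cell_policy == "strict":
            if b * c == 0:
                raise ZeroDivisionError("odds ratio undefined: zero in b or c cell")
            return (a * d) / (b * c), False
        if zero_cell_policy != "haldane":
            raise ValueError(f"unknown zero_cell_policy: {zero_cell_policy!r}")
        return ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5)), True
    return (a * d) / (b * c), False


def bh_adjust(pvals: Sequence[float]) -> AdjustedPValues:
    """Benjamini-Hochberg step-up adjustment, preserving input order.

    Ties in the raw p-values are handled by a stable argsort, so the output
    is deterministic and invariant (up to the same permutation) under input
    permutation.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # step-up: running minimum from the largest rank down
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.clip(adj_sorted, 0.0, 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    adjusted = np.maximum(adjusted, p)  # guard float round-off; BH never lowers p
    return AdjustedPValues(raw=tuple(p.tolist()), adjusted=tuple(adjusted.tolist()))


def pearson_chi2_2x2(t: Table2x2, continuity: bool = False) -> tuple[float, float]:
    """Pearson chi-square statistic and df=1 upper-tail p for a 2x2 table.

    ``continuity=True`` applies the Yates correction.  A zero row or column
    margin makes the statistic undefined and raises DegenerateTableError.
    """
    a, b, c, d = (float(x) for x in (t.a, t.b, t.c, t.d))
    n = a + b + c + d
    margins = (a + b, c + d, a + c, b + d)
    if min(margins) == 0:
        raise DegenerateTableError("zero margin in 2x2 table")
    diff = abs(a * d - b * c)
    if continuity:
        diff = max(diff - n / 2.0, 0.0)
    statistic = n * diff**2 / (margins[0] * margins[1] * margins[2] * margins[3])
    p = float(stats.chi2.sf(statistic, df=1))
    return float(statistic), p


def normal_two_sided_p(x: float, mu: float, sigma: float) -> float:
    """Two-sided tail probability of ``x`` under N(mu, sigma^2).

    p = 2 * min(Phi(z), 1 - Phi(z)) with z = (x - mu) / sigma.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    z = abs((x - mu) / sigma)
    return min(2.0 * float(stats.norm.sf(z)), 1.0)


def normal_upper_tail(z: float) -> float:
    """P(Z > z) for standard normal Z (one-sided)."""
    return float(stats.norm.sf(z))
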