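"""The twelve diversity indices for clonotype abundance vectors.

A TCR repertoire is summarized by its clonotype count vector
``x_1, ..., x_S`` (copies per unique rearrangement).  Writing
``N = sum(x_i)`` and ``p_i = x_i / N``, the indices computed here are the
twelve in routine use for repertoire profiling:

=============  ==========================================================
S              richness, the number of unique clonotypes
Chao1          ``S + n1*(n1-1) / (2*(n2+1))`` (bias-corrected form), with
               ``n_i`` the number of clonotypes observed exactly i times
ACE            abundance-based coverage estimator with rare threshold 10
Shannon        ``H = -sum p_i ln p_i``
Inv.Simpson    ``1 / sum p_i^2``  (Hill number of order 2)
Gini.Simpson   ``1 - sum p_i^2``
D3, D4         Hill numbers ``(sum p_i^q)^(1/(1-q))`` at q = 3, 4
Pielou         ``J = H / ln S``
Basharin       ``J' = (H - (S-1)/(2N)) / ln S``
d50            smallest percentage of dominant clonotypes holding >= 50%
               of all copies
Gini           ``sum_ij |p_i - p_j| / (2 S^2 pbar)`` with ``pbar = 1/S``
=============  ==========================================================

Indices that are undefined for a particular vector (Pielou and Basharin at
S = 1, ACE when every rare clonotype is a singleton) are reported with an
explicit status rather than an exception, so that subsampling loops never
abort on degenerate draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "INDEX_NAMES",
    "AbundanceSummary",
    "DiversityVector",
    "summarize_abundance",
    "richness_s",
    "chao1",
    "ace",
    "d50",
    "hill_number",
    "shannon",
    "inv_simpson",
    "gini_simpson",
    "pielou",
    "basharin",
    "gini_coefficient",
    "compute_all",
]

#: Canonical order of the twelve indices in all tabular output.
INDEX_NAMES = (
    "S",
    "Chao1",
    "ACE",
    "Shannon",
    "Inv.Simpson",
    "Gini.Simpson",
    "D3",
    "D4",
    "Pielou",
    "Basharin",
    "d50",
    "Gini",
)

OK = "ok"
UNDEFINED = "undefined"
FALLBACK = "fallback"


@dataclass(frozen=True)
class AbundanceSummary:
    """Shared substrate of the index formulas.

    Attributes
    ----------
    counts : ndarray
        Clonotype copy numbers, each >= 1 (float64; exact for all realistic
        magnitudes, and the formulas only use relative abundances plus the
        small-count buckets ``n_i``).
    S : int
        Number of unique clonotypes.
    N : float
        Total number of copies.
    freq_of_freqs : mapping
        ``i -> n_i``: number of clonotypes with exactly ``i`` copies, for
        the small ``i`` needed by Chao1/ACE.
    p : ndarray
        Relative abundances ``counts / N``.
    """

    counts: np.ndarray
    S: int
    N: float
    freq_of_freqs: Mapping[int, int]
    p: np.ndarray = field(repr=False)

    def n(self, i: int) -> int:
        """Number of clonotypes observed exactly ``i`` times."""
        return self.freq_of_freqs.get(i, 0)


def _as_counts(counts: Iterable[float]) -> np.ndarray:
    x = np.asarray(list(counts) if not isinstance(counts, np.ndarray) else counts,
                   dtype=np.float64)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("counts must be a non-empty 1-D vector")
    if np.any(x < 1):
        raise ValueError("all clonotype counts must be >= 1")
    return x


def summarize_abundance(counts: Iterable[float]) -> AbundanceSummary:
    """Build the :class:`AbundanceSummary` for a count vector."""
    x = _as_counts(counts)
    N = float(x.sum())
    S = int(x.size)
    # frequency-of-frequencies only needed for small i (<= ACE threshold);
    # collect it for counts up to 1000 to stay exact for any sane threshold.
    small = x[x <= 1000]
    vals, reps = np.unique(small.astype(np.int64), return_counts=True)
    fof = {int(v): int(r) for v, r in zip(vals, reps)}
    return AbundanceSummary(counts=x, S=S, N=N, freq_of_freqs=fof, p=x / N)


# ---------------------------------------------------------------------------
# individual indices
# ---------------------------------------------------------------------------

def richness_s(a: AbundanceSummary) -> float:
    """Richness: the number of unique clonotypes."""
    return float(a.S)


def chao1(a: AbundanceSummary) -> float:
    """Chao1 richness estimator, bias-corrected form.

    Defined for every vector (the ``n2 + 1`` denominator never vanishes)
    and always >= S.
    """
    n1, n2 = a.n(1), a.n(2)
    return a.S + n1 * (n1 - 1) / (2.0 * (n2 + 1))


def ace(a: AbundanceSummary, rare_threshold: int = 10) -> tuple[float, str]:
    """ACE richness estimator.

    Splits clonotypes at ``rare_threshold`` copies into rare
    (1..threshold) and abundant (> threshold) groups; estimates coverage
    ``C = 1 - n1/N_rare`` from the rare group and corrects with the
    squared coefficient of variation

    ``gamma^2 = max(S_rare * sum_{i<=t} i(i-1) n_i / (C N_rare (N_rare-1)) - 1, 0)``.

    Returns ``(value, status)``.  When there are no rare clonotypes the
    estimator falls back to ``S_abund`` (= S); when every rare clonotype is
    a singleton the coverage is zero and the value is undefined.
    """
    rare = a.counts[a.counts <= rare_threshold]
    s_abund = int(np.sum(a.counts > rare_threshold))
    s_rare = int(rare.size)
    if s_rare == 0:
        return float(s_abund), FALLBACK
    n_rare = float(rare.sum())
    n1 = a.n(1)
    c_ace = 1.0 - n1 / n_rare
    if c_ace == 0.0:
        return math.nan, UNDEFINED
    ssum = sum(i * (i - 1) * a.n(i) for i in range(1, rare_threshold + 1))
    if n_rare > 1:
        gamma2 = max(s_rare * ssum / (c_ace * n_rare * (n_rare - 1)) - 1.0, 0.0)
    else:  # single rare clonotype with >1 copies: no dispersion information
        gamma2 = 0.0
    return s_abund + s_rare / c_ace + (n1 / c_ace) * gamma2, OK


def d50(counts: Iterable[float], as_fraction: bool = False) -> float:
    """Smallest percentage of dominant clonotypes holding >= half the copies.

    Counts are sorted descending; ``k`` is the shortest prefix whose sum
    reaches ``N/2``; the result is ``100 * k / S`` (or ``k/S`` when
    ``as_fraction``).  Equal counts are interchangeable, so the value does
    not depend on their ordering.
    """
    x = _as_counts(counts)
    order = np.sort(x)[::-1]
    csum = np.cumsum(order)
    k = int(np.searchsorted(csum, csum[-1] / 2.0, side="left")) + 1
    frac = k / x.size
    return frac if as_fraction else 100.0 * frac


def _sum_pq(p: np.ndarray, q: float) -> float:
    # compensated summation: p_i^q spans many orders of magnitude at S ~ 1e6
    return math.fsum(np.power(p, q).tolist())


def hill_number(a: AbundanceSummary, q: float) -> float:
    """Hill number (effective number of clonotypes) of order ``q != 1``."""
    if q == 1:
        raise ValueError("q = 1 is the Shannon limit; use exp(shannon(a))")
    if q < 0:
        raise ValueError("q must be >= 0")
    return _sum_pq(a.p, q) ** (1.0 / (1.0 - q))


def shannon(a: AbundanceSummary) -> float:
    """Shannon entropy ``H = -sum p_i ln p_i`` (natural log)."""
    p = a.p
    return -math.fsum((p * np.log(p)).tolist())


def inv_simpson(a: AbundanceSummary) -> float:
    """Inverse Simpson index ``1 / sum p_i^2`` (Hill number at q = 2)."""
    return 1.0 / _sum_pq(a.p, 2.0)


def gini_simpson(a: AbundanceSummary) -> float:
    """Gini-Simpson index ``1 - sum p_i^2``: probability that two randomly
    drawn copies belong to different clonotypes."""
    return 1.0 - _sum_pq(a.p, 2.0)


def pielou(a: AbundanceSummary) -> tuple[float, str]:
    """Pielou evenness ``J = H / ln S``; undefined at S = 1."""
    if a.S < 2:
        return math.nan, UNDEFINED
    return shannon(a) / math.log(a.S), OK


def basharin(a: AbundanceSummary) -> tuple[float, str]:
    """Basharin's bias-adjusted evenness ``(H - (S-1)/(2N)) / ln S``.

    The only index here that uses the total count N, so unlike the others
    it is *not* invariant to multiplying every count by a constant.
    Undefined at S = 1.
    """
    if a.S < 2:
        return math.nan, UNDEFINED
    return (shannon(a) - (a.S - 1) / (2.0 * a.N)) / math.log(a.S), OK


def gini_coefficient(a: AbundanceSummary) -> float:
    """Gini coefficient of the relative abundances.

    Mean absolute difference form ``sum_ij |p_i - p_j| / (2 S^2 pbar)``
    with ``pbar = 1/S``; evaluated via the O(S log S) sorted identity
    ``sum_ij |p_i - p_j| = 2 * sum_i (2i - S - 1) p_(i)`` (ascending,
    1-based), which the tests check against the brute-force double sum.
    """
    p = np.sort(a.p)
    S = a.S
    i = np.arange(1, S + 1, dtype=np.float64)
    # / (2 S^2 pbar) with pbar = 1/S  ->  / (2 S); times the factor 2 above
    return float(np.sum((2.0 * i - S - 1.0) * p) / S)


# ---------------------------------------------------------------------------
# the full vector
# ---------------------------------------------------------------------------

@dataclass
class DiversityVector:
    """Values and statuses of the twelve indices for one repertoire."""

    values: dict[str, float]
    status: dict[str, str]
    sample_id: str | None = None

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_series(self) -> pd.Series:
        return pd.Series({k: self.values[k] for k in INDEX_NAMES}, name=self.sample_id)

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame: one row per index with value and status."""
        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "index": list(INDEX_NAMES),
                "value": [self.values[k] for k in INDEX_NAMES],
                "status": [self.status[k] for k in INDEX_NAMES],
            }
        )


def compute_all(
    counts: Iterable[float],
    sample_id: str | None = None,
    ace_rare_threshold: int = 10,
) -> DiversityVector:
    """Compute all twelve indices for one count vector.

    Undefined indices are carried as NaN with status ``"undefined"``;
    the vector itself never raises for degenerate (e.g. S = 1) input.
    """
    a = summarize_abundance(counts)
    values: dict[str, float] = {}
    status: dict[str, str] = {}

    def put(name: str, value: float, st: str = OK) -> None:
        values[name] = value
        status[name] = st

    put("S", richness_s(a))
    put("Chao1", chao1(a))
    put("ACE", *ace(a, rare_threshold=ace_rare_threshold))
    put("Shannon", shannon(a))
    put("Inv.Simpson", inv_simpson(a))
    put("Gini.Simpson", gini_simpson(a))
    put("D3", hill_number(a, 3))
    put("D4", hill_number(a, 4))
    put("Pielou", *pielou(a))
    put("Basharin", *basharin(a))
    put("d50", d50(a.counts))
    put("Gini", gini_coefficient(a))
    return DiversityVector(values=values, status=status, sample_id=sample_id)


def diversity_table(samples: Mapping[str, Iterable[float]]) -> pd.DataFrame:
    """Long-format diversity table for a mapping sample_id -> counts."""
    frames = [compute_all(c, sample_id=sid).to_frame() for sid, c in samples.items()]
    return pd.concat(frames, ignore_index=True)
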