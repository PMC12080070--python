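"""Subsampling robustness of diversity indices.

A repertoire is repeatedly downsampled without replacement to a grid of
sequencing depths (total copy numbers); at every depth and repeat all
diversity indices are recomputed.  Robustness is quantified by

* CV — coefficient of variation of an index across repeats at one depth
  (precision under resampling), and
* RE — absolute relative error of the subsampled value against the value
  on the full, non-subsampled repertoire (bias), summarized as the median
  over repeats,

together with the OLS slope of each quantity against log10(depth)
(stability as coverage grows).  Indices are ranked within each dataset on
median CV, |CV slope|, median RE and |RE slope| (rank 1 = smallest, ties
averaged); the robustness score of an index is its rank sum over all
datasets and criteria — the smaller, the more robust.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .diversity import INDEX_NAMES, compute_all

__all__ = [
    "SubsampleDesign",
    "DepthNotApplicable",
    "build_depth_grid",
    "subsample_counts",
    "cv",
    "relative_error",
    "fit_slope",
    "robustness_curves",
    "summarize_robustness",
    "robustness_ranking",
]

logger = logging.getLogger(__name__)


class DepthNotApplicable(ValueError):
    """Requested depth exceeds the sample's total copy number."""


@dataclass
class SubsampleDesign:
    """Depth grid and repeat count for a subsampling experiment."""

    depths: np.ndarray
    repeats: int = 100
    base_seed: int = 0

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=np.int64)
        if np.any(np.diff(self.depths) <= 0):
            raise ValueError("depths must be strictly increasing")
        if self.depths[0] < 1:
            raise ValueError("depths must be >= 1")


def build_depth_grid(
    min_depth: int,
    max_depth: int,
    n_log: int = 10,
    n_extra: int = 4,
    repeats: int = 100,
    base_seed: int = 0,
) -> SubsampleDesign:
    """Depth grid: ``n_log`` log-equally-spaced values from ``min_depth`` to
    ``max_depth`` inclusive, plus ``n_extra`` linearly spaced values strictly
    inside the top log-interval (where log spacing leaves the largest gaps).

    The default (10 log points = minimum + 8 intermediates + maximum, plus
    4 supplementary upper-range points) yields 14 depths.  Values are
    rounded to integers and deduplicated; a grid that collapses below the
    nominal size after rounding is returned with a warning.
    """
    if not 1 <= min_depth <= max_depth:
        raise ValueError("need 1 <= min_depth <= max_depth")
    if min_depth == max_depth:
        warnings.warn("min_depth == max_depth: degenerate single-depth grid")
        return SubsampleDesign(np.array([min_depth]), repeats, base_seed)
    base = np.geomspace(min_depth, max_depth, n_log)
    extra = np.linspace(base[-2], base[-1], n_extra + 2)[1:-1] if n_extra else np.array([])
    depths = np.unique(np.rint(np.concatenate([base, extra])).astype(np.int64))
    depths[0], depths[-1] = min_depth, max_depth  # endpoints exact
    nominal = n_log + n_extra
    if depths.size < nominal:
        warnings.warn(
            f"depth grid collapsed to {depths.size} distinct depths "
            f"(nominal {nominal}) after integer rounding"
        )
    return SubsampleDesign(depths, repeats, base_seed)


_EXACT_POP_LIMIT = 10**9  # numpy's hypergeometric samplers require sums below this


def _approx_hypergeom(rng: np.random.Generator, ngood: int, nbad: int, n: int) -> int:
    # normal approximation with continuity rounding, clipped to the support;
    # used only for mega-clone marginals in populations beyond the exact
    # sampler's range, where the relative error is O(1/sqrt(n))
    N = ngood + nbad
    mean = n * ngood / N
    var = n * (ngood / N) * (nbad / N) * (N - n) / (N - 1)
    k = int(round(rng.normal(mean, math.sqrt(max(var, 0.0)))))
    return int(np.clip(k, max(0, n - nbad), min(ngood, n)))


def subsample_counts(
    counts: Iterable[int],
    depth: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Draw ``depth`` sequence copies without replacement (multivariate
    hypergeometric over clonotypes); zero-count clonotypes are dropped.

    Populations within numpy's exact-sampler range (< 1e9 copies) are drawn
    exactly.  Heavier repertoires are handled by peeling off the dominant
    clones — their hypergeometric marginals drawn via a clipped normal
    approximation — until the remaining population is exactly samplable.

    Raises :class:`DepthNotApplicable` when ``depth`` exceeds the total —
    callers skip such depths rather than clamp them.
    """
    x = np.asarray(counts, dtype=np.int64)
    total = int(x.sum())
    if depth > total:
        raise DepthNotApplicable(f"depth {depth} exceeds total copies {total}")
    if depth == total:
        return x.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if total < _EXACT_POP_LIMIT:
        drawn = rng.multivariate_hypergeometric(x, depth, method="marginals")
        return drawn[drawn > 0]
    # peel dominant clones until the remainder is exactly samplable
    order = np.argsort(x)[::-1]
    drawn = np.zeros_like(x)
    remaining_total, remaining_depth = total, int(depth)
    peeled = 0
    while remaining_total - int(x[order[peeled]]) >= _EXACT_POP_LIMIT or \
            remaining_total >= _EXACT_POP_LIMIT:
        i = order[peeled]
        xi = int(x[i])
        k = _approx_hypergeom(rng, xi, remaining_total - xi, remaining_depth)
        drawn[i] = k
        remaining_total -= xi
        remaining_depth -= k
        peeled += 1
        if remaining_total < _EXACT_POP_LIMIT:
            break
    rest = order[peeled:]
    if remaining_depth > 0 and rest.size:
        drawn[rest] = rng.multivariate_hypergeometric(
            x[rest], remaining_depth, method="marginals"
        )
    return drawn[drawn > 0]


def cv(values: Iterable[float]) -> float:
    """Coefficient of variation: sample SD (n-1 denominator) over mean."""
    x = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                   dtype=np.float64)
    if x.size < 2:
        raise ValueError("CV needs at least 2 values")
    m = x.mean()
    if m == 0:
        return math.nan
    return float(x.std(ddof=1) / m)


def relative_error(value: float, reference: float) -> float:
    """Absolute relative error ``|value - reference| / |reference|``."""
    if reference == 0:
        return math.nan
    return abs(value - reference) / abs(reference)


def fit_slope(depths: Sequence[float], values: Sequence[float],
              log_depth: bool = True) -> float:
    """OLS slope of a robustness metric against depth.

    The regressor is log10(depth) by default — depths span orders of
    magnitude, so the trend is linear on a log axis; set ``log_depth=False``
    for a raw-depth fit.  Returns NaN with fewer than 2 finite points.
    """
    d = np.asarray(depths, dtype=np.float64)
    v = np.asarray(values, dtype=np.float64)
    ok = np.isfinite(d) & np.isfinite(v)
    if ok.sum() < 2:
        return math.nan
    x = np.log10(d[ok]) if log_depth else d[ok]
    if np.ptp(x) == 0:
        return math.nan
    return float(np.polyfit(x, v[ok], 1)[0])


def robustness_curves(
    counts: Iterable[int],
    design: SubsampleDesign,
    sample_id: str = "sample",
) -> pd.DataFrame:
    """CV and median RE per index and depth for one repertoire.

    Reference values come from the full (non-subsampled) repertoire; at
    each applicable depth the indices are recomputed on ``design.repeats``
    independent draws.  Columns: sample_id, index, depth, cv, median_re,
    n_ok (repeats where the index was defined).
    """
    x = np.asarray(counts, dtype=np.int64)
    reference = compute_all(x).values
    rows = []
    for i_depth, depth in enumerate(design.depths):
        if depth > x.sum():
            logger.info("sample %s: skipping depth %d > total %d",
                        sample_id, depth, x.sum())
            continue
        per_index: dict[str, list[float]] = {k: [] for k in INDEX_NAMES}
        for rep in range(design.repeats):
            seed = np.random.SeedSequence(
                [int(design.base_seed), int(i_depth), int(rep)]
            ).generate_state(1)[0] % (2**31)
            sub = subsample_counts(x, int(depth), int(seed))
            vec = compute_all(sub).values
            for k in INDEX_NAMES:
                per_index[k].append(vec[k])
        for k in INDEX_NAMES:
            vals = np.asarray(per_index[k], dtype=np.float64)
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                logger.info("sample %s: index %s undefined at depth %d",
                            sample_id, k, depth)
                continue
            the_cv = cv(vals) if vals.size >= 2 else math.nan
            ref = reference[k]
            res = ([relative_error(v, ref) for v in vals]
                   if math.isfinite(ref) and ref != 0 else [math.nan])
            rows.append(
                {
                    "sample_id": sample_id,
                    "index": k,
                    "depth": int(depth),
                    "cv": the_cv,
                    "median_re": float(np.nanmedian(res)) if np.any(np.isfinite(res)) else math.nan,
                    "n_ok": int(vals.size),
                }
            )
    return pd.DataFrame(rows)


def summarize_robustness(
    curves: pd.DataFrame,
    dataset_of: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per (dataset, index) robustness summary.

    ``curves`` is the concatenated output of :func:`robustness_curves` for
    all samples; ``dataset_of`` maps sample_id to dataset label (a single
    dataset is assumed when omitted).  For each dataset and index: median
    CV and median RE over all (sample, depth) cells, and the OLS slope of
    CV / RE against log10(depth) pooled over samples.
    """
    df = curves.copy()
    df["dataset"] = (df["sample_id"].map(dataset_of) if dataset_of is not None
                     else "all")
    rows = []
    for (ds, idx), g in df.groupby(["dataset", "index"], sort=False):
        rows.append(
            {
                "dataset": ds,
                "index": idx,
                "median_cv": float(np.nanmedian(g["cv"])),
                "median_re": float(np.nanmedian(g["median_re"])),
                "slope_cv": fit_slope(g["depth"], g["cv"]),
                "slope_re": fit_slope(g["depth"], g["median_re"]),
            }
        )
    return pd.DataFrame(rows)


#: criteria entering the robustness ranking (absolute value taken of slopes)
RANKING_CRITERIA = ("median_cv", "slope_cv", "median_re", "slope_re")


def robustness_ranking(summary: pd.DataFrame) -> pd.DataFrame:
    """Rank-sum robustness score across datasets.

    Within each dataset, indices are ranked on each criterion (median CV,
    |CV slope|, median RE, |RE slope|; rank 1 = smallest, ties receive the
    average rank).  The score is the sum of all ranks over datasets and
    criteria; the output is sorted ascending (most robust first).  Missing
    cells are excluded from that criterion's ranking.
    """
    if summary["index"].nunique() < 2:
        raise ValueError("ranking needs at least 2 indices")
    scores: dict[str, float] = {}
    for _, g in summary.groupby("dataset", sort=False):
        for crit in RANKING_CRITERIA:
            vals = g[crit].to_numpy(dtype=np.float64)
            if crit.startswith("slope"):
                vals = np.abs(vals)
            ok = np.isfinite(vals)
            if ok.sum() == 0:
                logger.info("criterion %s has no finite values in a dataset", crit)
                continue
            ranks = rankdata(vals[ok], method="average")
            for idx, r in zip(g["index"].to_numpy()[ok], ranks):
                scores[idx] = scores.get(idx, 0.0) + float(r)
    out = pd.DataFrame(
        {"index": list(scores), "rank_sum": [scores[k] for k in scores]}
    ).sort_values("rank_sum", kind="mergesort", ignore_index=True)
    return out
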