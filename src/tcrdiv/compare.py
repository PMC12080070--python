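"""Between-group testing, index correlations and variable importance.

Group comparisons use the two-sided Mann-Whitney U test with the
rank-biserial coefficient of correlation (RBCC, Wendt's formula)

    RBCC = |1 - 2 U / (n1 * n2)|

as effect size; RBCC lies in [0, 1] and is classified as negligible /
small / medium / high / very high at the 0.1 / 0.3 / 0.5 / 0.7 cut
points.  The absolute-value form makes the result identical whichever
group's U is used.

Variable importance quantifies how strongly each diversity index responds
to Richness versus Evenness on the simulation grid: a flexible regressor
(random forest, spline-with-interactions, or additive spline model) is fit
to index values on predictors (log10 richness, alpha), and permutation
importance — mean R^2 degradation when one predictor is shuffled — is
scaled so the two shares sum to 100%.  Permutation importance is used for
every model because it is model-agnostic and reproducible; the model tag
records which regressor produced the fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.linear_model import Ridge
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import PolynomialFeatures, SplineTransformer, StandardScaler

from .robustness import cv as _cv

__all__ = [
    "EffectSizeResult",
    "ImportanceResult",
    "mann_whitney_rbcc",
    "classify_effect",
    "pairwise_correlations",
    "variable_importance",
    "cv_profiles",
]

logger = logging.getLogger(__name__)

#: RBCC magnitude cut points
EFFECT_THRESHOLDS = (0.1, 0.3, 0.5, 0.7)
EFFECT_LABELS = ("negligible", "small", "medium", "high", "very_high")


def classify_effect(rbcc: float) -> str:
    """Magnitude label for an RBCC value at the 0.1/0.3/0.5/0.7 thresholds."""
    return EFFECT_LABELS[int(np.searchsorted(EFFECT_THRESHOLDS, rbcc, side="right"))]


@dataclass(frozen=True)
class EffectSizeResult:
    u_statistic: float
    p_value: float
    rbcc: float
    n1: int
    n2: int
    magnitude: str


def mann_whitney_rbcc(group_a, group_b) -> EffectSizeResult:
    """Two-sided Mann-Whitney U test with rank-biserial effect size.

    The exact null distribution is enumerated for small tie-free samples
    (both groups <= 20); larger or tied samples use the normal
    approximation with tie correction.  U is the first-group statistic.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (max(a.size, b.size) <= 20 and not has_ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    u = float(res.statistic)
    rbcc = abs(1.0 - 2.0 * u / (a.size * b.size))
    return EffectSizeResult(
        u_statistic=u,
        p_value=float(res.pvalue),
        rbcc=rbcc,
        n1=int(a.size),
        n2=int(b.size),
        magnitude=classify_effect(rbcc),
    )


def effect_size_table(diversity_wide: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Per-index effect sizes between the two levels of ``groups``.

    ``diversity_wide`` is samples x indices; ``groups`` assigns each sample
    one of exactly two labels.  Undefined index values are dropped per
    group before testing.
    """
    levels = pd.unique(groups.dropna())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 group levels, got {list(levels)}")
    rows = []
    for idx in diversity_wide.columns:
        va = diversity_wide.loc[groups == levels[0], idx].dropna()
        vb = diversity_wide.loc[groups == levels[1], idx].dropna()
        if va.empty or vb.empty:
            logger.info("index %s: a group has no defined values; skipped", idx)
            continue
        r = mann_whitney_rbcc(va, vb)
        rows.append({"index": idx, "u_statistic": r.u_statistic, "p_value": r.p_value,
                     "rbcc": r.rbcc, "magnitude": r.magnitude, "n1": r.n1, "n2": r.n2})
    return pd.DataFrame(rows)


def pairwise_correlations(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson and Spearman correlation matrices across indices.

    ``matrix`` is samples x indices; undefined values are handled
    pairwise-complete, and columns with fewer than 3 finite values are
    dropped (logged).  Both outputs are symmetric with unit diagonal.
    """
    if len(matrix) < 3:
        raise ValueError("need at least 3 samples for correlations")
    ok_cols = [c for c in matrix.columns if matrix[c].notna().sum() >= 3]
    dropped = set(matrix.columns) - set(ok_cols)
    if dropped:
        logger.info("dropping columns with <3 finite values: %s", sorted(dropped))
    m = matrix[ok_cols]
    pearson = m.corr(method="pearson", min_periods=3)
    spearman = m.corr(method="spearman", min_periods=3)
    for c in (pearson, spearman):
        np.fill_diagonal(c.values, 1.0)
    return pearson, spearman


@dataclass(frozen=True)
class ImportanceResult:
    index: str
    model_tag: str
    richness_importance: float  # percent; sums with evenness to 100
    evenness_importance: float
    r_squared: float


def _make_model(model_tag: str, seed: int):
    if model_tag == "forest":
        return RandomForestRegressor(n_estimators=200, random_state=seed, n_jobs=1)
    if model_tag == "spline":
        # spline bases with pairwise interactions (MARS-like capacity)
        return make_pipeline(
            StandardScaler(),
            SplineTransformer(degree=3, n_knots=8),
            PolynomialFeatures(degree=2, interaction_only=True, include_bias=False),
            Ridge(alpha=1e-3),
        )
    if model_tag == "additive":
        # additive in the two predictors: per-feature smooth + linear blend
        return make_pipeline(
            StandardScaler(),
            SplineTransformer(degree=3, n_knots=12),
            Ridge(alpha=1e-3),
        )
    raise ValueError(f"unknown model_tag {model_tag!r}; choose forest|spline|additive")


def variable_importance(
    grid_results: pd.DataFrame,
    index: str,
    model_tag: str = "forest",
    seed: int = 0,
    n_shuffles: int = 10,
) -> ImportanceResult:
    """Richness-vs-evenness importance for one index on the simulation grid.

    ``grid_results`` needs columns alpha, richness and ``index`` (one row
    per simulated repertoire).  The regressor is fit on
    (log10 richness, alpha); permutation importance (mean R^2 drop over
    ``n_shuffles`` shuffles, fixed seed) is clipped at zero and scaled so
    richness + evenness = 100.
    """
    df = grid_results.dropna(subset=[index])
    if df["alpha"].nunique() < 2 or df["richness"].nunique() < 2:
        raise ValueError("grid must cover >= 2 distinct alpha and richness values")
    X = np.column_stack([np.log10(df["richness"].to_numpy(dtype=np.float64)),
                         df["alpha"].to_numpy(dtype=np.float64)])
    y = df[index].to_numpy(dtype=np.float64)
    model = _make_model(model_tag, seed)
    model.fit(X, y)
    r2 = float(model.score(X, y))
    if r2 <= 0:
        raise RuntimeError(
            f"{model_tag} model for {index} explains no variance (R^2 = {r2:.3f})"
        )
    imp = permutation_importance(
        model, X, y, scoring="r2", n_repeats=n_shuffles, random_state=seed
    ).importances_mean
    imp = np.clip(imp, 0.0, None)
    if imp.sum() == 0:
        raise RuntimeError(f"no predictor matters for {index} under {model_tag}")
    share = 100.0 * imp / imp.sum()
    return ImportanceResult(
        index=index,
        model_tag=model_tag,
        richness_importance=float(share[0]),
        evenness_importance=float(share[1]),
        r_squared=r2,
    )


def importance_table(
    grid_results: pd.DataFrame,
    indices: list[str],
    model_tags: list[str] = ["forest"],
    seed: int = 0,
    n_shuffles: int = 10,
) -> pd.DataFrame:
    rows = []
    for tag in model_tags:
        for idx in indices:
            r = variable_importance(grid_results, idx, tag, seed=seed,
                                    n_shuffles=n_shuffles)
            rows.append(vars(r))
    return pd.DataFrame(rows)


def cv_profiles(grid_results: pd.DataFrame, index: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Variation of an index across one grid axis at fixed levels of the other.

    Per-cell means (over replicates) are computed first; then, for every
    fixed richness, the CV of the mean index across evenness values, and
    for every fixed evenness, the CV across richness values.  Cells where
    the mean is zero yield NaN profile points (logged).
    """
    cells = (grid_results.dropna(subset=[index])
             .groupby(["alpha", "richness"], sort=True)[index].mean().reset_index())

    def profile(fixed: str) -> pd.DataFrame:
        rows = []
        for level, g in cells.groupby(fixed, sort=True):
            vals = g[index].to_numpy(dtype=np.float64)
            if vals.size < 2:
                logger.info("%s=%s: fewer than 2 cells for CV profile", fixed, level)
                continue
            rows.append({fixed: level, "cv": _cv(vals), "n": vals.size})
        return pd.DataFrame(rows)

    across_evenness = profile("richness")   # CV over alpha at fixed S
    across_richness = profile("alpha")      # CV over S at fixed alpha
    return across_evenness, across_richness
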