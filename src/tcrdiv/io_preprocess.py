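"""Reading rearrangement tables and preprocessing repertoires.

Supports three TSV dialects of clonotype abundance tables:

* ``immunoseq`` — immunoSEQ-style exports: ``rearrangement`` (or
  ``amino_acid``) identifies the clonotype, ``templates`` or ``reads``
  carries the copy number (templates for v3/v4 data, reads for v1/v2; the
  ``count_column`` argument selects explicitly), ``frame_type`` in
  {In, Out, Stop} marks functionality (In = functional).
* ``airr`` — AIRR rearrangement columns: ``junction_aa``,
  ``duplicate_count``, ``productive`` (T/F or true/false).
* ``generic`` — ``id``, ``count``, optional boolean ``functional``.

Preprocessing follows the standard repertoire workflow: drop nonfunctional
(out-of-frame / stop-codon) sequences, characterize each repertoire
(richness, total copies, median copies, fitted power-law evenness alpha),
and flag outlying samples with the adjusted-boxplot (medcouple) rule for
skewed distributions applied to four per-sample statistics, a sample being
an outlier when flagged on at least two of the four.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import zeta as _zeta
from statsmodels.stats.stattools import medcouple

__all__ = [
    "ClonotypeTable",
    "RepertoireSummary",
    "OutlierReport",
    "RepertoireFormatError",
    "read_repertoire_table",
    "filter_functional",
    "estimate_alpha",
    "summarize_repertoire",
    "tukey_outliers",
    "detect_outliers",
    "summary_table",
]

ALPHA_BRACKET = (1.01, 50.0)


class RepertoireFormatError(ValueError):
    """A required column is missing or malformed in an input table."""


@dataclass
class ClonotypeTable:
    """One repertoire: unique clonotypes with positive copy numbers."""

    sample_id: str
    clonotype_ids: list[str]
    counts: np.ndarray
    functional_flags: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if len(self.clonotype_ids) != len(self.counts):
            raise ValueError("clonotype_ids and counts must have equal length")
        if self.counts.size and self.counts.min() < 1:
            raise ValueError("all counts must be >= 1")
        if len(set(self.clonotype_ids)) != len(self.clonotype_ids):
            raise ValueError("clonotype ids must be unique within a table")
        if self.functional_flags is not None:
            self.functional_flags = np.asarray(self.functional_flags, dtype=bool)
            if len(self.functional_flags) != len(self.counts):
                raise ValueError("functional_flags length mismatch")

    @property
    def S(self) -> int:
        return len(self.counts)

    @property
    def N(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class RepertoireSummary:
    """Per-sample basic characteristics used for QC and outlier screening."""

    sample_id: str
    unique_count: int
    total_count: int
    median_copies: float
    alpha_hat: float


_DIALECTS = {
    "immunoseq": {
        "id": ("rearrangement", "amino_acid"),
        "count": ("templates", "reads"),
        "functional": "frame_type",
    },
    "airr": {
        "id": ("junction_aa",),
        "count": ("duplicate_count",),
        "functional": "productive",
    },
    "generic": {
        "id": ("id",),
        "count": ("count",),
        "functional": "functional",
    },
}

_TRUTHY = {"t", "true", "1", "yes", "y"}
_FALSY = {"f", "false", "0", "no", "n"}


def _pick_column(df: pd.DataFrame, candidates: Sequence[str], kind: str,
                 dialect: str) -> str:
    for c in candidates:
        if c in df.columns:
            return c
    raise RepertoireFormatError(
        f"{dialect} table is missing a {kind} column "
        f"(expected one of: {', '.join(candidates)})"
    )


def _parse_functional(col: pd.Series, dialect: str) -> np.ndarray:
    if dialect == "immunoseq":
        return (col.astype(str).str.strip() == "In").to_numpy()
    out = np.empty(len(col), dtype=bool)
    for i, v in enumerate(col):
        if isinstance(v, (bool, np.bool_)):
            out[i] = bool(v)
            continue
        s = str(v).strip().lower()
        if s in _TRUTHY:
            out[i] = True
        elif s in _FALSY:
            out[i] = False
        else:
            raise RepertoireFormatError(
                f"cannot interpret functionality value {v!r} in row {i}"
            )
    return out


def read_repertoire_table(
    path: str | Path,
    dialect: str = "generic",
    sample_id: str | None = None,
    count_column: str | None = None,
) -> ClonotypeTable:
    """Read a TSV rearrangement table into a :class:`ClonotypeTable`.

    ``count_column`` overrides the dialect's default copy-number column
    (immunoSEQ data may carry either ``reads`` or ``templates``; which one
    is appropriate depends on the assay version).  Duplicate clonotype ids
    are aggregated by summing their counts — the downstream analysis
    depends only on the abundance vector.
    """
    path = Path(path)
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {sorted(_DIALECTS)}")
    spec = _DIALECTS[dialect]
    df = pd.read_csv(path, sep="\t")

    id_col = _pick_column(df, spec["id"], "clonotype-identifier", dialect)
    if count_column is not None:
        if count_column not in df.columns:
            raise RepertoireFormatError(f"requested count column {count_column!r} not present")
        count_col = count_column
    else:
        count_col = _pick_column(df, spec["count"], "count", dialect)

    counts_raw = pd.to_numeric(df[count_col], errors="coerce")
    bad = counts_raw.isna() | (counts_raw < 1)
    if bad.any():
        row = int(np.argmax(bad.to_numpy()))
        raise ValueError(
            f"non-positive or non-numeric count {df[count_col].iloc[row]!r} "
            f"in row {row} of {path.name}"
        )

    func_col = spec["functional"]
    flags = _parse_functional(df[func_col], dialect) if func_col in df.columns else None

    work = pd.DataFrame({"id": df[id_col].astype(str), "count": counts_raw.astype(np.int64)})
    if flags is not None:
        work["functional"] = flags
    grouped = work.groupby("id", sort=False).agg(
        {"count": "sum", **({"functional": "first"} if flags is not None else {})}
    )

    return ClonotypeTable(
        sample_id=sample_id or path.stem,
        clonotype_ids=list(grouped.index),
        counts=grouped["count"].to_numpy(),
        functional_flags=grouped["functional"].to_numpy() if flags is not None else None,
        metadata={"path": str(path), "dialect": dialect, "count_column": count_col},
    )


def filter_functional(table: ClonotypeTable) -> ClonotypeTable:
    """Keep only functional (in-frame, no stop codon) clonotypes.

    Idempotent; never increases S or N.  Warns when nothing survives.
    """
    if table.functional_flags is None:
        raise ValueError(
            "table has no functionality flags; read it with a dialect that "
            "provides them or attach functional_flags explicitly"
        )
    keep = table.functional_flags
    if not keep.any():
        warnings.warn(f"sample {table.sample_id}: no functional sequences remain")
    return ClonotypeTable(
        sample_id=table.sample_id,
        clonotype_ids=[c for c, k in zip(table.clonotype_ids, keep) if k],
        counts=table.counts[keep],
        functional_flags=table.functional_flags[keep],
        metadata=dict(table.metadata),
    )


def _alpha_nll(alpha: float, n: int, sum_log: float) -> float:
    return n * math.log(_zeta(alpha, 1)) + alpha * sum_log


def estimate_alpha(counts: Iterable[float], bracket: tuple[float, float] = ALPHA_BRACKET) -> float:
    """Maximum-likelihood evenness exponent of the zeta (discrete power-law)
    distribution with lower bound 1.

    Maximizes ``-n log zeta(alpha) - alpha * sum(log x_i)`` over
    ``alpha`` in ``bracket`` by bounded scalar optimization (tolerance
    1e-6).  Requires at least one count above 1; an all-singleton sample
    pushes the likelihood to the ``alpha -> inf`` boundary.
    """
    x = np.asarray(list(counts) if not isinstance(counts, np.ndarray) else counts,
                   dtype=np.float64)
    if x.size < 2:
        raise ValueError("need at least 2 counts to estimate alpha")
    if np.any(x < 1):
        raise ValueError("counts must be >= 1")
    if np.all(x == 1):
        raise ValueError(
            "all counts equal 1: the likelihood is maximized at the "
            "alpha -> infinity boundary and the exponent is not identifiable"
        )
    sum_log = float(np.log(x).sum())
    res = minimize_scalar(
        _alpha_nll,
        bounds=bracket,
        args=(x.size, sum_log),
        method="bounded",
        options={"xatol": 1e-6},
    )
    ahat = float(res.x)
    edge_tol = 1e-4
    if ahat <= bracket[0] + edge_tol or ahat >= bracket[1] - edge_tol:
        edge = bracket[0] if ahat <= bracket[0] + edge_tol else bracket[1]
        warnings.warn(f"alpha MLE hit the search bracket edge {edge}")
        return float(edge)
    return ahat


def summarize_repertoire(table: ClonotypeTable) -> RepertoireSummary:
    """Richness, total copies, median copies and fitted evenness alpha."""
    if table.S == 0:
        raise ValueError(f"sample {table.sample_id} is empty")
    return RepertoireSummary(
        sample_id=table.sample_id,
        unique_count=table.S,
        total_count=table.N,
        median_copies=float(np.median(table.counts)),
        alpha_hat=estimate_alpha(table.counts) if table.S >= 2 and table.counts.max() > 1
        else math.nan,
    )


# ---------------------------------------------------------------------------
# outlier screening
# ---------------------------------------------------------------------------

def _quartiles(x: np.ndarray) -> tuple[float, float]:
    # linear-interpolation quartile convention, pinned: fence membership
    # depends on it
    q1, q3 = np.quantile(x, [0.25, 0.75], method="linear")
    return float(q1), float(q3)


def tukey_outliers(values: Iterable[float]) -> np.ndarray:
    """Mild-outlier flags: strictly outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR]."""
    x = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                   dtype=np.float64)
    if x.size < 4:
        raise ValueError("need at least 4 values for outlier fences")
    q1, q3 = _quartiles(x)
    iqr = q3 - q1
    if iqr == 0:
        return np.zeros(x.size, dtype=bool)
    return (x < q1 - 1.5 * iqr) | (x > q3 + 1.5 * iqr)


def adjusted_boxplot_outliers(values: Iterable[float]) -> np.ndarray:
    """Adjusted-boxplot flags for skewed data (medcouple fences).

    For medcouple MC >= 0 the fences are
    ``[Q1 - 1.5 exp(-4 MC) IQR, Q3 + 1.5 exp(3 MC) IQR]``; for MC < 0 they
    mirror to ``[Q1 - 1.5 exp(-3 MC) IQR, Q3 + 1.5 exp(4 MC) IQR]``.
    At MC = 0 this is exactly Tukey's rule.  Zero-IQR data flags nothing.
    """
    x = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                   dtype=np.float64)
    if x.size < 4:
        raise ValueError("need at least 4 values for outlier fences")
    q1, q3 = _quartiles(x)
    iqr = q3 - q1
    if iqr == 0:
        return np.zeros(x.size, dtype=bool)
    mc = float(medcouple(x))
    if mc >= 0:
        lo = q1 - 1.5 * math.exp(-4.0 * mc) * iqr
        hi = q3 + 1.5 * math.exp(3.0 * mc) * iqr
    else:
        lo = q1 - 1.5 * math.exp(-3.0 * mc) * iqr
        hi = q3 + 1.5 * math.exp(4.0 * mc) * iqr
    return (x < lo) | (x > hi)


#: the four per-sample screening statistics
OUTLIER_CRITERIA = ("unique_count", "median_copies", "total_count", "alpha_hat")


@dataclass
class OutlierReport:
    """Per-sample outlier flags: one column per criterion plus the overall
    call (outlying on >= 2 of the 4 criteria)."""

    flags: pd.DataFrame  # index: sample_id; columns: criteria + "outlier"

    def outliers(self) -> list[str]:
        return list(self.flags.index[self.flags["outlier"]])


def detect_outliers(summaries: Sequence[RepertoireSummary]) -> OutlierReport:
    """Screen samples on richness, median copies, total copies and fitted
    alpha with the adjusted-boxplot rule; overall flag at >= 2 criteria."""
    if len(summaries) < 4:
        raise ValueError("need at least 4 samples to establish outlier fences")
    df = pd.DataFrame(
        {c: [getattr(s, c) for s in summaries] for c in OUTLIER_CRITERIA},
        index=[s.sample_id for s in summaries],
    )
    flags = pd.DataFrame(index=df.index)
    for c in OUTLIER_CRITERIA:
        col = df[c].to_numpy(dtype=np.float64)
        if np.isnan(col).any():
            ok = ~np.isnan(col)
            f = np.zeros(col.size, dtype=bool)
            if ok.sum() >= 4:
                f[ok] = adjusted_boxplot_outliers(col[ok])
            flags[c] = f
        else:
            flags[c] = adjusted_boxplot_outliers(col)
    flags["outlier"] = flags[list(OUTLIER_CRITERIA)].sum(axis=1) >= 2
    return OutlierReport(flags=flags)


def summary_table(
    summaries: Sequence[RepertoireSummary],
    report: OutlierReport | None = None,
) -> pd.DataFrame:
    """Per-sample summary frame (the TSV the CLI writes)."""
    df = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in summaries],
            "unique_count": [s.unique_count for s in summaries],
            "total_count": [s.total_count for s in summaries],
            "median_copies": [s.median_copies for s in summaries],
            "alpha_hat": [s.alpha_hat for s in summaries],
        }
    )
    if report is not None:
        df["outlier"] = report.flags["outlier"].reindex(df["sample_id"]).to_numpy()
    return df
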