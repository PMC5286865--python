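"""Relating ARSI scores to expression measurements.

Spearman and partial Spearman correlations of per-gene scores with mRNA
levels or protein abundance, and high-vs-low expression group
comparisons (Wilcoxon rank-sum).  Partial correlation follows the
rank-residual construction: rank-transform the variables, regress both
on the (ranked) controls, and correlate the residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

EXPRESSION_FIELDS = ("mrna", "pa")


def load_expression_table(path: str | Path) -> pd.DataFrame:
    """Read a gene_id/mrna/pa TSV (header required; empty field = missing)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if "gene_id" not in df.columns:
        raise ValueError("expression table must have a 'gene_id' header column")
    for col in EXPRESSION_FIELDS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
            if (df[col].dropna() < 0).any():
                raise ValueError(f"negative values in expression column {col!r}")
    return df.set_index("gene_id")


@dataclass(frozen=True)
class CorrelationResult:
    pair: tuple[str, str]
    rho: float
    p_value: float
    n: int
    controls: tuple[str, ...] = ()


def _align(scores: Mapping[str, float] | pd.Series,
           expr: pd.DataFrame, column: str) -> pd.DataFrame:
    s = pd.Series(dict(scores)) if not isinstance(scores, pd.Series) else scores
    if column not in expr.columns:
        raise KeyError(f"expression table has no column {column!r}")
    df = pd.DataFrame({"score": s, "expr": expr[column]}).dropna()
    return df


def spearman_corr(scores: Mapping[str, float] | pd.Series,
                  expr: pd.DataFrame, column: str = "mrna") -> CorrelationResult:
    """Spearman correlation of per-gene scores with one expression column.

    Missing entries are excluded pairwise; at least three complete pairs
    are required.
    """
    df = _align(scores, expr, column)
    if len(df) < 3:
        raise ValueError(f"need >=3 complete pairs, got {len(df)}")
    rho, p = stats.spearmanr(df["score"], df["expr"])
    return CorrelationResult(("arsi", column), float(rho), float(p), len(df))


def partial_spearman(x: Sequence[float], y: Sequence[float],
                     controls: Mapping[str, Sequence[float]] | None = None,
                     pair: tuple[str, str] = ("x", "y")) -> CorrelationResult:
    """Partial Spearman correlation of x and y given controlling covariates.

    All variables are rank-transformed (average ranks); x and y are each
    regressed on the controls (with intercept) by least squares and the
    Pearson correlation of the residuals is returned, with a two-sided p
    from the t approximation on n - 2 - k degrees of freedom.  With no
    controls this reduces exactly to the Spearman correlation.
    """
    controls = dict(controls or {})
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cols = {name: np.asarray(v, dtype=float) for name, v in controls.items()}
    mask = ~np.isnan(x) & ~np.isnan(y)
    for v in cols.values():
        mask &= ~np.isnan(v)
    n, k = int(mask.sum()), len(cols)
    if n < 3 + k:
        raise ValueError(f"need >={3 + k} complete cases, got {n}")
    rx = stats.rankdata(x[mask])
    ry = stats.rankdata(y[mask])
    if cols:
        Z = np.column_stack([stats.rankdata(v[mask]) for v in cols.values()])
        design = np.column_stack([np.ones(n), Z])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError(f"collinear controls: {sorted(cols)}")
        beta_x, *_ = np.linalg.lstsq(design, rx, rcond=None)
        beta_y, *_ = np.linalg.lstsq(design, ry, rcond=None)
        ex = rx - design @ beta_x
        ey = ry - design @ beta_y
    else:
        ex = rx - rx.mean()
        ey = ry - ry.mean()
    denom = np.sqrt((ex ** 2).sum() * (ey ** 2).sum())
    if denom == 0:
        raise ValueError("constant variable after rank transform")
    rho = float((ex * ey).sum() / denom)
    df = n - 2 - k
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt(df / (1 - rho ** 2))
        p = float(2 * stats.t.sf(abs(t), df))
    return CorrelationResult(pair, rho, p, n, tuple(sorted(cols)))


def split_high_low(expr: pd.DataFrame, column: str = "mrna",
                   policy: str = "median",
                   quantile: float = 0.25) -> tuple[list[str], list[str]]:
    """Split genes into high/low expression sets.

    ``policy="median"`` (default) puts ties at the median into the high
    set; ``policy="quantile"`` keeps the top and bottom ``quantile``
    fractions only.  Constant expression cannot be split.
    """
    vals = expr[column].dropna()
    if len(vals) < 4:
        raise ValueError("need >=4 genes with expression values")
    if vals.nunique() == 1:
        raise ValueError("expression is constant; cannot split")
    if policy == "median":
        med = vals.median()
        high = vals.index[vals >= med]
        low = vals.index[vals < med]
    elif policy == "quantile":
        lo_q, hi_q = vals.quantile(quantile), vals.quantile(1 - quantile)
        high = vals.index[vals >= hi_q]
        low = vals.index[vals <= lo_q]
    else:
        raise ValueError(f"unknown split policy {policy!r}")
    return list(high), list(low)


@dataclass(frozen=True)
class GroupComparison:
    statistic: float
    p_value: float
    median_high: float
    median_low: float
    n_high: int
    n_low: int


def compare_groups(scores: Mapping[str, float] | pd.Series,
                   high: Sequence[str], low: Sequence[str]) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum comparison of scores between gene sets."""
    s = pd.Series(dict(scores)) if not isinstance(scores, pd.Series) else scores
    hi = s.reindex(high).dropna().to_numpy()
    lo = s.reindex(low).dropna().to_numpy()
    if hi.size == 0 or lo.size == 0:
        raise ValueError("both groups must be nonempty")
    stat, p = stats.mannwhitneyu(hi, lo, alternative="two-sided")
    return GroupComparison(float(stat), float(p),
                           float(np.median(hi)), float(np.median(lo)),
                           int(hi.size), int(lo.size))


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted q-values for a batch of tests (optional multi-region use)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    q = np.empty(m)
    prev = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        val = min(prev, p[i] * m / (rank_idx + 1))
        q[i] = val
        prev = val
    return q
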