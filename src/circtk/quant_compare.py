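"""Quantification and comparison of circular transcriptomes.

Support counts (CCRs or BSJ reads) per circRNA per dataset are normalized by
library size (uniquely mapped reads, "per million") and by TMM (trimmed mean
of M-values) scaling factors computed between datasets; batch-level
expression is the mean of the normalized per-dataset values. On top of this
sit Top-N rankings and their pairwise overlaps, per-gene circular expression
(sum over a gene's circRNAs), isoform-balance summaries, cross-species
expression correlations, and an exact rank-sum test for batch-versus-batch
comparisons of per-dataset summaries.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("circtk")

__all__ = [
    "ExpressionTable",
    "per_million",
    "tmm_factors",
    "batch_expression",
    "gene_expression",
    "top_n",
    "overlap_pct",
    "isoform_balance",
    "cross_expression_correlation",
    "compare_batch_counts",
]


@dataclass
class ExpressionTable:
    """circRNA x dataset junction-read count matrix with metadata.

    ``counts``: rows are circRNA ids, columns dataset ids, values >= 0.
    ``library_sizes``: uniquely mapped read count per dataset.
    ``batch_map``: DataFrame indexed by dataset id with columns
    species, tissue, batch_id.
    """

    counts: pd.DataFrame
    library_sizes: pd.Series
    batch_map: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        missing = set(self.counts.columns) - set(self.library_sizes.index)
        if missing:
            raise ValueError(f"missing library size(s) for {sorted(missing)}")
        if (self.library_sizes.loc[list(self.counts.columns)] <= 0).any():
            raise ValueError("library sizes must be positive")
        uncovered = set(self.counts.columns) - set(self.batch_map.index)
        if uncovered:
            raise ValueError(f"batch_map does not cover {sorted(uncovered)}")

    def datasets_in_batch(self, batch_id: str) -> list[str]:
        sel = self.batch_map.index[self.batch_map["batch_id"] == batch_id]
        cols = [d for d in sel if d in self.counts.columns]
        if not cols:
            raise KeyError(f"unknown batch {batch_id!r}")
        return cols


def per_million(count: float, library_size: float) -> float:
    """Counts per million library reads."""
    if library_size <= 0:
        raise ValueError("library size must be > 0")
    return count * 1e6 / library_size


# ---------------------------------------------------------------------------
# TMM normalization (trimmed mean of M-values)
# ---------------------------------------------------------------------------

def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              trim_m: float, trim_a: float) -> float:
    both = (obs > 0) & (ref > 0)
    o, r = obs[both].astype(float), ref[both].astype(float)
    if o.size == 0:
        return 1.0
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    # asymptotic (delta-method) variance of M, used as inverse weight
    v = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = math.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    return 1.0 if not np.isfinite(f) else float(2.0 ** f)


def tmm_factors(counts: pd.DataFrame | ExpressionTable,
                trim_m: float = 0.30, trim_a: float = 0.05,
                ref_column: str | None = None) -> pd.Series:
    """Per-dataset TMM scaling factors.

    M-values (log2 count ratios, library-size scaled) and A-values (average
    log abundance) are computed over features positive in both the test and
    reference columns, doubly trimmed (``trim_m`` on M, ``trim_a`` on A), and
    combined as a precision-weighted mean; the factor is 2 to that mean. The
    reference column is the one whose library-size-scaled 75th-percentile
    count is closest to the mean of those quantiles. Factors are rescaled so
    their log-mean is zero; a column of all zeros is an error.
    """
    if isinstance(counts, ExpressionTable):
        counts = counts.counts
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two columns")
    mat = counts.to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    for j, col in enumerate(counts.columns):
        if lib[j] == 0:
            raise ValueError(f"column {col!r} has all-zero counts; TMM factor undefined")
    f75 = np.quantile(mat / lib, 0.75, axis=0)
    if ref_column is None:
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_idx = list(counts.columns).index(ref_column)
    factors = np.array([
        _tmm_pair(mat[:, j], mat[:, ref_idx], lib[j], lib[ref_idx], trim_m, trim_a)
        for j in range(mat.shape[1])
    ])
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


# ---------------------------------------------------------------------------
# Batch aggregation and gene-level expression
# ---------------------------------------------------------------------------

def normalized_counts(table: ExpressionTable, factors: pd.Series | None = None
                      ) -> pd.DataFrame:
    """Counts per million effective library size (library size x TMM factor)."""
    if factors is None:
        factors = (tmm_factors(table.counts) if table.counts.shape[1] >= 2
                   else pd.Series(1.0, index=table.counts.columns))
    lib = table.library_sizes.loc[list(table.counts.columns)]
    eff = lib * factors.loc[list(table.counts.columns)]
    return table.counts * 1e6 / eff


def batch_expression(table: ExpressionTable, batch_id: str,
                     factors: pd.Series | None = None) -> pd.Series:
    """Mean normalized count per circRNA across the datasets of one batch."""
    cols = table.datasets_in_batch(batch_id)
    norm = normalized_counts(table, factors)
    return norm[cols].mean(axis=1)


def gene_expression(parent_map: Mapping[str, str],
                    expression: pd.DataFrame | pd.Series
                    ) -> tuple[pd.DataFrame | pd.Series, pd.Series | float]:
    """Per-gene circular expression: the sum over that gene's circRNAs.

    ``parent_map`` maps circRNA id -> parent gene id for annotated circles;
    circRNAs absent from the map are excluded, and their total expression is
    returned separately as the unannotated residual. Conservation holds:
    gene totals + residual == input totals.
    """
    if isinstance(expression, pd.Series):
        df = expression.to_frame("value")
        genes, residual = gene_expression(parent_map, df)
        return genes["value"] if len(genes) else pd.Series(dtype=float), float(residual.iloc[0])
    annotated_ids = [i for i in expression.index if i in parent_map]
    residual = expression.drop(index=annotated_ids).sum(axis=0)
    if not annotated_ids:
        return expression.iloc[0:0].copy(), residual
    sub = expression.loc[annotated_ids]
    gene_ids = pd.Index([parent_map[i] for i in annotated_ids], name="gene")
    genes = sub.groupby(gene_ids).sum()
    return genes, residual


# ---------------------------------------------------------------------------
# Rankings, overlaps, balances
# ---------------------------------------------------------------------------

def top_n(expression: pd.Series, n: int = 100) -> list[str]:
    """Ids of the ``n`` largest expression values, descending; ties broken by
    lexicographically smaller id. Zero-expression entries never rank; fewer
    than ``n`` nonzero entries yield a shorter list."""
    nonzero = expression[expression > 0]
    ranked = sorted(nonzero.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ranked) < n:
        logger.info("top_n: only %d nonzero entries for n=%d", len(ranked), n)
    return [k for k, _ in ranked[:n]]


def overlap_pct(top_a: Sequence[str], top_b: Sequence[str]) -> float:
    """Percentage overlap between two equal-length Top-N lists."""
    if len(top_a) != len(top_b):
        raise ValueError(f"length mismatch: {len(top_a)} vs {len(top_b)}")
    if not top_a:
        raise ValueError("empty lists")
    return 100.0 * len(set(top_a) & set(top_b)) / len(top_a)


def isoform_balance(gene_id: str, expression: pd.Series,
                    parent_map: Mapping[str, str]
                    ) -> tuple[int, float, float]:
    """Circular isoform balance of one parent gene.

    Returns (n_isoforms, dominance, max_min) where dominance is the ratio of
    the strongest to the second-strongest isoform and max_min the ratio of
    strongest to weakest; both are ``inf`` for a single isoform (or a zero
    denominator)."""
    values = sorted((float(expression.get(c, 0.0))
                     for c, g in parent_map.items() if g == gene_id), reverse=True)
    if not values:
        raise ValueError(f"gene {gene_id!r} has no circRNAs in the map")
    n = len(values)
    if n == 1:
        return 1, math.inf, math.inf
    dominance = values[0] / values[1] if values[1] > 0 else math.inf
    max_min = values[0] / values[-1] if values[-1] > 0 else math.inf
    return n, dominance, max_min


# ---------------------------------------------------------------------------
# Cross-species correlation and batch tests
# ---------------------------------------------------------------------------

def cross_expression_correlation(expr_a: pd.Series, expr_b: pd.Series,
                                 id_map: Iterable[tuple[str, str]],
                                 min_log10: float = 1.2,
                                 method: str = "pearson",
                                 ) -> tuple[int, float]:
    """Correlation of log10 expression across matched rows of two tables.

    ``id_map`` pairs ids of ``expr_a`` with ids of ``expr_b`` (orthologous
    genes or circRNAs). Only pairs with log10(value) > ``min_log10`` on both
    sides enter; returns (n_pairs, r). Fewer than 3 surviving pairs is an
    error (the correlation is undefined)."""
    xs, ys = [], []
    for id_a, id_b in id_map:
        va = expr_a.get(id_a)
        vb = expr_b.get(id_b)
        if va is None or vb is None or va <= 0 or vb <= 0:
            continue
        la, lb = math.log10(va), math.log10(vb)
        if la > min_log10 and lb > min_log10:
            xs.append(la)
            ys.append(lb)
    if len(xs) < 3:
        raise ValueError(f"only {len(xs)} pairs pass the expression filter; "
                         "correlation undefined")
    if method == "pearson":
        r = stats.pearsonr(xs, ys).statistic
    elif method == "spearman":
        r = stats.spearmanr(xs, ys).statistic
    else:
        raise ValueError(f"unknown method {method!r}")
    return len(xs), float(r)


def compare_batch_counts(values_a: Sequence[float], values_b: Sequence[float]
                         ) -> tuple[float, float]:
    """Two-sided exact Mann-Whitney rank-sum test between two groups of
    per-dataset scalar summaries (e.g. exonic circRNAs per million)."""
    if len(values_a) < 2 or len(values_b) < 2:
        raise ValueError("each group needs at least 2 values")
    method = "exact" if max(len(values_a), len(values_b)) <= 25 else "auto"
    res = stats.mannwhitneyu(values_a, values_b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
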