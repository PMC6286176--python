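"""Differential-enrichment screen over a count matrix.

Median-of-ratios size factors normalize for sequencing depth, per-site
log2 fold changes (with a pseudocount) are compared against a cutoff of
1.0, and an optional label-permutation test with Benjamini-Hochberg
adjustment supplies p-values.  This screen is a deliberately lightweight
built-in: the canonical route for a real study is exporting the count
matrix to a dedicated negative-binomial differential tool.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .consolidate import CountMatrix


@dataclass(frozen=True)
class ScreenParams:
    lfc_cutoff: float = 1.0
    padj_cutoff: float = 0.05
    pseudocount: float = 1.0
    n_permutations: int = 10000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.lfc_cutoff <= 0 or self.padj_cutoff <= 0:
            raise ValueError("cutoffs must be > 0")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")


def size_factors(counts: np.ndarray | CountMatrix) -> np.ndarray:
    """Median-of-ratios size factors (one positive factor per sample).

    factor_j = median over sites with all-positive counts of
    counts[i, j] / geometric_mean_i.  A matrix with identical columns gets
    factors of exactly 1.  Raises if no site has all-positive counts.
    """
    x = np.asarray(counts.counts if isinstance(counts, CountMatrix) else counts, dtype=float)
    positive = (x > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no site has positive counts in every sample; add a pseudocount or more data"
        )
    logs = np.log(x[positive])
    log_geo_mean = logs.mean(axis=1, keepdims=True)
    return np.exp(np.median(logs - log_geo_mean, axis=0))


def _group_columns(matrix: CountMatrix) -> tuple[str, str, np.ndarray, np.ndarray]:
    labels = sorted({matrix.condition[s] for s in matrix.samples})
    if len(labels) != 2:
        raise ValueError(f"screen requires exactly 2 condition labels, got {labels}")
    a, b = labels
    cols_a = np.array([j for j, s in enumerate(matrix.samples) if matrix.condition[s] == a])
    cols_b = np.array([j for j, s in enumerate(matrix.samples) if matrix.condition[s] == b])
    if len(cols_a) == 0 or len(cols_b) == 0:
        raise ValueError("each condition needs at least one sample")
    return a, b, cols_a, cols_b


def _log2fc(normed: np.ndarray, cols_a: np.ndarray, cols_b: np.ndarray, pc: float) -> np.ndarray:
    mean_a = normed[:, cols_a].mean(axis=1)
    mean_b = normed[:, cols_b].mean(axis=1)
    return np.log2((mean_a + pc) / (mean_b + pc))


def log2fc_screen(matrix: CountMatrix, params: ScreenParams = ScreenParams()) -> pd.DataFrame:
    """Per-site normalized group means, log2FC(A/B) and the flag
    |log2FC| > lfc_cutoff (strict).  Conditions are ordered alphabetically,
    so with labels M1/M2 the ratio is M1/M2."""
    a, b, cols_a, cols_b = _group_columns(matrix)
    normed = matrix.counts / size_factors(matrix)
    lfc = _log2fc(normed, cols_a, cols_b, params.pseudocount)
    return pd.DataFrame(
        {
            "site": matrix.site_ids,
            f"mean_{a}": normed[:, cols_a].mean(axis=1),
            f"mean_{b}": normed[:, cols_b].mean(axis=1),
            "log2fc": lfc,
            "flagged": np.abs(lfc) > params.lfc_cutoff,
        }
    )


def permutation_test(matrix: CountMatrix, params: ScreenParams = ScreenParams()) -> np.ndarray:
    """Per-site permutation p-value for the statistic |log2FC|.

    The null is built from relabelings of the samples: every distinct
    assignment of the group-A label (including the observed one) when there
    are at most ``n_permutations``, otherwise that many seeded random draws.
    p = (1 + #{null >= observed}) / (1 + #null).
    """
    _, _, cols_a, cols_b = _group_columns(matrix)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("permutation test needs >= 2 samples per condition")
    n, n_a = len(matrix.samples), len(cols_a)
    normed = matrix.counts / size_factors(matrix)
    observed = np.abs(_log2fc(normed, cols_a, cols_b, params.pseudocount))

    all_splits = list(combinations(range(n), n_a))
    if len(all_splits) <= params.n_permutations:
        splits = all_splits
    else:
        rng = np.random.default_rng(params.seed)
        splits = [tuple(rng.permutation(n)[:n_a]) for _ in range(params.n_permutations)]

    exceed = np.zeros(len(observed), dtype=int)
    idx = np.arange(n)
    for split in splits:
        pa = np.asarray(split)
        pb = idx[~np.isin(idx, pa)]
        null = np.abs(_log2fc(normed, pa, pb, params.pseudocount))
        exceed += null >= observed
    return (1 + exceed) / (1 + len(splits))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def apply_de_filter(stats: pd.DataFrame, params: ScreenParams = ScreenParams()) -> pd.DataFrame:
    """Rows with padj < padj_cutoff AND |log2fc| > lfc_cutoff, both strict;
    row order preserved.  This is the generic selection rule also applied to
    externally computed differential-expression tables."""
    for col in ("padj", "log2fc"):
        if col not in stats.columns:
            raise ValueError(f"missing required column: {col!r}")
    keep = (stats["padj"] < params.padj_cutoff) & (stats["log2fc"].abs() > params.lfc_cutoff)
    return stats.loc[keep]


def run_screen(
    matrix: CountMatrix,
    params: ScreenParams = ScreenParams(),
    permutations: bool = True,
) -> pd.DataFrame:
    """Full screen table: log2FC flagging plus (optionally) permutation
    p-values and their BH adjustment; ``flagged`` then additionally requires
    padj < padj_cutoff."""
    table = log2fc_screen(matrix, params)
    if permutations:
        table["perm_p"] = permutation_test(matrix, params)
        table["padj"] = bh_adjust(table["perm_p"].to_numpy())
        table["flagged"] = table["flagged"] & (table["padj"] < params.padj_cutoff)
    return table
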