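"""Shared statistical machinery.

Every correlation screen in the package follows the same recipe: quantile
normalize the two feature-by-subclass matrices, compute Pearson
correlations over a list of feature pairs, build a null by shuffling
feature rows *within each subclass column* (which breaks the genomic
pairing while preserving subclass-level global differences), fit a single
normal distribution to the pooled shuffled correlations for smooth small-p
estimation, and control FDR with Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "NullModel",
    "CorrelationResult",
    "quantile_normalize",
    "pearson",
    "pairwise_pearson",
    "build_shuffle_null",
    "empirical_null_pvalues",
    "normal_p",
    "bh_fdr",
    "correlation_screen",
]


@dataclass(frozen=True)
class NullModel:
    """Normal approximation of a within-column shuffle null for PCCs."""

    mean: float
    sd: float
    n_shuffles: int
    seed: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("null sd must be >= 0")
        if self.n_shuffles < 1:
            raise ValueError("n_shuffles must be >= 1")


def quantile_normalize(matrix, axis: int = 1):
    """Quantile normalize a features x samples matrix along samples.

    After normalization every column holds the same multiset of values
    (the across-column mean of order statistics), reassigned by each
    column's within-column ranks.  Tied values receive the mean of their
    span of target values, which keeps the operation deterministic and
    idempotent.
    """
    df_in = isinstance(matrix, pd.DataFrame)
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D features x samples matrix")
    if axis == 0:
        out = quantile_normalize(X.T).T
        if df_in:
            out = pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
        return out
    n_feat, n_samp = X.shape
    if n_samp < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    if np.isnan(X).all(axis=0).any():
        raise ValueError("all-missing column")
    order = np.argsort(X, axis=0, kind="stable")
    ref = np.mean(np.take_along_axis(X, order, axis=0), axis=1)
    out = np.empty_like(X)
    for j in range(n_samp):
        col_sorted_ref = ref  # target order statistics, shared by columns
        col = X[:, j]
        idx = order[:, j]
        vals = col[idx]
        # group ties in the sorted column; each group gets the mean target
        boundaries = np.flatnonzero(np.diff(vals) != 0) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [n_feat]))
        assigned = np.empty(n_feat)
        csum = np.concatenate(([0.0], np.cumsum(col_sorted_ref)))
        for s, e in zip(starts, ends):
            assigned[s:e] = (csum[e] - csum[s]) / (e - s)
        out[idx, j] = assigned
    if df_in:
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


def pearson(x, y) -> float:
    """Product-moment correlation; NaN for constant or too-short input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    if x.size < 3:
        raise ValueError("need length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=1, keepdims=True)
    sd = Xc.std(axis=1)
    sd[sd == 0] = np.nan
    return Xc / sd[:, None]


def pairwise_pearson(A: np.ndarray, B: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    """PCC across columns for each (row of A, row of B) pair.

    ``pairs`` is an (n, 2) integer array of row indices.  Pairs involving a
    constant row come back NaN.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    pairs = np.asarray(pairs)
    if pairs.size == 0:
        return np.empty(0)
    Az = _standardize_rows(A)
    Bz = _standardize_rows(B)
    n = A.shape[1]
    return np.einsum("ij,ij->i", Az[pairs[:, 0]], Bz[pairs[:, 1]]) / n


def _shuffle_within_columns(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = np.empty_like(X)
    n = X.shape[0]
    for j in range(X.shape[1]):
        out[:, j] = X[rng.permutation(n), j]
    return out


def build_shuffle_null(
    A,
    B,
    pairs,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> NullModel:
    """Fit a pooled normal null for PCCs by within-column row shuffling.

    Feature rows of A and of B are independently permuted within every
    sample column; PCCs are recomputed over ``pairs`` and pooled over all
    shuffles.  One pooled null serves the whole analysis family.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    pairs = np.asarray(pairs)
    if pairs.size == 0:
        raise ValueError("empty pair list")
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    rng = np.random.default_rng(seed)
    # accumulate pooled moments instead of materializing all samples
    total = 0.0
    total_sq = 0.0
    count = 0
    for _ in range(n_shuffles):
        pcc = pairwise_pearson(
            _shuffle_within_columns(A, rng), _shuffle_within_columns(B, rng), pairs
        )
        pcc = pcc[np.isfinite(pcc)]
        total += pcc.sum()
        total_sq += (pcc**2).sum()
        count += pcc.size
    if count == 0:
        raise ValueError("all shuffled correlations undefined")
    mean = total / count
    var = max(total_sq / count - mean**2, 0.0)
    return NullModel(mean=mean, sd=float(np.sqrt(var)), n_shuffles=n_shuffles, seed=seed)


def empirical_null_pvalues(
    A,
    B,
    pairs,
    observed: np.ndarray,
    n_shuffles: int,
    seed: int = 0,
) -> np.ndarray:
    """Two-sided empirical p-values against the pooled shuffle null.

    Exceedances of |shuffled - null mean| over |observed - null mean| are
    counted on the fly (the pooled sample is never stored), so very large
    shuffle counts stay cheap in memory.  Uses the add-one permutation
    correction.
    """
    pairs = np.asarray(pairs)
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    observed = np.asarray(observed, dtype=float)
    rng = np.random.default_rng(seed)
    null_sum = 0.0
    null_n = 0
    chunks = []
    for _ in range(n_shuffles):
        pcc = pairwise_pearson(
            _shuffle_within_columns(A, rng), _shuffle_within_columns(B, rng), pairs
        )
        pcc = pcc[np.isfinite(pcc)]
        chunks.append(pcc.astype(np.float32))
        null_sum += pcc.sum()
        null_n += pcc.size
    null = np.abs(np.concatenate(chunks) - null_sum / null_n)
    null.sort()
    dev = np.abs(observed - null_sum / null_n)
    exceed = null.size - np.searchsorted(null, dev, side="left")
    return (1.0 + exceed) / (1.0 + null.size)


def normal_p(observed_pcc, null: NullModel) -> np.ndarray | float:
    """Two-sided p-value from the fitted normal null; in (0, 1]."""
    if null.sd <= 0:
        raise ValueError("null sd must be > 0")
    z = (np.asarray(observed_pcc, dtype=float) - null.mean) / null.sd
    p = np.clip(2.0 * sps.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)
    return float(p) if np.isscalar(observed_pcc) else p


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, monotone and clipped to 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.empty(0)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def correlation_screen(
    A,
    B,
    pairs,
    ids_a,
    ids_b,
    n_shuffles: int = 1000,
    seed: int = 0,
    null: NullModel | None = None,
) -> pd.DataFrame:
    """Full family screen: PCC per pair, pooled shuffle null, normal p, BH q.

    Pairs with undefined PCC (constant rows) are excluded from the family
    before FDR correction.  Returns a tidy CorrelationResult frame with
    columns (feature_a, feature_b, pcc, p, q).
    """
    pairs = np.asarray(pairs)
    pcc = pairwise_pearson(A, B, pairs)
    keep = np.isfinite(pcc)
    if null is None:
        null = build_shuffle_null(A, B, pairs, n_shuffles=n_shuffles, seed=seed)
    p = normal_p(pcc[keep], null)
    q = bh_fdr(p)
    ids_a = np.asarray(ids_a, dtype=object)
    ids_b = np.asarray(ids_b, dtype=object)
    return pd.DataFrame(
        {
            "feature_a": ids_a[pairs[keep, 0]],
            "feature_b": ids_b[pairs[keep, 1]],
            "pcc": pcc[keep],
            "p": p,
            "q": q,
        }
    )
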