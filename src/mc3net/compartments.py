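"""A/B compartment scoring at 100 kb and its methylation correlation.

Per chromosome, each subclass's group matrix is distance-normalized
(observed/expected per diagonal) and turned into a bin-by-bin Pearson
correlation matrix.  The rows of all subclasses' correlation matrices
are pooled as observations to fit one shared two-component PCA
(incrementally, one subclass batch at a time), so every subclass is
scored with the same loadings.  The component correlating most strongly
with CpG density is the compartment score, signed so that high-CpG bins
(A compartment) are positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA, IncrementalPCA

from . import core_stats
from .utils import blacklist_bin_mask

__all__ = [
    "BinCoverage",
    "CompartmentScoreTrack",
    "filter_bins",
    "distance_normalize",
    "correlation_matrix",
    "compartment_scores",
    "compartment_mc_correlation",
]


@dataclass
class BinCoverage:
    chrom: str
    row_sums: np.ndarray  # R_c,i: row sum of the group matrix at bin i


@dataclass
class CompartmentScoreTrack:
    chrom: str
    scores: pd.DataFrame  # kept bins x subclasses
    component: int  # 0-based index of the chosen PC (0 or 1)
    sign: int
    kept_bins: np.ndarray

    @property
    def std(self) -> pd.Series:
        """Per-bin standard deviation of the score across subclasses."""
        return self.scores.std(axis=1, ddof=0)


def filter_bins(
    coverage: BinCoverage,
    blacklist: list[tuple[str, int, int]] | None = None,
    chrom_length: int | None = None,
    resolution: int = 100_000,
) -> np.ndarray:
    """Keep bins with 2*median(R) - Q99(R) <= R_i <= Q99(R), minus blacklist.

    The percentile and median are computed on non-blacklisted bins.
    """
    R = np.asarray(coverage.row_sums, dtype=float)
    if R.size < 10:
        raise ValueError("need at least 10 bins per chromosome")
    bl = blacklist_bin_mask(blacklist, coverage.chrom, chrom_length or R.size * resolution, resolution)
    usable = ~bl
    vals = R[usable]
    q99 = np.percentile(vals, 99)
    lo = 2 * np.median(vals) - q99
    keep = usable & (R >= lo) & (R <= q99)
    if not keep.any():
        raise ValueError("all bins filtered")
    return keep


def distance_normalize(matrix: np.ndarray) -> np.ndarray:
    """Observed/expected: divide each entry by its diagonal's mean."""
    M = np.asarray(matrix, dtype=float)
    n = M.shape[0]
    if M.shape[0] != M.shape[1]:
        raise ValueError("matrix must be square")
    out = np.zeros_like(M)
    idx = np.arange(n)
    offs = idx[None, :] - idx[:, None]
    for d in range(-(n - 1), n):
        diag = np.diagonal(M, offset=d)
        mu = diag.mean()
        if mu != 0:
            sel = offs == d
            out[sel] = M[sel] / mu
    return out


def correlation_matrix(matrix: np.ndarray) -> np.ndarray:
    """Bin-by-bin PCC matrix; rows with zero variance yield zero entries."""
    M = np.asarray(matrix, dtype=float)
    sd = M.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(M)
    C = np.nan_to_num(C, nan=0.0)
    C[sd == 0, :] = 0.0
    C[:, sd == 0] = 0.0
    return C


def compartment_scores(
    group_matrices: dict[str, np.ndarray],
    cpg_density: np.ndarray,
    chrom: str = "",
    keep: np.ndarray | None = None,
    incremental: bool = True,
) -> CompartmentScoreTrack:
    """Shared-loading compartment scores for all subclasses of one chromosome.

    ``group_matrices`` maps subclass -> group contact matrix (full bins);
    ``keep`` is the kept-bin mask from :func:`filter_bins` (all bins if
    None).  ``incremental=False`` fits an exact PCA on the pooled rows
    instead of sklearn's IncrementalPCA (used for oracle equivalence).
    """
    subclasses = list(group_matrices)
    if len(subclasses) < 2:
        raise ValueError("need at least 2 subclasses")
    any_mat = next(iter(group_matrices.values()))
    n = any_mat.shape[0]
    if keep is None:
        keep = np.ones(n, dtype=bool)
    if keep.sum() < 3:
        raise ValueError("fewer than 3 kept bins")
    corr = {}
    for s, m in group_matrices.items():
        sub = np.asarray(m)[np.ix_(keep, keep)]
        corr[s] = correlation_matrix(distance_normalize(sub))
    if incremental:
        pca = IncrementalPCA(n_components=2)
        for s in subclasses:
            pca.partial_fit(corr[s])
    else:
        pca = PCA(n_components=2)
        pca.fit(np.vstack([corr[s] for s in subclasses]))
    proj = {s: pca.transform(corr[s]) for s in subclasses}
    cpg = np.asarray(cpg_density, dtype=float)[keep]
    # choose PC1 vs PC2 by pooled |corr with CpG density|, then orient
    pooled = {k: np.concatenate([proj[s][:, k] for s in subclasses]) for k in (0, 1)}
    cpg_pooled = np.tile(cpg, len(subclasses))
    cors = {k: np.corrcoef(pooled[k], cpg_pooled)[0, 1] for k in (0, 1)}
    cors = {k: 0.0 if np.isnan(v) else v for k, v in cors.items()}
    comp = 0 if abs(cors[0]) >= abs(cors[1]) else 1
    sign = 1 if cors[comp] >= 0 else -1
    scores = pd.DataFrame(
        {s: sign * proj[s][:, comp] for s in subclasses}, index=np.flatnonzero(keep)
    )
    return CompartmentScoreTrack(chrom=chrom, scores=scores, component=comp, sign=sign, kept_bins=np.flatnonzero(keep))


def compartment_mc_correlation(
    track: CompartmentScoreTrack,
    bin_mc: pd.DataFrame,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-bin PCC between compartment score and mC fraction across subclasses.

    Both matrices are quantile normalized along subclasses first.  Bins
    with a constant score or fraction are skipped.  The per-bin
    cross-subclass score standard deviation is reported alongside.
    """
    common = track.scores.index.intersection(bin_mc.index)
    if len(track.scores.columns) < 3:
        raise ValueError("need at least 3 subclasses for per-bin correlation")
    S = track.scores.loc[common, :]
    M = bin_mc.loc[common, S.columns]
    Sq = core_stats.quantile_normalize(S.to_numpy())
    Mq = core_stats.quantile_normalize(M.to_numpy())
    pairs = np.column_stack([np.arange(len(common))] * 2)
    res = core_stats.correlation_screen(
        Sq, Mq, pairs, np.asarray(common), np.asarray(common), n_shuffles=n_shuffles, seed=seed
    )
    res = res.rename(columns={"feature_a": "bin"}).drop(columns="feature_b")
    std = track.scores.loc[common].std(axis=1, ddof=0)
    res["score_std"] = std.loc[res["bin"]].to_numpy()
    return res
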