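"""Per-cell contact matrices: binning, imputation, aggregation.

Raw matrices accumulate cis-long contact pairs (anchor separation
> 2,500 bp) into symmetric per-chromosome bin matrices at 100 kb, 25 kb
or 10 kb.  Imputation smooths each sparse single-cell matrix with a
uniform (2*pad+1)^2 mean filter ("Gaussian convolution, pad=1" in the
originating single-cell Hi-C practice) and then runs a random walk with
restart on the row-normalized result.  Imputed matrices are band-limited:
whole chromosome at 100 kb, 10.05 Mb at 25 kb, 5.05 Mb at 10 kb.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage, sparse

__all__ = [
    "CellContactMatrix",
    "GroupContactMatrix",
    "DEFAULT_BANDS_BP",
    "bin_contact_pairs",
    "convolve",
    "random_walk_impute",
    "impute_cell",
    "aggregate_group",
    "band_mask",
    "write_coo_tsv",
]

#: imputation band per resolution (bp); None = whole chromosome
DEFAULT_BANDS_BP: dict[int, int | None] = {100_000: None, 25_000: 10_050_000, 10_000: 5_050_000}
MIN_CIS_DISTANCE = 2_500


@dataclass
class CellContactMatrix:
    cell_id: str
    chrom: str
    resolution: int
    matrix: np.ndarray | sparse.spmatrix  # symmetric, n_bins x n_bins
    band_bp: int | None = None
    stage: str = "raw"

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def dense(self) -> np.ndarray:
        m = self.matrix
        return m.toarray() if sparse.issparse(m) else np.asarray(m)


@dataclass
class GroupContactMatrix:
    group: str
    chrom: str
    resolution: int
    matrix: np.ndarray
    n_cells: int
    band_bp: int | None = None


def bin_contact_pairs(
    pos_a: np.ndarray,
    pos_b: np.ndarray,
    chrom: str,
    chrom_length: int,
    resolution: int,
    cell_id: str = "",
    min_cis_distance: int = MIN_CIS_DISTANCE,
) -> CellContactMatrix:
    """Accumulate cis pairs of one cell/chromosome into a symmetric matrix.

    Pairs with |pos_a - pos_b| <= ``min_cis_distance`` are discarded
    (cis-short contacts); trans pairs never reach this function because a
    matrix is per chromosome by construction.
    """
    if resolution not in DEFAULT_BANDS_BP:
        raise ValueError(f"unsupported resolution {resolution}")
    pos_a = np.asarray(pos_a, dtype=np.int64)
    pos_b = np.asarray(pos_b, dtype=np.int64)
    if pos_a.shape != pos_b.shape:
        raise ValueError("pos_a and pos_b must have equal length")
    if pos_a.size and (
        pos_a.min() < 0 or pos_b.min() < 0 or max(pos_a.max(), pos_b.max()) >= chrom_length
    ):
        raise ValueError("contact position outside chromosome bounds")
    n = -(-chrom_length // resolution)
    keep = np.abs(pos_a - pos_b) > min_cis_distance
    bi = pos_a[keep] // resolution
    bj = pos_b[keep] // resolution
    m = sparse.coo_matrix(
        (np.ones(bi.size), (bi, bj)), shape=(n, n)
    ).tocsr()
    m = m + m.T  # symmetrize; diagonal pairs (bi == bj) count twice like off-diagonal mirrors
    return CellContactMatrix(cell_id, chrom, resolution, m, band_bp=None, stage="raw")


def convolve(matrix, pad: int = 1, sigma: float | None = None) -> np.ndarray:
    """Neighborhood smoothing with zero padding at the edges.

    Default is the (2*pad+1)^2 uniform mean filter; pass ``sigma`` for a
    true Gaussian kernel instead.
    """
    if pad < 0:
        raise ValueError("pad must be >= 0")
    dense = matrix.toarray() if sparse.issparse(matrix) else np.asarray(matrix)
    if not np.issubdtype(dense.dtype, np.floating):
        dense = dense.astype(float)
    if pad == 0 and sigma is None:
        return dense
    if sigma is not None:
        return ndimage.gaussian_filter(dense, sigma=sigma, mode="constant", cval=0.0)
    return ndimage.uniform_filter(dense, size=2 * pad + 1, mode="constant", cval=0.0)


from functools import lru_cache


@lru_cache(maxsize=8)
def _band_mask_cached(n: int, resolution: int, band_bp: int) -> np.ndarray:
    idx = np.arange(n)
    return (np.abs(idx[None, :] - idx[:, None]) * resolution) <= band_bp


def band_mask(n: int, resolution: int, band_bp: int | None) -> np.ndarray:
    """Boolean mask of pixels whose anchor distance is within the band."""
    if band_bp is None:
        return np.ones((n, n), dtype=bool)
    return _band_mask_cached(n, resolution, band_bp)


def random_walk_impute(
    matrix,
    restart_p: float = 0.5,
    tol: float = 1e-6,
    max_iter: int = 500,
    resolution: int = 10_000,
    band_bp: int | None = "default",
    method: str = "direct",
    cell_id: str = "",
    chrom: str = "",
    dtype=np.float64,
) -> CellContactMatrix:
    """Random walk with restart on the convolved matrix.

    The transition matrix P is the row-normalized input (all-zero rows
    keep the walker at its start bin).  Scores from all start bins solve
    S = restart_p * I + (1 - restart_p) * S @ P.  ``method='direct'``
    solves the equivalent linear system exactly; ``method='iterative'``
    iterates to max-abs change < ``tol`` (the two agree within the
    tolerance — see the oracle-equivalence tests).  The result is
    symmetrized as (S + S.T) / 2 and masked to the resolution's band.
    """
    if not 0 < restart_p <= 1:
        raise ValueError("restart_p must be in (0, 1]")
    dense = matrix.toarray() if sparse.issparse(matrix) else np.asarray(matrix, dtype=float)
    if not np.any(dense):
        raise ValueError("empty cell: all-zero contact matrix")
    n = dense.shape[0]
    rowsum = dense.sum(axis=1)
    P = np.zeros_like(dense, dtype=dtype)
    nz = rowsum > 0
    P[nz] = dense[nz] / rowsum[nz, None]
    P[~nz, ~nz] = 1.0  # stranded walker restarts at itself

    if restart_p == 1.0:
        S = np.eye(n, dtype=dtype)
    elif method == "direct":
        # S = restart_p * (I - (1-restart_p) P)^-1, via one LU solve
        A = np.eye(n, dtype=dtype) - (1.0 - restart_p) * P
        from scipy.linalg import solve

        S = restart_p * solve(A.T, np.eye(n, dtype=dtype), assume_a="gen").T
    elif method == "iterative":
        S = np.full((n, n), restart_p / n, dtype=dtype)
        rI = restart_p * np.eye(n, dtype=dtype)
        q = 1.0 - restart_p
        for _ in range(max_iter):
            S_new = rI + q * (S @ P)
            delta = np.abs(S_new - S).max()
            S = S_new
            if delta < tol:
                break
        else:
            warnings.warn("random walk did not converge; returning best iterate")
    else:
        raise ValueError(f"unknown method {method!r}")

    S = (S + S.T) / 2.0
    if band_bp == "default":
        band_bp = DEFAULT_BANDS_BP[resolution]
    if band_bp is not None:
        S = S * band_mask(n, resolution, band_bp)
    return CellContactMatrix(cell_id, chrom, resolution, S, band_bp=band_bp, stage="imputed")


def impute_cell(
    raw: CellContactMatrix,
    pad: int = 1,
    restart_p: float = 0.5,
    tol: float = 1e-6,
    max_iter: int = 500,
    method: str = "direct",
    dtype=np.float64,
) -> CellContactMatrix:
    """Convolution followed by random walk with restart for one raw matrix."""
    m = raw.matrix.astype(dtype) if sparse.issparse(raw.matrix) else np.asarray(raw.matrix, dtype=dtype)
    conv = convolve(m, pad=pad)
    return random_walk_impute(
        conv,
        restart_p=restart_p,
        tol=tol,
        max_iter=max_iter,
        resolution=raw.resolution,
        method=method,
        cell_id=raw.cell_id,
        chrom=raw.chrom,
        dtype=dtype,
    )


def aggregate_group(cells: list[CellContactMatrix], labels: list[str]) -> dict[str, GroupContactMatrix]:
    """Element-wise mean of member cells' imputed matrices per label."""
    if len(cells) != len(labels):
        raise ValueError("labels must match cells")
    if not cells:
        raise ValueError("no cells to aggregate")
    ref = cells[0]
    sums: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    for cell, lab in zip(cells, labels):
        if (cell.chrom, cell.resolution, cell.band_bp) != (ref.chrom, ref.resolution, ref.band_bp):
            raise ValueError("cells disagree on chromosome/resolution/band")
        d = cell.dense()
        if lab in sums:
            if d.shape != sums[lab].shape:
                raise ValueError("mismatched matrix dimensions")
            sums[lab] += d
        else:
            sums[lab] = d.astype(np.float64, copy=True)
        counts[lab] = counts.get(lab, 0) + 1
    return {
        lab: GroupContactMatrix(lab, ref.chrom, ref.resolution, sums[lab] / counts[lab], counts[lab], ref.band_bp)
        for lab in sums
    }


def write_coo_tsv(matrix, path: str | Path, header: str = "# coordinates: 0-based bins\n") -> Path:
    """Upper-triangle COO TSV (bin1, bin2, value) for a symmetric matrix."""
    dense = matrix.toarray() if sparse.issparse(matrix) else np.asarray(matrix)
    rows, cols = np.nonzero(np.triu(dense))
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(header)
        fh.write("bin1\tbin2\tvalue\n")
        for i, j in zip(rows.tolist(), cols.tolist()):
            fh.write(f"{i}\t{j}\t{dense[i, j]:.6g}\n")
    return path
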