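"""Domain-boundary calling at 25 kb and downstream statistics.

Boundaries are called per cell with a TopDom-style detector: the
``binSignal`` of bin i is the mean of the w x w diamond of contacts
between the w bins upstream (ending at i) and the w bins downstream
(starting at i+1); local minima of the signal within +/- w bins are
candidate boundaries, kept when a one-sided rank-sum test finds the
diamond significantly weaker than the flanking within-domain contacts.
Boundary probability per group is the fraction of member cells calling
the bin; differential boundaries are flagged by a per-bin chi-square
test on the groups x {boundary, not} contingency table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import core_stats
from .utils import blacklist_bin_mask

__all__ = [
    "BoundaryCallMatrix",
    "BoundaryProbabilityTrack",
    "topdom_boundaries",
    "boundary_probability",
    "differential_boundary_test",
    "collapse_transcripts",
    "transcript_boundary_correlation",
]


@dataclass
class BoundaryCallMatrix:
    calls: np.ndarray  # cells x bins, bool
    cell_ids: list[str]
    window: int


@dataclass
class BoundaryProbabilityTrack:
    prob: pd.DataFrame  # groups x bins
    n_cells: pd.Series  # per group


def _diamond_values(matrix: np.ndarray, i: int, w: int) -> np.ndarray:
    n = matrix.shape[0]
    up = slice(max(0, i - w + 1), i + 1)
    down = slice(i + 1, min(n, i + w + 1))
    return matrix[up, down].ravel()


def _within_values(matrix: np.ndarray, i: int, w: int) -> np.ndarray:
    n = matrix.shape[0]
    lo, hi = max(0, i - w + 1), min(n, i + w + 1)
    up = np.arange(lo, i + 1)
    down = np.arange(i + 1, hi)
    vals = []
    for block in (up, down):
        if block.size >= 2:
            sub = matrix[np.ix_(block, block)]
            iu = np.triu_indices(block.size, k=1)
            vals.append(sub[iu])
    return np.concatenate(vals) if vals else np.empty(0)


def topdom_boundaries(
    matrix: np.ndarray,
    w: int = 5,
    alpha: float = 0.05,
    blacklist_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Per-bin boolean boundary calls for one imputed 25-kb cell matrix."""
    M = np.asarray(matrix, dtype=float)
    n = M.shape[0]
    if w < 2:
        raise ValueError("window must be >= 2")
    if n < 2 * w:
        raise ValueError("matrix smaller than 2*w bins")
    # diamond means via a summed-area table
    sat = np.zeros((n + 1, n + 1))
    sat[1:, 1:] = M.cumsum(0).cumsum(1)

    def _rect_sum(r0, r1, c0, c1):  # half-open [r0, r1) x [c0, c1)
        return sat[r1, c1] - sat[r0, c1] - sat[r1, c0] + sat[r0, c0]

    # full w x w windows only: clipped windows at the chromosome ends distort
    # the signal and produce spurious edge minima
    signal = np.full(n, np.nan)
    for i in range(w - 1, n - w):
        r0, r1 = i - w + 1, i + 1
        c0, c1 = i + 1, i + w + 1
        signal[i] = _rect_sum(r0, r1, c0, c1) / (w * w)

    calls = np.zeros(n, dtype=bool)
    for i in range(w - 1, n - w):
        lo, hi = max(0, i - w), min(n, i + w + 1)
        window = signal[lo:hi]
        window = window[np.isfinite(window)]
        if window.size == 0 or not np.isfinite(signal[i]):
            continue
        if signal[i] > window.min() or np.all(window == signal[i]):
            continue
        diamond = _diamond_values(M, i, w)
        within = _within_values(M, i, w)
        if diamond.size == 0 or within.size == 0:
            continue
        if np.all(diamond == diamond[0]) and np.all(within == diamond[0]):
            continue
        p = sps.mannwhitneyu(diamond, within, alternative="less").pvalue
        calls[i] = p < alpha
    if blacklist_mask is not None:
        calls &= ~np.asarray(blacklist_mask, dtype=bool)
    return calls


def boundary_probability(calls: np.ndarray, labels: list[str]) -> BoundaryProbabilityTrack:
    """Fraction of a group's cells calling each bin a boundary."""
    calls = np.asarray(calls, dtype=bool)
    labels = np.asarray(labels)
    groups = sorted(set(labels.tolist()))
    rows, ns = [], []
    for g in groups:
        sel = labels == g
        if not sel.any():
            raise ValueError(f"group {g} has no cells")
        rows.append(calls[sel].mean(axis=0))
        ns.append(int(sel.sum()))
    prob = pd.DataFrame(np.vstack(rows), index=groups)
    return BoundaryProbabilityTrack(prob=prob, n_cells=pd.Series(ns, index=groups))


def differential_boundary_test(
    calls: np.ndarray,
    labels: list[str],
    q_threshold: float = 1e-3,
) -> pd.DataFrame:
    """Chi-square test of the groups x {boundary, not} table per bin."""
    calls = np.asarray(calls, dtype=bool)
    labels = np.asarray(labels)
    groups = sorted(set(labels.tolist()))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    B = np.vstack([calls[labels == g].sum(axis=0) for g in groups]).astype(float)
    n_g = np.array([(labels == g).sum() for g in groups], dtype=float)[:, None]
    if (n_g == 0).any():
        raise ValueError("group with zero cells")
    N = n_g.sum()
    pbar = B.sum(axis=0) / N  # per bin
    with np.errstate(invalid="ignore", divide="ignore"):
        E1 = n_g * pbar[None, :]
        E0 = n_g * (1 - pbar)[None, :]
        chi2 = np.nansum((B - E1) ** 2 / E1, axis=0) + np.nansum(
            ((n_g - B) - E0) ** 2 / E0, axis=0
        )
    degenerate = (pbar == 0) | (pbar == 1)
    chi2[degenerate] = 0.0
    min_e = np.minimum(E1, E0).min()
    if min_e < 5:
        warnings.warn("expected counts < 5 in some contingency cells")
    p = sps.chi2.sf(chi2, df=len(groups) - 1)
    p[degenerate] = 1.0
    q = core_stats.bh_fdr(p)
    return pd.DataFrame(
        {"bin": np.arange(calls.shape[1]), "chi2": chi2, "p": p, "q": q, "variable": q < q_threshold}
    )


def collapse_transcripts(
    transcripts: list[tuple[str, str, str, int, int, str]],
    min_overlap: float = 0.9,
) -> list[tuple[str, str, str, int, int, str]]:
    """Group same-gene transcripts overlapping > ``min_overlap`` of the
    shorter one; each group is represented by its longest spanned range."""
    by_gene: dict[str, list] = {}
    for rec in transcripts:
        by_gene.setdefault(rec[1], []).append(rec)
    out = []
    for gene, recs in by_gene.items():
        recs = sorted(recs, key=lambda r: (r[2], r[3], r[4]))
        clusters: list[list] = []
        for rec in recs:
            placed = False
            for cl in clusters:
                _, _, chrom, start, end, _ = cl[0]
                if rec[2] != chrom:
                    continue
                inter = min(end, rec[4]) - max(start, rec[3])
                shorter = min(end - start, rec[4] - rec[3])
                if inter > min_overlap * shorter:
                    cl.append(rec)
                    cl[0] = (cl[0][0], gene, chrom, min(start, rec[3]), max(end, rec[4]), cl[0][5])
                    placed = True
                    break
            if not placed:
                clusters.append([rec])
        for cl in clusters:
            out.append(cl[0])
    return sorted(out, key=lambda r: (r[2], r[3]))


def transcript_boundary_correlation(
    transcript_mc: pd.DataFrame,
    track: BoundaryProbabilityTrack,
    transcripts: list[tuple[str, str, str, int, int, str]],
    variable_bins: np.ndarray,
    chrom: str,
    resolution: int = 25_000,
    window_bp: int = 2_000_000,
    n_shuffles: int = 1000,
    seed: int = 0,
    q_threshold: float = 1e-3,
) -> pd.DataFrame:
    """PCC between transcript-body mC and boundary probability of variable
    bins within the transcript body +/- 2 Mb, with shuffle-null FDR."""
    prob = track.prob.T  # bins x subclasses
    subclasses = [s for s in transcript_mc.columns if s in prob.columns]
    A = core_stats.quantile_normalize(transcript_mc[subclasses].to_numpy())
    B = core_stats.quantile_normalize(prob[subclasses].to_numpy())
    tids = list(transcript_mc.index)
    tpos = {rec[0]: rec for rec in transcripts}
    variable_bins = np.asarray(sorted(set(np.asarray(variable_bins).tolist())), dtype=int)
    pairs = []
    for ti, tid in enumerate(tids):
        rec = tpos.get(tid)
        if rec is None or rec[2] != chrom:
            continue
        lo = (rec[3] - window_bp) // resolution
        hi = (rec[4] + window_bp - 1) // resolution
        sel = variable_bins[(variable_bins >= lo) & (variable_bins <= hi)]
        pairs.extend((ti, int(b)) for b in sel)
    if not pairs:
        return pd.DataFrame(columns=["transcript", "bin", "pcc", "p", "q", "significant"])
    res = core_stats.correlation_screen(
        A,
        B,
        np.asarray(pairs),
        np.asarray(tids, dtype=object),
        np.asarray(prob.index),
        n_shuffles=n_shuffles,
        seed=seed,
    )
    res = res.rename(columns={"feature_a": "transcript", "feature_b": "bin"})
    res["significant"] = res["q"] < q_threshold
    return res
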