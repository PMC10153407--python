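"""Highly variable 10-kb interactions and their methylation correlation.

Each interaction is one pixel of the imputed 10-kb contact map with
anchor distance between 50 kb and 5 Mb.  A one-way ANOVA across cell
subclasses on the single-cell (imputed) contact strengths measures
interaction variability; pixels with F > 3 and BH FDR < 0.001 are the
highly variable interactions (HVIs).  HVIs with an anchor overlapping a
transcript body are correlated with the transcript's mCH fraction at
group level, and significant pairs are categorized by anchor position
relative to the gene: I, U, D, U-I, D-I, U-D.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import core_stats
from .utils import blacklist_bin_mask, intervals_overlap

__all__ = [
    "band_pixels",
    "interaction_anova",
    "select_hvi",
    "categorize_interaction",
    "interaction_mc_correlation",
]

MIN_DISTANCE_BP = 50_000
MAX_DISTANCE_BP = 5_000_000
CATEGORIES = ("I", "U", "D", "U-I", "D-I", "U-D")


def band_pixels(
    n_bins: int,
    resolution: int = 10_000,
    min_bp: int = MIN_DISTANCE_BP,
    max_bp: int = MAX_DISTANCE_BP,
) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle pixel indices with min_bp <= anchor distance <= max_bp."""
    rows, cols = [], []
    d_lo = -(-min_bp // resolution)
    d_hi = max_bp // resolution
    for d in range(d_lo, min(d_hi, n_bins - 1) + 1):
        i = np.arange(n_bins - d)
        rows.append(i)
        cols.append(i + d)
    return np.concatenate(rows), np.concatenate(cols)


def interaction_anova(
    values: np.ndarray,
    labels: list[str],
    rows: np.ndarray,
    cols: np.ndarray,
    resolution: int = 10_000,
    chrom: str = "",
    blacklist: list[tuple[str, int, int]] | None = None,
    chrom_length: int | None = None,
) -> pd.DataFrame:
    """One-way ANOVA per pixel over single-cell contact strengths.

    ``values`` is cells x pixels (imputed strengths at the band pixels
    given by ``rows``/``cols``).  Pixels with an anchor in the blacklist
    are dropped before testing.  Zero within-group variance with
    distinct group means yields an infinite F (p underflows to 0).
    """
    values = np.asarray(values)
    labels = np.asarray(labels)
    groups = sorted(set(labels.tolist()))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    rows = np.asarray(rows)
    cols = np.asarray(cols)
    keep = np.ones(rows.size, dtype=bool)
    if blacklist and chrom_length:
        bl = blacklist_bin_mask(blacklist, chrom, chrom_length, resolution)
        keep &= ~bl[rows] & ~bl[cols]
    V = values[:, keep]
    pixel_idx = np.flatnonzero(keep)
    rows, cols = rows[keep], cols[keep]

    N = V.shape[0]
    k = len(groups)
    n_g = np.array([(labels == g).sum() for g in groups], dtype=np.float64)
    if (n_g < 2).any():
        raise ValueError("each group needs >= 2 cells")
    # center by the grand mean first so the sums-of-squares stay stable
    Vc = (V - V.mean(axis=0)).astype(np.float32, copy=False)
    onehot = np.stack([(labels == g) for g in groups]).astype(np.float32)
    gsum = onehot @ Vc  # k x pixels
    ssb = ((gsum**2) / n_g[:, None]).sum(axis=0).astype(np.float64)
    total_ss = np.einsum("ij,ij->j", Vc, Vc, dtype=np.float64)
    ssw = np.maximum(total_ss - ssb, 0.0)
    msb = ssb / (k - 1)
    msw = ssw / (N - k)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = msb / msw
    F[(msw == 0) & (msb == 0)] = 0.0
    F[(msw == 0) & (msb > 0)] = np.inf
    p = np.where(np.isinf(F), 0.0, sps.f.sf(np.where(np.isinf(F), 1.0, F), k - 1, N - k))
    p[F == 0] = 1.0
    q = core_stats.bh_fdr(p)
    return pd.DataFrame(
        {
            "pixel": pixel_idx,  # column index into the cells x band-pixels array
            "bin_i": rows,
            "bin_j": cols,
            "distance_bp": (cols - rows) * resolution,
            "F": F,
            "p": p,
            "q": q,
        }
    )


def select_hvi(table: pd.DataFrame, f_min: float = 3.0, q_max: float = 0.001) -> pd.DataFrame:
    """Flag highly variable interactions: F strictly > f_min AND q < q_max."""
    out = table.copy()
    out["highly_variable"] = (out["F"] > f_min) & (out["q"] < q_max)
    return out


def _anchor_label(
    anchor_start: int, anchor_end: int, tss: int, tts: int, body: tuple[int, int], strand: str
) -> str:
    if intervals_overlap(anchor_start, anchor_end, *body):
        return "I"  # body takes precedence, incl. anchors spanning the TSS
    upstream_of_body = anchor_end <= body[0]
    if strand == "+":
        return "U" if upstream_of_body else "D"
    return "D" if upstream_of_body else "U"


def categorize_interaction(
    bin_i: int,
    bin_j: int,
    transcript: tuple[str, str, str, int, int, str],
    resolution: int = 10_000,
) -> str:
    """Six-way category of an interaction relative to a transcript.

    Each anchor is labelled U (strand-aware 5' of the body), I (within
    the body) or D (3' of the body); the pair label combines the
    unordered anchor labels.
    """
    _, _, _, start, end, strand = transcript
    body = (start, end)
    labels = []
    for b in (bin_i, bin_j):
        a_start, a_end = b * resolution, (b + 1) * resolution
        labels.append(_anchor_label(a_start, a_end, start, end, body, strand))
    la, lb = labels
    if la == lb:
        return la
    return {frozenset(("U", "I")): "U-I", frozenset(("D", "I")): "D-I", frozenset(("U", "D")): "U-D"}[
        frozenset((la, lb))
    ]


def interaction_mc_correlation(
    transcript_mch: pd.DataFrame,
    group_strength: pd.DataFrame,
    hvi_table: pd.DataFrame,
    transcripts: list[tuple[str, str, str, int, int, str]],
    chrom: str,
    resolution: int = 10_000,
    n_shuffles: int = 1000,
    seed: int = 0,
    q_threshold: float = 0.001,
) -> pd.DataFrame:
    """PCC between transcript-body mCH and HVI group contact strength.

    ``group_strength`` is HVI x subclass (rows aligned with the
    ``highly_variable`` rows of ``hvi_table``).  A record is produced for
    every (transcript, HVI) where at least one anchor overlaps the
    transcript body; interactions with constant strength are skipped.
    """
    hvi = hvi_table[hvi_table["highly_variable"]].reset_index(drop=True)
    if len(hvi) != len(group_strength):
        raise ValueError("group_strength rows must align with highly variable interactions")
    subclasses = [s for s in transcript_mch.columns if s in group_strength.columns]
    A = core_stats.quantile_normalize(transcript_mch[subclasses].to_numpy())
    B = core_stats.quantile_normalize(group_strength[subclasses].to_numpy())
    tids = list(transcript_mch.index)
    by_tid = {r[0]: r for r in transcripts}
    bi_arr = hvi["bin_i"].to_numpy()
    bj_arr = hvi["bin_j"].to_numpy()
    pairs, cats = [], []
    for ti, tid in enumerate(tids):
        rec = by_tid.get(tid)
        if rec is None or rec[2] != chrom:
            continue
        start, end = rec[3], rec[4]
        touches = (
            (bi_arr * resolution < end) & (start < (bi_arr + 1) * resolution)
        ) | ((bj_arr * resolution < end) & (start < (bj_arr + 1) * resolution))
        for hi_idx in np.flatnonzero(touches):
            pairs.append((ti, int(hi_idx)))
            cats.append(
                categorize_interaction(int(bi_arr[hi_idx]), int(bj_arr[hi_idx]), rec, resolution)
            )
    cols = ["transcript", "bin_i", "bin_j", "pcc", "p", "q", "significant", "category"]
    if not pairs:
        return pd.DataFrame(columns=cols)
    pairs = np.asarray(pairs)
    res = core_stats.correlation_screen(
        A,
        B,
        pairs,
        np.asarray(tids, dtype=object),
        np.arange(len(hvi)),
        n_shuffles=n_shuffles,
        seed=seed,
    )
    # correlation_screen drops undefined-PCC pairs; realign categories
    cat_map = {(tids[i], j): c for (i, j), c in zip(map(tuple, pairs), cats)}
    res = res.rename(columns={"feature_a": "transcript", "feature_b": "hvi_index"})
    res["bin_i"] = hvi.loc[res["hvi_index"], "bin_i"].to_numpy()
    res["bin_j"] = hvi.loc[res["hvi_index"], "bin_j"].to_numpy()
    res["significant"] = res["q"] < q_threshold
    res["category"] = [cat_map[(t, h)] for t, h in zip(res["transcript"], res["hvi_index"])]
    return res[["transcript", "hvi_index"] + cols[1:]]
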