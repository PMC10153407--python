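"""Differentially methylated site and region calling.

CpG base calls are first combined across the +/- strand pair, then
coverage-downsampled (per-site cap, then across-sample total cap) so the
permutation null is comparable across samples.  The DMS statistic is the
root mean square of per-sample deviations of the methylation fraction
from the pooled mean; its null is obtained by permuting individual base
calls across samples while preserving each sample's coverage (a
sequential hypergeometric allocation of the pooled methylated calls).
Significant sites chain into DMRs when within 250 bp and with adjacent
fraction-vector PCC > 0.3; overlapping DMR sets merge at distance 0 with
representative selection by the strongest statistic.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import core_stats

__all__ = [
    "combine_strand_counts",
    "downsample_counts",
    "rms_test",
    "call_dms",
    "merge_dms",
    "merge_overlapping",
    "select_representative",
]


def combine_strand_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Sum mc/cov over the (pos, +) / (pos+1, -) strand pair of each CpG.

    Input: index (chrom, pos, strand), columns (sample, {mc, cov}).
    Output: one row per CpG pair indexed by (chrom, pos of the + strand).
    Unpaired rows are kept as their own CpG with a warning.
    """
    strands = table.index.get_level_values("strand")
    plus = table[strands == "+"].droplevel("strand")
    minus = table[strands == "-"].droplevel("strand")
    # expected partner of (chrom, pos, +) is (chrom, pos+1, -)
    partner = minus.copy()
    partner.index = pd.MultiIndex.from_arrays(
        [partner.index.get_level_values(0), partner.index.get_level_values(1) - 1],
        names=["chrom", "pos"],
    )
    paired = plus.index.intersection(partner.index)
    combined = plus.loc[paired] + partner.loc[paired]
    orphan_plus = plus.drop(paired)
    orphan_minus = partner.drop(partner.index.intersection(plus.index))
    if len(orphan_plus) or len(orphan_minus):
        warnings.warn(f"{len(orphan_plus) + len(orphan_minus)} unpaired CpG strand rows kept as-is")
    out = pd.concat([combined, orphan_plus, orphan_minus]).sort_index()
    return out


def _split_mc_cov(pair_table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    samples = list(pair_table.columns.get_level_values("sample").unique())
    mc = np.column_stack([pair_table[(s, "mc")].to_numpy() for s in samples])
    cov = np.column_stack([pair_table[(s, "cov")].to_numpy() for s in samples])
    return mc.astype(np.int64), cov.astype(np.int64), samples


def _rebuild(pair_table, mc, cov, samples) -> pd.DataFrame:
    data = {}
    for j, s in enumerate(samples):
        data[(s, "mc")] = mc[:, j]
        data[(s, "cov")] = cov[:, j]
    out = pd.DataFrame(data, index=pair_table.index)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["sample", "field"])
    return out


def downsample_counts(
    pair_table: pd.DataFrame,
    site_cap: int = 50,
    total_cap: int = 3000,
    seed: int = 0,
) -> pd.DataFrame:
    """Proportionally downsample coverage to ``site_cap`` per sample-site
    and ``total_cap`` across samples per site (hypergeometric draws keep
    the expected fraction unchanged)."""
    if site_cap < 1 or total_cap < 1:
        raise ValueError("caps must be >= 1")
    rng = np.random.default_rng(seed)
    mc, cov, samples = _split_mc_cov(pair_table)

    over = cov > site_cap
    if over.any():
        mc_o, cov_o = mc[over], cov[over]
        mc[over] = rng.hypergeometric(mc_o, cov_o - mc_o, site_cap)
        cov[over] = site_cap

    totals = cov.sum(axis=1)
    over_t = totals > total_cap
    if over_t.any():
        scale = total_cap / totals[over_t]
        new_cov = np.rint(cov[over_t] * scale[:, None]).astype(np.int64)
        new_cov = np.minimum(new_cov, cov[over_t])
        shrink = new_cov < cov[over_t]
        mc_s, cov_s = mc[over_t], cov[over_t]
        new_mc = mc_s.copy()
        if shrink.any():
            new_mc[shrink] = rng.hypergeometric(
                mc_s[shrink], cov_s[shrink] - mc_s[shrink], new_cov[shrink]
            )
        mc[over_t] = new_mc
        cov[over_t] = new_cov
    return _rebuild(pair_table, mc, cov, samples)


def _rms_stat(mc: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """sqrt(mean over covered samples of (p_s - pooled p)^2); NaN if < 2
    covered samples."""
    covered = cov > 0
    n_cov = covered.sum(axis=1)
    total_c = cov.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pbar = mc.sum(axis=1) / total_c
        p_hat = np.where(covered, mc / np.where(cov > 0, cov, 1), np.nan)
        dev = np.nansum((p_hat - pbar[:, None]) ** 2, axis=1) / n_cov
    S = np.sqrt(dev)
    S[n_cov < 2] = np.nan
    return S


def rms_test(
    pair_table: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation RMS test per CpG pair across samples.

    Sites sharing a coverage vector and pooled methylated-call total share
    one null distribution, so permutations are drawn per signature rather
    than per site.  p = (1 + #{S_perm >= S_obs}) / (1 + n_perm), with BH q
    over the defined sites.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    mc, cov, samples = _split_mc_cov(pair_table)
    n_sites, k = mc.shape
    S_obs = _rms_stat(mc, cov)

    # group by (coverage vector, total mc): identical null distribution
    M = mc.sum(axis=1)
    key = np.concatenate([cov, M[:, None]], axis=1)
    _, group_ids, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    p = np.full(n_sites, np.nan)
    frac_cols = {}
    for g, rep in enumerate(group_ids):
        members = np.flatnonzero(inverse == g)
        if not np.isfinite(S_obs[members]).any():
            continue
        c = cov[rep]
        total_c = c.sum()
        total_m = int(M[rep])
        # sequential hypergeometric allocation of total_m over samples
        rem_m = np.full(n_perm, total_m, dtype=np.int64)
        rem_c = np.full(n_perm, total_c, dtype=np.int64)
        mc_perm = np.zeros((n_perm, k), dtype=np.int64)
        for j in range(k):
            cj = int(c[j])
            if cj == 0:
                continue
            draw = rng.hypergeometric(rem_m, rem_c - rem_m, cj) if total_m else np.zeros(n_perm, np.int64)
            mc_perm[:, j] = draw
            rem_m -= draw
            rem_c -= cj
        S_perm = np.sort(_rms_stat(mc_perm, np.broadcast_to(c, (n_perm, k))))
        exceed = n_perm - np.searchsorted(S_perm, S_obs[members] - 1e-12, side="left")
        p[members] = (1.0 + exceed) / (1.0 + n_perm)

    defined = np.isfinite(S_obs) & np.isfinite(p)
    q = np.full(n_sites, np.nan)
    if defined.any():
        q[defined] = core_stats.bh_fdr(p[defined])
    with np.errstate(invalid="ignore", divide="ignore"):
        fracs = np.where(cov > 0, mc / np.where(cov > 0, cov, 1), np.nan)
    out = pd.DataFrame(
        {
            "chrom": pair_table.index.get_level_values(0),
            "pos": pair_table.index.get_level_values(1),
            "S": S_obs,
            "p": p,
            "q": q,
        }
    )
    for j, s in enumerate(samples):
        out[f"frac_{s}"] = fracs[:, j]
        frac_cols[s] = f"frac_{s}"
    return out


def call_dms(
    table: pd.DataFrame,
    site_cap: int = 50,
    total_cap: int = 3000,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Strand combination, downsampling and the permutation RMS test."""
    pair = combine_strand_counts(table)
    pair = downsample_counts(pair, site_cap=site_cap, total_cap=total_cap, seed=seed)
    return rms_test(pair, n_perm=n_perm, seed=seed + 1)


def merge_dms(
    dms: pd.DataFrame,
    max_gap: int = 250,
    min_pcc: float = 0.3,
    q_threshold: float = 0.01,
) -> pd.DataFrame:
    """Greedy left-to-right chaining of significant DMS into DMRs.

    The chain extends over the next DMS iff the positional gap is
    <= ``max_gap`` and the adjacent sites' per-sample fraction vectors
    have PCC > ``min_pcc``.  DMR fractions pool the sites' fractions
    (mean over member sites per sample).
    """
    frac_cols = [c for c in dms.columns if str(c).startswith("frac_")]
    if len(dms) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_sites", "stat"] + frac_cols)
    sig = dms[(dms["q"] < q_threshold) & np.isfinite(dms["S"])].sort_values(["chrom", "pos"])
    records = []
    current: list[pd.Series] = []

    def _flush():
        if not current:
            return
        chrom = current[0]["chrom"]
        start = int(current[0]["pos"])
        end = int(current[-1]["pos"]) + 2  # cover the CpG strand pair
        fr = np.nanmean(np.vstack([r[frac_cols].to_numpy(dtype=float) for r in current]), axis=0)
        rec = {
            "chrom": chrom,
            "start": start,
            "end": end,
            "n_sites": len(current),
            "stat": float(np.nanmax([r["S"] for r in current])),
        }
        rec.update(dict(zip(frac_cols, fr)))
        records.append(rec)

    for _, row in sig.iterrows():
        if current:
            prev = current[-1]
            same = prev["chrom"] == row["chrom"]
            gap = row["pos"] - prev["pos"]
            if same and gap <= max_gap:
                a = prev[frac_cols].to_numpy(dtype=float)
                b = row[frac_cols].to_numpy(dtype=float)
                ok = np.isfinite(a) & np.isfinite(b)
                pcc = np.nan
                if ok.sum() >= 3 and np.ptp(a[ok]) > 0 and np.ptp(b[ok]) > 0:
                    pcc = np.corrcoef(a[ok], b[ok])[0, 1]
                if np.isfinite(pcc) and pcc > min_pcc:
                    current.append(row)
                    continue
        _flush()
        current = [row]
    _flush()
    cols = ["chrom", "start", "end", "n_sites", "stat"] + frac_cols
    return pd.DataFrame(records, columns=cols)


def merge_overlapping(dmr_sets: list[pd.DataFrame]) -> pd.DataFrame:
    """Union of intervals from multiple rounds, merged at distance 0
    (bookended half-open intervals merge)."""
    frames = [d for d in dmr_sets if len(d)]
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    allr = pd.concat(frames, ignore_index=True).sort_values(["chrom", "start", "end"])
    out = []
    cur = None
    for _, row in allr.iterrows():
        if cur is not None and row["chrom"] == cur["chrom"] and row["start"] <= cur["end"]:
            cur["end"] = max(cur["end"], int(row["end"]))
        else:
            if cur is not None:
                out.append(cur)
            cur = {"chrom": row["chrom"], "start": int(row["start"]), "end": int(row["end"])}
    if cur is not None:
        out.append(cur)
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def select_representative(candidates: pd.DataFrame, key: str = "stat") -> pd.Series:
    """Pick the candidate with the largest |key|; ties break by smaller
    start, then shorter length."""
    if len(candidates) == 0:
        raise ValueError("no candidates")
    df = candidates.copy()
    df["_abskey"] = df[key].abs()
    df["_len"] = df["end"] - df["start"]
    df = df.sort_values(["_abskey", "start", "_len"], ascending=[False, True, True], kind="stable")
    return candidates.loc[df.index[0]]
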