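"""TF-DMR-target regulatory network construction and TF ranking.

Three correlation edge types across subclasses (all on quantile
normalized fraction matrices, with pooled shuffle-null FDR < 0.001):

* DMR-Target (Sa): DMR mCG vs gene mCH, restricted to DMRs sitting in
  anchors of the gene's significantly correlated highly variable
  interactions; overlapping DMRs collapse to the max-|Sa| representative;
  the supporting interaction's gene-contact correlation is attached as Sd.
* TF-Target (Sc): TF gene-body mCH vs variable target mCH.
* TF-DMR (Sb): TF mCH vs DMR mCG, kept only when a motif annotated to
  the TF is enriched (recovery-curve NES > 3) in the sign-matched
  correlated DMR set and occurs in the particular DMR (leading edge).

Triples intersect the three edge lists; the final score is
S_all = (|Sa| |Sb| |Sc| |Sd|)^(1/4) and the sign pattern of (Sa, Sb, Sc)
assigns one of four regulatory models (all sign-consistent patterns,
product +1) or "Unknown".  Per-subclass TF importance is a personalized
PageRank on the TF/target graph with inverted-methylation node weights
W_i and triple-score edge weights (1/n) sum_t S_t V_{i,t}.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from . import core_stats
from .utils import intervals_overlap

__all__ = [
    "MotifEnrichmentResult",
    "dmr_target_edges",
    "tf_target_edges",
    "motif_enrichment_nes",
    "tf_dmr_edges",
    "assemble_triples",
    "classify_triple",
    "final_score",
    "inverted_weights",
    "pagerank_scores",
]

MODEL_TABLE = {
    (1, 1, 1): 1,
    (1, -1, -1): 2,
    (-1, -1, 1): 3,
    (-1, 1, -1): 4,
}


@dataclass
class MotifEnrichmentResult:
    motif: str
    sign: str
    auc: float
    nes: float
    leading_edge: list[str]


# ----------------------------------------------------------------------
# edges


def tf_target_edges(
    gene_mch: pd.DataFrame,
    tf_ids: list[str],
    q_max: float = 0.001,
    variance_min: float = 0.0,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Sc edges between TFs and variable genes (self-pairs excluded).

    TF gene bodies are normalized as part of the full gene matrix — their
    mCH fractions live on the same scale as every other gene's.
    """
    var = gene_mch.var(axis=1)
    genes = gene_mch.loc[var >= variance_min]
    B = core_stats.quantile_normalize(genes.to_numpy())
    tf_ids = [t for t in tf_ids if t in genes.index]
    pos = {g: i for i, g in enumerate(genes.index)}
    A = B[[pos[t] for t in tf_ids]]
    tf_ids = np.asarray(tf_ids, dtype=object)
    gene_ids = np.asarray(genes.index, dtype=object)
    pairs = [
        (i, j)
        for i in range(len(tf_ids))
        for j in range(len(gene_ids))
        if tf_ids[i] != gene_ids[j]
    ]
    res = core_stats.correlation_screen(
        A, B, np.asarray(pairs), tf_ids, gene_ids, n_shuffles=n_shuffles, seed=seed
    )
    res = res.rename(columns={"feature_a": "tf", "feature_b": "gene", "pcc": "sc"})
    return res[res["q"] < q_max].reset_index(drop=True)


def dmr_target_edges(
    dmr_mcg: pd.DataFrame,
    gene_mch: pd.DataFrame,
    gene_interactions: pd.DataFrame,
    dmr_intervals: pd.DataFrame,
    genes: dict[str, tuple[str, int, int]],
    resolution: int = 10_000,
    sign_filter: str = "positive",
    q_max: float = 0.001,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Sa edges from DMRs in correlated-interaction anchors to genes.

    ``gene_interactions`` is the significant output of the interaction
    correlation screen (columns transcript, bin_i, bin_j, pcc,
    significant); ``sign_filter`` restricts to positively ("positive"),
    negatively ("negative") or any ("both") correlated interactions.
    ``dmr_intervals`` has columns (dmr, chrom, start, end).  Overlapping
    candidate DMRs of a gene collapse to the max-|Sa| representative; the
    most negative qualifying interaction correlation is attached as Sd.
    """
    if sign_filter not in {"positive", "negative", "both"}:
        raise ValueError("sign_filter must be positive/negative/both")
    gi = gene_interactions[gene_interactions.get("significant", True)].copy()
    if sign_filter == "positive":
        gi = gi[gi["pcc"] > 0]
    elif sign_filter == "negative":
        gi = gi[gi["pcc"] < 0]

    dmr_rows = {r.dmr: (r.chrom, int(r.start), int(r.end)) for r in dmr_intervals.itertuples()}
    candidates: list[tuple[int, int]] = []
    support: dict[tuple[str, str], tuple[float, tuple[int, int]]] = {}
    dmr_ids = np.asarray(dmr_mcg.index, dtype=object)
    gene_ids = np.asarray(gene_mch.index, dtype=object)
    dmr_pos = {d: i for i, d in enumerate(dmr_ids)}
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    for gene_id, sub in gi.groupby("transcript"):
        if gene_id not in gene_pos:
            continue
        for row in sub.itertuples():
            for anchor in (int(row.bin_i), int(row.bin_j)):
                a_lo, a_hi = anchor * resolution, (anchor + 1) * resolution
                for dmr_id, (chrom, dstart, dend) in dmr_rows.items():
                    if chrom != genes[gene_id][0]:
                        continue
                    if intervals_overlap(a_lo, a_hi, dstart, dend):
                        key = (dmr_id, gene_id)
                        pair = (dmr_pos[dmr_id], gene_pos[gene_id])
                        if key not in support:
                            candidates.append(pair)
                            support[key] = (row.pcc, (int(row.bin_i), int(row.bin_j)))
                        elif row.pcc < support[key][0]:  # keep most negative Sd
                            support[key] = (row.pcc, (int(row.bin_i), int(row.bin_j)))
    cols = ["dmr", "gene", "sa", "p", "q", "sd", "bin_i", "bin_j"]
    if not candidates:
        return pd.DataFrame(columns=cols)
    A = core_stats.quantile_normalize(dmr_mcg.to_numpy())
    B = core_stats.quantile_normalize(gene_mch.to_numpy())
    res = core_stats.correlation_screen(
        A, B, np.asarray(candidates), dmr_ids, gene_ids, n_shuffles=n_shuffles, seed=seed
    )
    res = res.rename(columns={"feature_a": "dmr", "feature_b": "gene", "pcc": "sa"})
    res = res[res["q"] < q_max].reset_index(drop=True)
    res["sd"] = [support[(d, g)][0] for d, g in zip(res["dmr"], res["gene"])]
    res["bin_i"] = [support[(d, g)][1][0] for d, g in zip(res["dmr"], res["gene"])]
    res["bin_j"] = [support[(d, g)][1][1] for d, g in zip(res["dmr"], res["gene"])]
    # collapse overlapping DMRs per gene to the strongest |Sa|
    keep_rows = []
    for gene_id, sub in res.groupby("gene"):
        sub = sub.copy()
        sub["_abs"] = sub["sa"].abs()
        sub = sub.sort_values(["_abs"], ascending=False, kind="stable")
        chosen: list[tuple[int, int, int]] = []  # (start, end, row index)
        for row in sub.itertuples():
            chrom, dstart, dend = dmr_rows[row.dmr]
            if any(intervals_overlap(dstart, dend, s, e) for s, e, _ in chosen):
                continue
            chosen.append((dstart, dend, row.Index))
        keep_rows.extend(idx for _, _, idx in chosen)
    return res.loc[sorted(keep_rows), cols].reset_index(drop=True)


# ----------------------------------------------------------------------
# motif enrichment (recovery-curve NES)


def motif_enrichment_nes(
    motif_scores: pd.DataFrame,
    query_set: list[str],
    rank_fraction: float = 0.05,
    sign: str = "",
    seed: int = 0,
) -> list[MotifEnrichmentResult]:
    """Recovery-curve enrichment of every motif for one query DMR set.

    Each motif ranks all DMRs by descending score; the recovery curve is
    the cumulative fraction of the query recovered by rank, evaluated up
    to ``rank_fraction`` of the collection; AUC is the mean recovery over
    that range and NES standardizes AUC against all motifs.  The leading
    edge contains query DMRs ranked at or above the rank maximizing
    (recovery - expected uniform recovery).
    """
    n_dmrs, n_motifs = motif_scores.shape
    if n_motifs < 10:
        raise ValueError("need >= 10 motifs in the collection")
    query = [q for q in query_set if q in motif_scores.index]
    if not query:
        raise ValueError("empty query set")
    q_mask = motif_scores.index.isin(query).astype(float)
    # the recovery window is rank_fraction of the collection, but never
    # fewer than 25 regions (or the whole catalog): tiny windows make
    # every motif's AUC zero on miniature DMR catalogs
    top = max(int(np.floor(rank_fraction * n_dmrs)), 1)
    top = min(max(top, 25), n_dmrs)
    rng = np.random.default_rng(seed)
    # random tiebreak keeps ties from privileging input order
    jitter = rng.random((n_dmrs, n_motifs)) * 1e-9
    order = np.argsort(-(motif_scores.to_numpy() + jitter), axis=0, kind="stable")
    hits = q_mask[order]  # ranked query membership per motif
    recovery = np.cumsum(hits, axis=0) / len(query)
    aucs = recovery[:top].mean(axis=0)
    sd = aucs.std()
    if sd == 0:
        raise ValueError("degenerate motif collection: identical AUCs")
    nes = (aucs - aucs.mean()) / sd
    results = []
    uniform = (np.arange(1, n_dmrs + 1)) / n_dmrs
    dmr_index = np.asarray(motif_scores.index, dtype=object)
    for m, motif in enumerate(motif_scores.columns):
        gain = recovery[:, m] - uniform
        r_star = int(np.argmax(gain))
        ranked = dmr_index[order[: r_star + 1, m]]
        leading = [d for d in ranked if d in set(query)]
        results.append(
            MotifEnrichmentResult(motif=str(motif), sign=sign, auc=float(aucs[m]), nes=float(nes[m]), leading_edge=leading)
        )
    return results


def tf_dmr_edges(
    gene_mch: pd.DataFrame,
    tf_ids: list[str],
    dmr_mcg: pd.DataFrame,
    motif_db,
    q_max: float = 0.001,
    nes_min: float = 3.0,
    rank_fraction: float = 0.05,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Sb edges gated by sign-split motif enrichment and occurrence.

    For each TF the significantly correlated DMRs are split by sign(Sb);
    the recovery-curve enrichment runs on each sign set separately, and
    edges survive only for DMRs in the leading edge of a motif that is
    annotated to the TF and strictly exceeds the NES cutoff.
    """
    Q = core_stats.quantile_normalize(gene_mch.to_numpy())
    pos = {g: i for i, g in enumerate(gene_mch.index)}
    tf_ids = [t for t in tf_ids if t in pos]
    A = Q[[pos[t] for t in tf_ids]]
    B = core_stats.quantile_normalize(dmr_mcg.to_numpy())
    tf_ids = np.asarray(tf_ids, dtype=object)
    dmr_ids = np.asarray(dmr_mcg.index, dtype=object)
    pairs = np.array([(i, j) for i in range(len(tf_ids)) for j in range(len(dmr_ids))])
    res = core_stats.correlation_screen(
        A, B, pairs, tf_ids, dmr_ids, n_shuffles=n_shuffles, seed=seed
    )
    res = res.rename(columns={"feature_a": "tf", "feature_b": "dmr", "pcc": "sb"})
    sig = res[res["q"] < q_max]
    edges = []
    for tf_id, sub in sig.groupby("tf"):
        tf_motifs = set(motif_db.motifs_for_tf(tf_id))
        if not tf_motifs:
            continue
        for sign, sset in (("positive", sub[sub["sb"] > 0]), ("negative", sub[sub["sb"] < 0])):
            query = list(sset["dmr"])
            if not query:
                continue
            enr = motif_enrichment_nes(
                motif_db.scores, query, rank_fraction=rank_fraction, sign=sign, seed=seed
            )
            for r in enr:
                if r.nes <= nes_min or r.motif not in tf_motifs:
                    continue
                occur = {
                    d
                    for d in r.leading_edge
                    if motif_db.scores.loc[d, r.motif] >= motif_db.thresholds[r.motif]
                }
                for row in sset.itertuples():
                    if row.dmr in occur:
                        edges.append(
                            {
                                "tf": tf_id,
                                "dmr": row.dmr,
                                "sb": row.sb,
                                "p": row.p,
                                "q": row.q,
                                "motif": r.motif,
                                "nes": r.nes,
                                "sign": sign,
                            }
                        )
    cols = ["tf", "dmr", "sb", "p", "q", "motif", "nes", "sign"]
    out = pd.DataFrame(edges, columns=cols)
    return out.drop_duplicates(subset=["tf", "dmr"]).reset_index(drop=True)


# ----------------------------------------------------------------------
# triples


def final_score(sa: float, sb: float, sc: float, sd: float) -> float:
    """Geometric mean of the absolute values of the four correlations."""
    return float((abs(sa) * abs(sb) * abs(sc) * abs(sd)) ** 0.25)


def classify_triple(sa: float, sb: float, sc: float) -> str:
    """Model class from the sign pattern of (Sa, Sb, Sc).

    The four models are exactly the sign-consistent patterns (product
    +1); anything else, or a zero correlation, is "Unknown".
    """
    if sa == 0 or sb == 0 or sc == 0 or not all(np.isfinite([sa, sb, sc])):
        return "Unknown"
    key = (int(np.sign(sa)), int(np.sign(sb)), int(np.sign(sc)))
    model = MODEL_TABLE.get(key)
    return f"Model {model}" if model else "Unknown"


def assemble_triples(
    dmr_target: pd.DataFrame,
    tf_target: pd.DataFrame,
    tf_dmr: pd.DataFrame,
) -> pd.DataFrame:
    """Intersect the three edge lists into scored, classified triples."""
    cols = ["tf", "dmr", "gene", "sa", "sb", "sc", "sd", "s_all", "model"]
    if not len(dmr_target) or not len(tf_target) or not len(tf_dmr):
        return pd.DataFrame(columns=cols)
    m = tf_dmr.merge(dmr_target, on="dmr", suffixes=("_b", "_a"))
    m = m.merge(tf_target, on=["tf", "gene"])
    if not len(m):
        return pd.DataFrame(columns=cols)
    out = pd.DataFrame(
        {
            "tf": m["tf"],
            "dmr": m["dmr"],
            "gene": m["gene"],
            "sa": m["sa"],
            "sb": m["sb"],
            "sc": m["sc"],
            "sd": m["sd"],
        }
    )
    out["s_all"] = [final_score(a, b, c, d) for a, b, c, d in zip(out.sa, out.sb, out.sc, out.sd)]
    out["model"] = [classify_triple(a, b, c) for a, b, c in zip(out.sa, out.sb, out.sc)]
    return out.reset_index(drop=True)


# ----------------------------------------------------------------------
# PageRank


def inverted_weights(matrix: pd.DataFrame, quantile_range=(10.0, 90.0)) -> pd.DataFrame:
    """Quantile normalize along subclasses, robust-scale each feature by
    (x - median)/(Q90 - Q10), then invert per feature:
    W_i = (max - x_i)/(max - min) across subclasses, in [0, 1]."""
    from sklearn.preprocessing import RobustScaler

    qn = core_stats.quantile_normalize(matrix.to_numpy())
    scaled = RobustScaler(quantile_range=quantile_range).fit_transform(qn.T).T
    mx = scaled.max(axis=1, keepdims=True)
    mn = scaled.min(axis=1, keepdims=True)
    span = np.where(mx - mn > 0, mx - mn, 1.0)
    W = (mx - scaled) / span
    return pd.DataFrame(W, index=matrix.index, columns=matrix.columns)


def pagerank_scores(
    triples: pd.DataFrame,
    gene_mch: pd.DataFrame,
    dmr_mcg: pd.DataFrame,
    damping: float = 0.85,
    tol: float = 1e-9,
    edge_direction: str = "target_to_tf",
) -> dict[str, pd.DataFrame]:
    """Per-subclass personalized PageRank over the TF/target network.

    The network keeps only TF and target gene nodes; node weights are the
    inverted scaled gene-body mCH values W_i (personalization), and the
    TF-target edge weight in subclass i is (1/n) sum_t S_all,t * V_{i,t}
    over the n triples connecting the pair, V being the inverted scaled
    DMR mCG.  With ``edge_direction='target_to_tf'`` importance flows
    from regulated genes to their regulators, so hub TFs of active
    targets rank highly; 'tf_to_target' orients edges the other way.

    Returns {'raw': nodes x subclasses, 'normalized': per-node min-max}.
    """
    if not len(triples):
        raise ValueError("no triples")
    if edge_direction not in {"target_to_tf", "tf_to_target"}:
        raise ValueError("edge_direction must be target_to_tf or tf_to_target")
    nodes = sorted(set(triples["tf"]) | set(triples["gene"]))
    gm = gene_mch.loc[[n for n in nodes if n in gene_mch.index]]
    W = inverted_weights(gm)
    V = inverted_weights(dmr_mcg.loc[sorted(set(triples["dmr"]))])
    subclasses = list(gene_mch.columns)
    raw = pd.DataFrame(0.0, index=nodes, columns=subclasses)
    for s in subclasses:
        G = nx.DiGraph()
        G.add_nodes_from(nodes)
        for (tf, gene), sub in triples.groupby(["tf", "gene"]):
            w = float(np.mean([r.s_all * V.loc[r.dmr, s] for r in sub.itertuples()]))
            if edge_direction == "target_to_tf":
                G.add_edge(gene, tf, weight=w)
            else:
                G.add_edge(tf, gene, weight=w)
        pers = {n: float(W.loc[n, s]) if n in W.index else 0.0 for n in nodes}
        if sum(pers.values()) == 0:
            pers = {n: 1.0 for n in nodes}
        pr = nx.pagerank(G, alpha=damping, personalization=pers, weight="weight", tol=tol, max_iter=500)
        raw[s] = pd.Series(pr)
    mx = raw.max(axis=1)
    mn = raw.min(axis=1)
    span = (mx - mn).replace(0, 1.0)
    normalized = raw.sub(mn, axis=0).div(span, axis=0)
    return {"raw": raw, "normalized": normalized}
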