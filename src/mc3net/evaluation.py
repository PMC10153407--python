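"""Recovery and calibration experiments against planted truth.

This module runs the package's standard experiments end-to-end and
scores the results against the synthetic generator's
:class:`~mc3net.synthetic.PlantedTruth` record: structural recovery
(compartment signs, differential boundaries, highly variable
interactions), network recovery (triples with intended sign models,
master-TF PageRank ranks), DMS recovery, discovery-rate calibration on
null data, and agreement between the fast estimators and their exact
counterparts.  Tests and the acceptance script both drive these
functions; analysis modules themselves never read the truth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import boundaries as bnd
from . import compartments as cmp
from . import contacts, core_stats, dmr, interactions, workflow
from .synthetic import (
    GenomeConfig,
    TruthConfig,
    atlas_config,
    grn_config,
    null_config,
    simulate_base_counts,
    simulate_contact_cells,
    simulate_genome,
    simulate_methylomes,
    simulate_motif_db,
)

__all__ = [
    "structural_recovery",
    "grn_recovery",
    "dms_recovery",
    "null_calibration",
    "oracle_equivalence",
]


def _seeded(seed: int, k: int) -> int:
    return (seed * 1000 + k) % (2**31 - 1)


# ----------------------------------------------------------------------
# criterion-style experiments


def structural_recovery(seed: int = 0, n_shuffles: int = 500) -> dict:
    """Compartment/boundary/HVI recovery under the atlas conditions
    (20 Mb genome, 5 subclasses x 40 cells)."""
    gcfg, tcfg, n_sub, n_cells = atlas_config()
    genome = simulate_genome(gcfg, seed=_seeded(seed, 1))
    methylome, truth = simulate_methylomes(genome, tcfg, n_subclasses=n_sub, seed=_seeded(seed, 2))
    cells = simulate_contact_cells(genome, truth, n_cells, seed=_seeded(seed, 3))
    chrom = genome.chromosomes[0][0]
    feats = workflow.collect_contact_features(genome, cells, chrom)

    out: dict = {}
    # compartments: pooled per-subclass bin-sign accuracy on kept bins
    track, _ = workflow.run_compartment_analysis(genome, feats, None)
    accs = [
        np.mean(
            np.sign(track.scores[s].to_numpy())
            == truth.compartment_labels[s][chrom][track.kept_bins]
        )
        for s in truth.subclasses
    ]
    out["compartment_sign_accuracy"] = float(np.mean(accs))
    out["n_compartment_bins"] = int(track.kept_bins.size * n_sub)

    # differential boundaries: planted bins flagged variable within +/- 1
    _, diff, _ = workflow.run_boundary_analysis(genome, feats, None)
    planted_b = truth.differential_boundary_bins(chrom)
    flagged = set(diff.loc[diff["variable"], "bin"].tolist())
    hits = sum(any(b + o in flagged for o in (-1, 0, 1)) for b in planted_b)
    out["boundary_sensitivity"] = float(hits / max(planted_b.size, 1))
    out["n_planted_boundaries"] = int(planted_b.size)

    # HVIs: planted variable loops with any dot pixel flagged
    table, _ = workflow.run_interaction_analysis(genome, feats, None)
    hv = table[table["highly_variable"]]
    hvset = set(zip(hv["bin_i"].tolist(), hv["bin_j"].tolist()))
    loops = [l for l in truth.loops if np.ptp(l.enrichment) > 0]
    hit = sum(
        any((l.bin_i + di, l.bin_j + dj) in hvset for di in (-1, 0, 1) for dj in (-1, 0, 1))
        for l in loops
    )
    out["hvi_sensitivity"] = float(hit / max(len(loops), 1))
    out["n_planted_loops"] = len(loops)
    return out


def grn_recovery(seed: int = 0, n_shuffles: int = 500) -> dict:
    """Triple assembly and PageRank recovery under the network conditions
    (8 Mb gene-dense genome, 30 subclasses x 16 cells)."""
    gcfg, tcfg, n_sub, n_cells = grn_config()
    genome = simulate_genome(gcfg, seed=_seeded(seed, 11))
    methylome, truth = simulate_methylomes(genome, tcfg, n_subclasses=n_sub, seed=_seeded(seed, 12))
    cells = simulate_contact_cells(genome, truth, n_cells, seed=_seeded(seed, 13))
    chrom = genome.chromosomes[0][0]
    feats = workflow.collect_contact_features(genome, cells, chrom, resolutions=(10_000,))
    table, icorr = workflow.run_interaction_analysis(
        genome, feats, methylome, n_shuffles=n_shuffles, seed=_seeded(seed, 14)
    )
    motif_db = simulate_motif_db(genome, truth, seed=_seeded(seed, 15))
    dmr_intervals = pd.DataFrame(
        [{"dmr": d.id, "chrom": d.chrom, "start": d.start, "end": d.end} for d in truth.dmrs]
    )
    res = workflow.run_grn_analysis(
        genome, methylome, motif_db, icorr, dmr_intervals, n_shuffles=n_shuffles, seed=_seeded(seed, 16)
    )
    planted = {(t.tf_id, t.dmr_id, t.gene_id): t.model_class for t in truth.triples}
    got = {(r.tf, r.dmr, r.gene): r.model for r in res["triples"].itertuples()}
    correct = sum(got.get(k) == f"Model {v}" for k, v in planted.items())
    out = {
        "triple_model_accuracy": float(correct / max(len(planted), 1)),
        "n_planted_triples": len(planted),
        "n_assembled_triples": int(len(res["triples"])),
        "n_spurious_triples": int(sum(k not in planted for k in got)),
    }
    master_top3 = []
    if res["pagerank"] is not None:
        raw = res["pagerank"]["raw"]
        tfs = [g.id for g in genome.tf_genes() if g.id in raw.index]
        for tf, s in truth.master_tfs.items():
            if tf in tfs:
                order = raw.loc[tfs, s].sort_values(ascending=False).index.tolist()
                master_top3.append(order.index(tf) < 3)
            else:
                master_top3.append(False)
    else:
        master_top3 = [False] * len(truth.master_tfs)
    out["master_top3"] = master_top3
    return out


def dms_recovery(seed: int = 0, n_sites: int = 10_000, n_perm: int = 1000) -> dict:
    """Sensitivity of the permutation RMS test for planted DMS."""
    gcfg, tcfg, _, _ = atlas_config()
    tcfg = TruthConfig(
        **{**tcfg.__dict__, "n_cpg_sites": n_sites, "dms_fraction": 0.25, "dms_delta": 0.6}
    )
    genome = simulate_genome(gcfg, seed=_seeded(seed, 21))
    _, truth = simulate_methylomes(genome, tcfg, n_subclasses=4, seed=_seeded(seed, 22))
    counts = simulate_base_counts(genome, truth, mean_cov=60, seed=_seeded(seed, 23))
    dms = dmr.call_dms(counts, n_perm=n_perm, seed=_seeded(seed, 24))
    merged = dms.merge(truth.dms_sites[["chrom", "pos", "is_dms"]], on=["chrom", "pos"])
    planted = merged[merged["is_dms"]]
    return {
        "dms_sensitivity": float((planted["q"] < 0.01).mean()),
        "n_planted_dms": int(len(planted)),
        "n_sites": int(len(merged)),
    }


# ----------------------------------------------------------------------
# calibration on null data


def null_calibration(seed: int = 0, fast: bool = False) -> dict:
    """Discovery fractions of every test family on unplanted data.

    Families: the pooled shuffle-null correlation screen (FDR < 1e-3),
    the chi-square boundary test (FDR < 1e-3), the ANOVA HVI selection
    (F > 3, FDR < 0.001) and the RMS DMS test (q < 0.01), each over at
    least 10^4 units (bins pooled over replicates for the boundary test).
    """
    rng = np.random.default_rng(_seeded(seed, 31))
    out: dict = {}

    # correlation family: i.i.d. fraction-like matrices, 10^4 pairs
    n_pairs = 10_000
    A = rng.normal(size=(n_pairs, 20))
    B = rng.normal(size=(n_pairs, 20))
    pairs = np.column_stack([np.arange(n_pairs)] * 2)
    res = core_stats.correlation_screen(A, B, pairs, np.arange(n_pairs), np.arange(n_pairs),
                                        n_shuffles=200, seed=_seeded(seed, 32))
    out["correlation_null_discovery_fraction"] = float((res["q"] < 1e-3).mean())
    out["n_correlation_pairs"] = int(len(res))

    # chi-square boundary test: null contact sims pooled over replicates
    gcfg, tcfg = null_config(chrom_mb=10)
    n_reps = 4 if fast else 25
    n_bins_total = 0
    n_flagged = 0
    for r in range(n_reps):
        genome = simulate_genome(gcfg, seed=_seeded(seed, 40 + r))
        _, truth = simulate_methylomes(genome, tcfg, n_subclasses=4, seed=_seeded(seed, 70 + r))
        cells = simulate_contact_cells(genome, truth, 20, 40_000, seed=_seeded(seed, 100 + r),
                                       compartment_delta=0.0)
        feats = workflow.collect_contact_features(genome, cells, "chr1", resolutions=(25_000,))
        diff = bnd.differential_boundary_test(feats.calls25, feats.labels)
        n_bins_total += len(diff)
        n_flagged += int(diff["variable"].sum())
    out["boundary_null_discovery_fraction"] = float(n_flagged / n_bins_total)
    out["n_boundary_bins"] = int(n_bins_total)

    # ANOVA HVI selection on one null replicate (>= 10^4 pixels)
    genome = simulate_genome(gcfg, seed=_seeded(seed, 131))
    _, truth = simulate_methylomes(genome, tcfg, n_subclasses=4, seed=_seeded(seed, 132))
    cells = simulate_contact_cells(genome, truth, 20, 40_000, seed=_seeded(seed, 133),
                                   compartment_delta=0.0)
    feats = workflow.collect_contact_features(genome, cells, "chr1", resolutions=(10_000,))
    table, _ = workflow.run_interaction_analysis(genome, feats, None)
    out["hvi_null_discovery_fraction"] = float(table["highly_variable"].mean())
    out["n_anova_pixels"] = int(len(table))

    # RMS DMS on null sites
    tcfg_dms = TruthConfig(**{**tcfg.__dict__, "n_cpg_sites": 3_000 if fast else 10_000,
                              "dms_fraction": 0.0})
    _, truth = simulate_methylomes(genome, tcfg_dms, n_subclasses=4, seed=_seeded(seed, 134))
    counts = simulate_base_counts(genome, truth, mean_cov=60, seed=_seeded(seed, 135))
    dms = dmr.call_dms(counts, n_perm=300 if fast else 1000, seed=_seeded(seed, 136))
    out["dms_null_discovery_fraction"] = float((dms["q"] < 0.01).mean())
    out["n_dms_sites"] = int(len(dms))
    return out


# ----------------------------------------------------------------------
# oracle equivalence


def oracle_equivalence(seed: int = 0, n_empirical_shuffles: int = 100_000) -> dict:
    """Agreement of fast estimators with exact/empirical counterparts."""
    from scipy.stats import spearmanr

    rng = np.random.default_rng(_seeded(seed, 51))
    out: dict = {}

    # normal-approximation p vs explicit-shuffle empirical p
    n_feat, n_samp = 150, 20
    A = rng.normal(size=(n_feat, n_samp))
    # couple rows with graded strength so observed p spans the band
    B = A * np.linspace(0.0, 0.9, n_feat)[:, None] + rng.normal(size=(n_feat, n_samp))
    pairs = np.column_stack([np.arange(n_feat)] * 2)
    obs = core_stats.pairwise_pearson(A, B, pairs)
    null = core_stats.build_shuffle_null(A, B, pairs, n_shuffles=2000, seed=_seeded(seed, 52))
    p_norm = core_stats.normal_p(obs, null)
    p_emp = core_stats.empirical_null_pvalues(A, B, pairs, obs, n_shuffles=n_empirical_shuffles,
                                              seed=_seeded(seed, 53))
    band = (p_emp >= 0.001) & (p_emp <= 0.5)
    rho = spearmanr(p_norm[band], p_emp[band]).statistic
    out["p_value_spearman"] = float(rho)
    out["n_p_value_pairs"] = int(band.sum())

    # incremental vs exact PCA scoring (<= 500 bins)
    gcfg = GenomeConfig(chromosomes=(("chr1", 20_000_000),))
    genome = simulate_genome(gcfg, seed=_seeded(seed, 54))
    _, truth = simulate_methylomes(genome, TruthConfig(), n_subclasses=4, seed=_seeded(seed, 55))
    cells = simulate_contact_cells(genome, truth, 10, 40_000, seed=_seeded(seed, 56))
    feats = workflow.collect_contact_features(genome, cells, "chr1", resolutions=(100_000,))
    mats = {g: m.matrix for g, m in feats.group100.items()}
    cpg = genome.cpg_density["chr1"]
    t_inc = cmp.compartment_scores(mats, cpg, "chr1", incremental=True)
    t_exact = cmp.compartment_scores(mats, cpg, "chr1", incremental=False)
    cosines = []
    for s in t_inc.scores.columns:
        a = t_inc.scores[s].to_numpy()
        b = t_exact.scores[s].to_numpy()
        cosines.append(abs(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b)))
    out["ipca_cosine"] = float(np.min(cosines))
    out["n_ipca_bins"] = int(t_inc.scores.shape[0])

    # iterative vs direct random walk with restart (<= 50 bins)
    n = 40
    raw = rng.poisson(1.0, size=(n, n)).astype(float)
    raw = np.triu(raw) + np.triu(raw, 1).T
    conv = contacts.convolve(raw, pad=1)
    direct = contacts.random_walk_impute(conv, resolution=100_000, method="direct")
    iterative = contacts.random_walk_impute(conv, resolution=100_000, method="iterative", tol=1e-10)
    out["rwr_max_abs_diff"] = float(np.abs(direct.dense() - iterative.dense()).max())
    out["n_rwr_bins"] = n
    return out
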