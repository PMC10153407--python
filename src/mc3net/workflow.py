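"""End-to-end orchestration helpers.

These functions wire the per-module operations into the standard
analysis passes: one sweep over the single cells building and imputing
matrices at the three resolutions (collecting group matrices, boundary
calls and band-pixel values in a single pass so per-cell dense matrices
are never all held at once), followed by the compartment, boundary,
interaction and network analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import boundaries, compartments, contacts, dmr, grn, interactions
from .synthetic import ContactCellSet, GenomeModel, MotifScoreMatrix, SubclassMethylome

__all__ = [
    "ContactFeatures",
    "collect_contact_features",
    "run_compartment_analysis",
    "run_boundary_analysis",
    "run_interaction_analysis",
    "run_dmr_analysis",
    "run_grn_analysis",
    "transcript_records",
]


@dataclass
class ContactFeatures:
    chrom: str
    labels: list[str]
    cell_ids: list[str]
    group100: dict[str, contacts.GroupContactMatrix] = field(default_factory=dict)
    calls25: np.ndarray | None = None
    window: int = 5
    band_rows: np.ndarray | None = None
    band_cols: np.ndarray | None = None
    band_values: np.ndarray | None = None  # cells x band pixels (imputed, 10 kb)

    def group_strength(self, pixel_rows: np.ndarray) -> pd.DataFrame:
        """Mean imputed strength per subclass at selected band-pixel rows."""
        labels = np.asarray(self.labels)
        out = {}
        for g in sorted(set(self.labels)):
            out[g] = self.band_values[labels == g][:, pixel_rows].mean(axis=0)
        return pd.DataFrame(out)


def collect_contact_features(
    genome: GenomeModel,
    cellset: ContactCellSet,
    chrom: str,
    resolutions: tuple[int, ...] = (100_000, 25_000, 10_000),
    w: int = 5,
    blacklist: list[tuple[str, int, int]] | None = None,
    restart_p: float = 0.5,
    dtype=np.float32,
) -> ContactFeatures:
    """One pass over cells: bin, impute and collect per-resolution features."""
    from .utils import blacklist_bin_mask

    L = genome.chrom_length(chrom)
    feats = ContactFeatures(chrom=chrom, labels=[], cell_ids=[], window=w)
    if 10_000 in resolutions:
        n10 = genome.n_bins(chrom, 10_000)
        feats.band_rows, feats.band_cols = interactions.band_pixels(n10)
    bl25 = blacklist_bin_mask(blacklist, chrom, L, 25_000) if blacklist else None
    sums: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    calls_rows = []
    band_rows_vals = []
    for cell in cellset:
        if chrom not in cell.pairs:
            continue
        pos_a, pos_b = cell.pairs[chrom]
        feats.labels.append(cell.subclass)
        feats.cell_ids.append(cell.cell_id)
        if 100_000 in resolutions:
            raw = contacts.bin_contact_pairs(pos_a, pos_b, chrom, L, 100_000, cell.cell_id)
            imp = contacts.impute_cell(raw, restart_p=restart_p, dtype=dtype)
            d = imp.dense().astype(np.float64)
            if cell.subclass in sums:
                sums[cell.subclass] += d
            else:
                sums[cell.subclass] = d
            counts[cell.subclass] = counts.get(cell.subclass, 0) + 1
        if 25_000 in resolutions:
            raw = contacts.bin_contact_pairs(pos_a, pos_b, chrom, L, 25_000, cell.cell_id)
            imp = contacts.impute_cell(raw, restart_p=restart_p, dtype=dtype)
            calls_rows.append(boundaries.topdom_boundaries(imp.dense(), w=w, blacklist_mask=bl25))
        if 10_000 in resolutions:
            raw = contacts.bin_contact_pairs(pos_a, pos_b, chrom, L, 10_000, cell.cell_id)
            imp = contacts.impute_cell(raw, restart_p=restart_p, dtype=dtype)
            band_rows_vals.append(
                imp.dense()[feats.band_rows, feats.band_cols].astype(np.float32)
            )
    if 100_000 in resolutions:
        feats.group100 = {
            g: contacts.GroupContactMatrix(g, chrom, 100_000, sums[g] / counts[g], counts[g])
            for g in sums
        }
    if 25_000 in resolutions and calls_rows:
        feats.calls25 = np.vstack(calls_rows)
    if 10_000 in resolutions and band_rows_vals:
        feats.band_values = np.vstack(band_rows_vals)
    return feats


def run_compartment_analysis(
    genome: GenomeModel,
    feats: ContactFeatures,
    methylome: SubclassMethylome | None = None,
    blacklist: list[tuple[str, int, int]] | None = None,
    n_shuffles: int = 1000,
    seed: int = 0,
):
    """Bin filtering, shared-PCA scoring and the mCG correlation screen."""
    chrom = feats.chrom
    mats = {g: m.matrix for g, m in feats.group100.items()}
    R = np.mean([m.sum(axis=1) for m in mats.values()], axis=0)
    keep = compartments.filter_bins(
        compartments.BinCoverage(chrom, R), blacklist, genome.chrom_length(chrom), 100_000
    )
    track = compartments.compartment_scores(mats, genome.cpg_density[chrom], chrom, keep)
    corr = None
    if methylome is not None:
        bin_mc = methylome.bin_mcg.xs(chrom, level="chrom")
        corr = compartments.compartment_mc_correlation(track, bin_mc, n_shuffles=n_shuffles, seed=seed)
    return track, corr


def run_boundary_analysis(
    genome: GenomeModel,
    feats: ContactFeatures,
    methylome: SubclassMethylome | None = None,
    n_shuffles: int = 1000,
    seed: int = 0,
    q_threshold: float = 1e-3,
):
    """Boundary probability, differential test, transcript correlation."""
    track = boundaries.boundary_probability(feats.calls25, feats.labels)
    diff = boundaries.differential_boundary_test(feats.calls25, feats.labels, q_threshold)
    corr = None
    if methylome is not None:
        recs = transcript_records(genome)
        recs = boundaries.collapse_transcripts(recs)
        variable = diff.loc[diff["variable"], "bin"].to_numpy()
        corr = boundaries.transcript_boundary_correlation(
            methylome.gene_mch,
            track,
            recs,
            variable,
            feats.chrom,
            n_shuffles=n_shuffles,
            seed=seed,
            q_threshold=q_threshold,
        )
    return track, diff, corr


def run_interaction_analysis(
    genome: GenomeModel,
    feats: ContactFeatures,
    methylome: SubclassMethylome | None = None,
    blacklist: list[tuple[str, int, int]] | None = None,
    f_min: float = 3.0,
    q_max: float = 0.001,
    n_shuffles: int = 1000,
    seed: int = 0,
):
    """ANOVA over single-cell strengths, HVI selection, mCH correlation."""
    table = interactions.interaction_anova(
        feats.band_values,
        feats.labels,
        feats.band_rows,
        feats.band_cols,
        chrom=feats.chrom,
        blacklist=blacklist,
        chrom_length=genome.chrom_length(feats.chrom),
    )
    table = interactions.select_hvi(table, f_min=f_min, q_max=q_max)
    corr = None
    if methylome is not None:
        hvi = table[table["highly_variable"]]
        # group-mean strengths at the HVI pixels (rows into the band arrays)
        strength = feats.group_strength(hvi["pixel"].to_numpy())
        recs = transcript_records(genome)
        corr = interactions.interaction_mc_correlation(
            methylome.gene_mch,
            strength,
            table,
            recs,
            feats.chrom,
            n_shuffles=n_shuffles,
            seed=seed,
            q_threshold=q_max,
        )
    return table, corr


def run_dmr_analysis(
    counts_table: pd.DataFrame,
    site_cap: int = 50,
    total_cap: int = 3000,
    n_perm: int = 1000,
    seed: int = 0,
    q_threshold: float = 0.01,
    max_gap: int = 250,
    min_pcc: float = 0.3,
):
    """DMS calling and DMR merging from a strand-resolved count table."""
    dms = dmr.call_dms(counts_table, site_cap=site_cap, total_cap=total_cap, n_perm=n_perm, seed=seed)
    regions = dmr.merge_dms(dms, max_gap=max_gap, min_pcc=min_pcc, q_threshold=q_threshold)
    return dms, regions


def run_grn_analysis(
    genome: GenomeModel,
    methylome: SubclassMethylome,
    motif_db: MotifScoreMatrix,
    gene_interactions: pd.DataFrame,
    dmr_intervals: pd.DataFrame,
    q_max: float = 0.001,
    nes_min: float = 3.0,
    sign_filter: str = "positive",
    n_shuffles: int = 1000,
    seed: int = 0,
):
    """Three edge screens, triple assembly and per-subclass PageRank."""
    genes_pos = {g.id: (g.chrom, g.start, g.end) for g in genome.genes}
    tf_ids = [g.id for g in genome.tf_genes()]
    dt = grn.dmr_target_edges(
        methylome.dmr_mcg,
        methylome.gene_mch,
        gene_interactions,
        dmr_intervals,
        genes_pos,
        sign_filter=sign_filter,
        q_max=q_max,
        n_shuffles=n_shuffles,
        seed=seed,
    )
    tt = grn.tf_target_edges(
        methylome.gene_mch, tf_ids, q_max=q_max, n_shuffles=n_shuffles, seed=seed + 1
    )
    td = grn.tf_dmr_edges(
        methylome.gene_mch,
        tf_ids,
        methylome.dmr_mcg,
        motif_db,
        q_max=q_max,
        nes_min=nes_min,
        n_shuffles=n_shuffles,
        seed=seed + 2,
    )
    triples = grn.assemble_triples(dt, tt, td)
    ranks = None
    if len(triples):
        ranks = grn.pagerank_scores(triples, methylome.gene_mch, methylome.dmr_mcg)
    return {"dmr_target": dt, "tf_target": tt, "tf_dmr": td, "triples": triples, "pagerank": ranks}


def transcript_records(genome: GenomeModel) -> list[tuple[str, str, str, int, int, str]]:
    """(transcript id, gene id, chrom, start, end, strand) records."""
    return [(g.id, g.id, g.chrom, g.start, g.end, g.strand) for g in genome.genes]
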