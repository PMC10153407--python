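"""Latent truth planting and pseudo-bulk methylome sampling.

Each feature (gene, 100-kb bin, DMR) carries a latent per-subclass
activity pattern; observed methylation fractions are Binomial(coverage,
latent fraction) / coverage draws.  Gene-body mCH is the (inverse) proxy
for gene activity, so a gene "active in subclass s" has its latent mCH
minimum in s.  Planted triples impose the intended correlation signs
among TF mCH, DMR mCG and target mCH; planted loops and boundaries are
tied to gene activity patterns so the contact-methylation correlation
screens have recoverable signal.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from dataclasses import dataclass, field

from .genome import GenomeModel
from .truth import (
    MODEL_SIGNS,
    BoundaryCoupling,
    PlantedDMR,
    PlantedLoop,
    PlantedTriple,
    PlantedTruth,
    TruthConfig,
)

__all__ = ["SubclassMethylome", "simulate_methylomes"]


@dataclass
class SubclassMethylome:
    """Sampled fraction matrices (features x subclasses) with coverages."""

    gene_mch: pd.DataFrame
    gene_mch_cov: pd.DataFrame
    bin_mcg: pd.DataFrame  # index (chrom, bin100)
    bin_mcg_cov: pd.DataFrame
    bin_mch: pd.DataFrame
    bin_mch_cov: pd.DataFrame
    dmr_mcg: pd.DataFrame
    dmr_mcg_cov: pd.DataFrame
    subclasses: list[str] = field(default_factory=list)

    def validate(self) -> None:
        for frac, cov in (
            (self.gene_mch, self.gene_mch_cov),
            (self.bin_mcg, self.bin_mcg_cov),
            (self.bin_mch, self.bin_mch_cov),
            (self.dmr_mcg, self.dmr_mcg_cov),
        ):
            if (cov.to_numpy() <= 0).any():
                raise ValueError("coverage must be positive everywhere")
            v = frac.to_numpy()
            if ((v < 0) | (v > 1)).any():
                raise ValueError("fractions must lie in [0, 1]")


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else v - v.mean()


def _rank01(v: np.ndarray) -> np.ndarray:
    """Rank-scale to [0, 1]: robust to outlying subclasses, so loop
    enrichment varies across all subclasses rather than only at extremes."""
    if np.ptp(v) == 0:
        return np.zeros_like(v, dtype=float)
    from scipy.stats import rankdata

    r = rankdata(v)
    return (r - 1) / (v.size - 1)


def _presence_subset(rng: np.random.Generator, n: int, fraction: float) -> np.ndarray:
    pres = rng.random(n) < fraction
    if pres.all():
        pres[rng.integers(n)] = False
    if not pres.any():
        pres[rng.integers(n)] = True
    return pres


def simulate_methylomes(
    genome: GenomeModel,
    truth_cfg: TruthConfig = TruthConfig(),
    n_subclasses: int = 8,
    seed: int = 0,
) -> tuple[SubclassMethylome, PlantedTruth]:
    """Plant the latent truth and sample the pseudo-bulk fraction matrices."""
    if n_subclasses < 2:
        raise ValueError("need at least 2 subclasses")
    cfg = truth_cfg
    rng = np.random.default_rng(seed)
    subclasses = [f"SC{i:02d}" for i in range(n_subclasses)]
    n = n_subclasses
    genes_by_id = genome.genes_by_id()

    # ------------------------------------------------------------------
    # compartments: consensus labels, with a few blocks flipped per subclass
    comp: dict[str, dict[str, np.ndarray]] = {s: {} for s in subclasses}
    switch_bins: dict[str, np.ndarray] = {}
    for chrom, _ in genome.chromosomes:
        base = genome.compartment_blocks[chrom]
        block_size = genome.config.compartment_block_bins if genome.config else 10
        n_blocks = int(np.ceil(base.size / block_size))
        interior = np.arange(1, max(n_blocks - 1, 2))
        k = min(cfg.n_switch_blocks, interior.size)
        switch_blocks = rng.choice(interior, size=k, replace=False) if k else np.array([], int)
        sw_bins = []
        flips = {s: np.zeros(base.size, bool) for s in subclasses}
        for b in switch_blocks:
            lo, hi = b * block_size, min((b + 1) * block_size, base.size)
            sw_bins.extend(range(lo, hi))
            pres = _presence_subset(rng, n, cfg.switch_fraction)
            for s, fl in zip(subclasses, pres):
                if fl:
                    flips[s][lo:hi] = True
        switch_bins[chrom] = np.array(sorted(sw_bins), dtype=int)
        for s in subclasses:
            lab = base.copy()
            lab[flips[s]] *= -1
            comp[s][chrom] = lab

    # ------------------------------------------------------------------
    # domain boundaries (25-kb bins); planted edge sits at (bin+1)*25000
    long_genes = [g for g in genome.genes if g.is_long and not g.is_tf]
    rng.shuffle(long_genes)
    coupling_genes = long_genes[: cfg.n_boundary_couplings]
    other_long = long_genes[cfg.n_boundary_couplings :]

    boundaries: dict[str, dict[str, list[int]]] = {s: {c: [] for c, _ in genome.chromosomes} for s in subclasses}
    boundary_presence: list[tuple[str, int, np.ndarray]] = []
    shared_bins: dict[str, list[int]] = {c: [] for c, _ in genome.chromosomes}
    couplings: list[BoundaryCoupling] = []
    used_bins: dict[str, set[int]] = {c: set() for c, _ in genome.chromosomes}

    block25 = (genome.config.compartment_block_bins if genome.config else 10) * 4

    def _free(chrom: str, b: int, min_sep: int = 8) -> bool:
        n25 = genome.n_bins(chrom, 25_000)
        if not (10 <= b < n25 - 10):
            return False
        # keep clear of compartment block edges, whose contact transition
        # would mask or mimic the planted insulation minimum
        if min(b % block25, block25 - b % block25) < 7:
            return False
        return all(abs(b - u) >= min_sep for u in used_bins[chrom])

    def _add_boundary(chrom: str, b: int, pres: np.ndarray) -> None:
        used_bins[chrom].add(b)
        boundary_presence.append((chrom, b, pres))
        for s, present in zip(subclasses, pres):
            if present:
                boundaries[s][chrom].append(b)
        if pres.all():
            shared_bins[chrom].append(b)

    # differential boundaries coupled to long-gene activity, at the TSS
    for g in coupling_genes:
        b = g.tss // 25_000
        if not _free(g.chrom, b):
            continue
        pres = _presence_subset(rng, n, cfg.diff_presence_fraction)
        _add_boundary(g.chrom, b, pres)
        couplings.append(BoundaryCoupling(g.id, g.chrom, b, pres))

    # remaining differential boundaries, preferentially at long-gene ends
    anchors_pool = [(g.chrom, g.tss // 25_000) for g in other_long] + [
        (g.chrom, g.tts // 25_000) for g in other_long
    ]
    rng.shuffle(anchors_pool)
    # capacity on small genomes is limited: stop after a bounded number of
    # placement attempts rather than insisting on the requested count
    placed_diff = len(couplings)
    attempts = 0
    while placed_diff < cfg.n_differential_boundaries and attempts < 60 * max(cfg.n_differential_boundaries, 1):
        attempts += 1
        if anchors_pool and rng.random() < cfg.boundary_at_gene_fraction:
            chrom, b = anchors_pool.pop()
        else:
            chrom = genome.chromosomes[int(rng.integers(len(genome.chromosomes)))][0]
            b = int(rng.integers(10, max(genome.n_bins(chrom, 25_000) - 10, 11)))
        if not _free(chrom, b):
            continue
        _add_boundary(chrom, b, _presence_subset(rng, n, cfg.diff_presence_fraction))
        placed_diff += 1

    placed_shared = 0
    attempts = 0
    while placed_shared < cfg.n_shared_boundaries and attempts < 60 * max(cfg.n_shared_boundaries, 1):
        attempts += 1
        if anchors_pool and rng.random() < cfg.boundary_at_gene_fraction:
            chrom, b = anchors_pool.pop()
        else:
            chrom = genome.chromosomes[int(rng.integers(len(genome.chromosomes)))][0]
            b = int(rng.integers(10, max(genome.n_bins(chrom, 25_000) - 10, 11)))
        if not _free(chrom, b):
            continue
        _add_boundary(chrom, b, np.ones(n, bool))
        placed_shared += 1

    # ------------------------------------------------------------------
    # latent gene mCH patterns (z-scale); default i.i.d. noise per gene
    patterns: dict[str, np.ndarray] = {g.id: rng.normal(size=n) for g in genome.genes}
    for bc in couplings:  # boundary present -> gene active -> mCH low
        raw = (~bc.presence).astype(float) + 0.05 * rng.normal(size=n)
        patterns[bc.gene_id] = _standardize(raw)

    # regulatory triples: masters are subclass-specific hubs, others cycle
    # through the four sign models
    tf_pool = [g for g in genome.tf_genes()]
    rng.shuffle(tf_pool)
    target_pool = [
        g
        for g in genome.genes
        if not g.is_tf and g.id not in {bc.gene_id for bc in couplings}
    ]
    rng.shuffle(target_pool)

    loops: list[PlantedLoop] = []
    dmrs: list[PlantedDMR] = []
    triples: list[PlantedTriple] = []
    master_tfs: dict[str, str] = {}
    E = cfg.loop_enrichment
    dmr_counter = 0

    def _plant_triple(tf, target, model_class: int, t_base: np.ndarray) -> bool:
        nonlocal dmr_counter
        sa, sb, sc = MODEL_SIGNS[model_class]
        t = _standardize(t_base + cfg.module_noise * rng.normal(size=n))
        patterns[target.id] = t
        # loop: one anchor in the gene body, one distal anchor holding the DMR
        n10 = genome.n_bins(target.chrom, 10_000)
        gb_lo, gb_hi = target.start // 10_000, (target.end - 1) // 10_000
        anchor_a = (gb_lo + gb_hi) // 2
        half_body = (gb_hi - gb_lo) // 2
        # enhancer-promoter range: short enough that per-pixel counts are
        # dense, long enough to clear the gene body
        lo = max(15, half_body + 4)
        offset = int(rng.integers(lo, lo + 45))
        if anchor_a + offset <= n10 - 3:
            anchor_b = anchor_a + offset
        elif anchor_a - offset >= 2:
            anchor_b = anchor_a - offset
        else:
            return False
        act = _rank01(t)  # insulation-style: contact strong when mCH high
        enr = 1.0 + (E - 1.0) * act
        dmr_id = f"dmr{dmr_counter:04d}"
        dmr_counter += 1
        d = _standardize(sa * t + cfg.module_noise * rng.normal(size=n))
        dstart = anchor_b * 10_000 + int(rng.integers(1_000, 8_000))
        dlen = int(rng.integers(150, 400))
        dmrs.append(
            PlantedDMR(
                dmr_id,
                target.chrom,
                dstart,
                dstart + dlen,
                np.clip(cfg.dmr_mcg_base + cfg.dmr_mcg_amp * d, 0.05, 0.95),
                tf_id=tf.id,
                gene_id=target.id,
            )
        )
        loops.append(
            PlantedLoop(
                target.chrom,
                min(anchor_a, anchor_b),
                max(anchor_a, anchor_b),
                enr,
                kind="triple",
                gene_id=target.id,
                dmr_id=dmr_id,
            )
        )
        triples.append(PlantedTriple(tf.id, dmr_id, target.id, model_class, len(loops) - 1))
        return True

    master_subclass_idx = rng.choice(n, size=min(cfg.n_master_tfs, len(tf_pool)), replace=False)
    ti = 0
    for mi, s_idx in enumerate(master_subclass_idx):
        tf = tf_pool[mi]
        master_tfs[tf.id] = subclasses[int(s_idx)]
        # a deep dip in the hub subclass riding on a shared smooth pattern,
        # so the module correlates across all subclasses, not just via the dip
        t_base = 0.8 + 0.45 * rng.normal(size=n)
        t_base[int(s_idx)] = -2.5
        patterns[tf.id] = _standardize(t_base + cfg.module_noise * rng.normal(size=n))
        for _ in range(cfg.master_targets):
            if ti < len(target_pool) and _plant_triple(tf, target_pool[ti], 1, t_base):
                ti += 1
    mc = 0
    for k in range(len(master_subclass_idx), min(len(master_subclass_idx) + cfg.n_triple_tfs, len(tf_pool))):
        tf = tf_pool[k]
        t_base = _standardize(rng.normal(size=n))
        model_class = cfg.model_cycle[mc % len(cfg.model_cycle)]
        mc += 1
        _, _, sc = MODEL_SIGNS[model_class]
        patterns[tf.id] = _standardize(sc * t_base + cfg.module_noise * rng.normal(size=n))
        for _ in range(cfg.targets_per_tf):
            if ti < len(target_pool) and _plant_triple(tf, target_pool[ti], model_class, t_base):
                ti += 1

    # variable loops with subclass-subset enrichment (pure HVI signal)
    for _ in range(cfg.n_subset_loops):
        chrom = genome.chromosomes[int(rng.integers(len(genome.chromosomes)))][0]
        n10 = genome.n_bins(chrom, 10_000)
        max_off = int(min(400, n10 - 30))
        bin_i = int(rng.integers(10, n10 - max_off - 5))
        bin_j = bin_i + int(rng.integers(6, max_off))
        pres = _presence_subset(rng, n, 0.4)
        enr = np.where(pres, E, 1.0)
        loops.append(PlantedLoop(chrom, bin_i, bin_j, enr, kind="subset"))

    # activity-style loops: contact strong where the gene is active (mCH low)
    neg_genes = [g for g in target_pool[ti:] if g.is_long][: cfg.n_negative_coupled_loops]
    for g in neg_genes:
        n10 = genome.n_bins(g.chrom, 10_000)
        anchor_a = (g.start // 10_000 + (g.end - 1) // 10_000) // 2
        offset = int(rng.integers(20, 150))
        anchor_b = anchor_a + offset if anchor_a + offset <= n10 - 3 else anchor_a - offset
        t = patterns[g.id]
        enr = 1.0 + (E - 1.0) * _rank01(-t)
        loops.append(
            PlantedLoop(g.chrom, min(anchor_a, anchor_b), max(anchor_a, anchor_b), enr, kind="negative_coupled", gene_id=g.id)
        )

    # decoy DMRs with unstructured patterns
    for _ in range(cfg.n_decoy_dmrs):
        chrom, clen = genome.chromosomes[int(rng.integers(len(genome.chromosomes)))]
        dstart = int(rng.integers(100_000, clen - 100_000))
        dlen = int(rng.integers(150, 400))
        d = _standardize(rng.normal(size=n))
        dmrs.append(
            PlantedDMR(
                f"dmr{dmr_counter:04d}",
                chrom,
                dstart,
                dstart + dlen,
                np.clip(cfg.dmr_mcg_base + cfg.dmr_mcg_amp * d, 0.05, 0.95),
            )
        )
        dmr_counter += 1

    # ------------------------------------------------------------------
    # latent fraction tables
    gene_ids = [g.id for g in genome.genes]
    latent_gene = pd.DataFrame(
        np.clip(
            cfg.mch_base + cfg.mch_amp * np.vstack([patterns[g] for g in gene_ids]),
            0.003,
            0.4,
        ),
        index=gene_ids,
        columns=subclasses,
    )
    latent_dmr = pd.DataFrame(
        np.vstack([d.latent_mcg for d in dmrs]), index=[d.id for d in dmrs], columns=subclasses
    )
    bin_index = pd.MultiIndex.from_tuples(
        [(c, b) for c, _ in genome.chromosomes for b in range(genome.n_bins(c, 100_000))],
        names=["chrom", "bin"],
    )
    lab_mat = np.vstack(
        [np.concatenate([comp[s][c] for c, _ in genome.chromosomes]) for s in subclasses]
    ).T  # bins x subclasses
    latent_bin_mcg = pd.DataFrame(
        np.clip(
            cfg.bin_mcg_base
            + cfg.bin_mcg_b_boost * (lab_mat == -1)
            + cfg.bin_jitter * rng.normal(size=lab_mat.shape),
            0.02,
            0.98,
        ),
        index=bin_index,
        columns=subclasses,
    )
    latent_bin_mch = pd.DataFrame(
        np.clip(0.03 + 0.004 * rng.normal(size=lab_mat.shape), 0.003, 0.3),
        index=bin_index,
        columns=subclasses,
    )

    # ------------------------------------------------------------------
    # base-level CpG sites with planted DMS
    sample_names = [f"S{i:02d}" for i in range(cfg.n_samples)]
    chrom0, clen0 = genome.chromosomes[0]
    candidates = np.arange(1_000, clen0 - 1_000, 10)
    pos = np.sort(rng.choice(candidates, size=min(cfg.n_cpg_sites, candidates.size), replace=False))
    is_dms = rng.random(pos.size) < cfg.dms_fraction
    levels = np.empty((pos.size, cfg.n_samples))
    base_level = rng.uniform(0.1, 0.9, size=pos.size)
    levels[:] = base_level[:, None]
    for i in np.flatnonzero(is_dms):
        c = rng.uniform(0.05 + cfg.dms_delta / 2, 0.95 - cfg.dms_delta / 2)
        hi = rng.permutation(cfg.n_samples) < cfg.n_samples // 2
        levels[i] = np.where(hi, c + cfg.dms_delta / 2, c - cfg.dms_delta / 2)
    dms_sites = pd.DataFrame({"chrom": chrom0, "pos": pos, "is_dms": is_dms})
    for j, s in enumerate(sample_names):
        dms_sites[f"level_{s}"] = levels[:, j]

    truth = PlantedTruth(
        subclasses=subclasses,
        compartment_labels=comp,
        switch_bins=switch_bins,
        boundaries={s: {c: np.array(sorted(v), int) for c, v in boundaries[s].items()} for s in subclasses},
        boundary_presence=boundary_presence,
        shared_boundary_bins={c: np.array(sorted(v), int) for c, v in shared_bins.items()},
        boundary_couplings=couplings,
        loops=loops,
        dmrs=dmrs,
        triples=triples,
        master_tfs=master_tfs,
        latent_gene_mch=latent_gene,
        latent_dmr_mcg=latent_dmr,
        latent_bin_mcg=latent_bin_mcg,
        latent_bin_mch=latent_bin_mch,
        dms_sites=dms_sites,
        config=cfg,
    )

    # ------------------------------------------------------------------
    # binomial sampling of the observed fraction matrices
    def _sample(latent: pd.DataFrame, mean_cov: int) -> tuple[pd.DataFrame, pd.DataFrame]:
        if mean_cov <= 0:
            raise ValueError("coverage must be positive")
        cov = np.maximum(rng.poisson(mean_cov, size=latent.shape), 1)
        mc = rng.binomial(cov, latent.to_numpy())
        frac = pd.DataFrame(mc / cov, index=latent.index, columns=latent.columns)
        return frac, pd.DataFrame(cov, index=latent.index, columns=latent.columns)

    gene_mch, gene_cov = _sample(latent_gene, cfg.gene_mch_cov)
    bin_mcg, bin_mcg_cov = _sample(latent_bin_mcg, cfg.bin_mcg_cov)
    bin_mch, bin_mch_cov = _sample(latent_bin_mch, cfg.bin_mch_cov)
    dmr_mcg, dmr_cov = _sample(latent_dmr, cfg.dmr_cov)

    methylome = SubclassMethylome(
        gene_mch=gene_mch,
        gene_mch_cov=gene_cov,
        bin_mcg=bin_mcg,
        bin_mcg_cov=bin_mcg_cov,
        bin_mch=bin_mch,
        bin_mch_cov=bin_mch_cov,
        dmr_mcg=dmr_mcg,
        dmr_mcg_cov=dmr_cov,
        subclasses=subclasses,
    )
    methylome.validate()
    return methylome, truth
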