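"""Planted-truth record and its configuration.

:class:`PlantedTruth` is the generator's complete account of every
structure it planted — compartment labels per subclass, domain-boundary
positions and presence patterns, variable loops with per-subclass
enrichment, DMS levels, DMR intervals with latent mCG, and TF-DMR-target
triples with their intended sign model.  Analysis modules never read it;
tests use it as the recovery oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TruthConfig",
    "PlantedLoop",
    "PlantedDMR",
    "PlantedTriple",
    "BoundaryCoupling",
    "PlantedTruth",
    "MODEL_SIGNS",
]

# intended correlation signs (Sa, Sb, Sc) for the four regulatory models:
# Sa = corr(DMR mCG, target mCH), Sb = corr(TF mCH, DMR mCG),
# Sc = corr(TF mCH, target mCH).  All four have sign product +1.
MODEL_SIGNS: dict[int, tuple[int, int, int]] = {
    1: (1, 1, 1),
    2: (1, -1, -1),
    3: (-1, -1, 1),
    4: (-1, 1, -1),
}


@dataclass(frozen=True)
class TruthConfig:
    """What to plant.  Defaults define the package's study conditions."""

    # compartments: blocks whose A/B label flips in a subset of subclasses
    n_switch_blocks: int = 2
    switch_fraction: float = 0.5
    # domain boundaries (25-kb bins)
    n_shared_boundaries: int = 10
    n_differential_boundaries: int = 12
    boundary_at_gene_fraction: float = 0.6
    diff_presence_fraction: float = 0.5
    n_boundary_couplings: int = 3
    # variable loops (10-kb pixels)
    n_subset_loops: int = 12
    n_negative_coupled_loops: int = 4
    loop_enrichment: float = 8.0
    # regulatory triples
    n_triple_tfs: int = 6
    targets_per_tf: int = 2
    n_master_tfs: int = 2
    master_targets: int = 6
    model_cycle: tuple[int, ...] = (1, 2, 3, 4)
    n_decoy_dmrs: int = 20
    module_noise: float = 0.12
    # methylation scales (fractions)
    mch_base: float = 0.03
    mch_amp: float = 0.011
    dmr_mcg_base: float = 0.6
    dmr_mcg_amp: float = 0.18
    bin_mcg_base: float = 0.7
    bin_mcg_b_boost: float = 0.06
    bin_jitter: float = 0.008
    # pseudo-bulk base-call coverages (mean counts per feature x subclass)
    gene_mch_cov: int = 20_000
    bin_mcg_cov: int = 3_000
    bin_mch_cov: int = 30_000
    dmr_cov: int = 1500
    # base-level CpG count table
    n_cpg_sites: int = 3_000
    dms_fraction: float = 0.25
    dms_delta: float = 0.6
    n_samples: int = 8


@dataclass
class PlantedLoop:
    chrom: str
    bin_i: int  # 10-kb bin
    bin_j: int
    enrichment: np.ndarray  # per subclass, multiplicative
    kind: str  # subset | positive_coupled | negative_coupled | triple
    gene_id: str | None = None
    dmr_id: str | None = None


@dataclass
class PlantedDMR:
    id: str
    chrom: str
    start: int
    end: int
    latent_mcg: np.ndarray  # per subclass
    tf_id: str | None = None
    gene_id: str | None = None


@dataclass(frozen=True)
class PlantedTriple:
    tf_id: str
    dmr_id: str
    gene_id: str
    model_class: int
    loop_index: int

    @property
    def signs(self) -> tuple[int, int, int]:
        return MODEL_SIGNS[self.model_class]


@dataclass
class BoundaryCoupling:
    gene_id: str
    chrom: str
    bin25: int
    presence: np.ndarray  # bool per subclass


@dataclass
class PlantedTruth:
    subclasses: list[str]
    # +1 = A, -1 = B per 100-kb bin, per subclass
    compartment_labels: dict[str, dict[str, np.ndarray]]
    switch_bins: dict[str, np.ndarray]
    # sorted 25-kb bin indices per subclass; plus presence records
    boundaries: dict[str, dict[str, np.ndarray]]
    boundary_presence: list[tuple[str, int, np.ndarray]]  # (chrom, bin25, bool/subclass)
    shared_boundary_bins: dict[str, np.ndarray]
    boundary_couplings: list[BoundaryCoupling]
    loops: list[PlantedLoop]
    dmrs: list[PlantedDMR]
    triples: list[PlantedTriple]
    master_tfs: dict[str, str]  # tf_id -> subclass in which it is the hub
    latent_gene_mch: pd.DataFrame  # genes x subclasses, pre-sampling fractions
    latent_dmr_mcg: pd.DataFrame
    latent_bin_mcg: pd.DataFrame
    latent_bin_mch: pd.DataFrame
    dms_sites: pd.DataFrame  # chrom, pos, is_dms, level_<sample> columns
    config: TruthConfig = field(repr=False, default=None)

    @property
    def n_subclasses(self) -> int:
        return len(self.subclasses)

    def subclass_index(self, subclass: str) -> int:
        return self.subclasses.index(subclass)

    def differential_boundary_bins(self, chrom: str) -> np.ndarray:
        return np.array(
            sorted(b for c, b, pres in self.boundary_presence if c == chrom and 0 < pres.sum() < pres.size),
            dtype=int,
        )

    def dmr_by_id(self) -> dict[str, PlantedDMR]:
        return {d.id: d for d in self.dmrs}

    def validate(self, genome) -> None:
        """Cross-check invariants against the genome model (used by tests)."""
        gene_ids = {g.id for g in genome.genes}
        dmr_ids = {d.id for d in self.dmrs}
        for t in self.triples:
            assert t.tf_id in gene_ids and t.gene_id in gene_ids
            assert t.dmr_id in dmr_ids
            sa, sb, sc = t.signs
            assert sa * sb * sc == 1
        for loop in self.loops:
            d_bp = abs(loop.bin_j - loop.bin_i) * 10_000
            assert 50_000 <= d_bp <= 5_000_000
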