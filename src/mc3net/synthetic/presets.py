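"""Canonical study conditions for the synthetic atlas.

Three presets cover the package's standard experiments:

* :func:`atlas_config` — a 20 Mb genome profiled in 5 subclasses of 40
  cells: the conditions for compartment, domain-boundary, and highly
  variable interaction recovery (cell-level statistics powered by cell
  counts, not subclass counts).
* :func:`grn_config` — an 8 Mb gene-dense genome profiled in 30
  subclasses of 16 cells: the conditions for the cross-subclass
  correlation screens behind the regulatory network.  Correlation FDR at
  the 0.001 threshold needs tens of subclasses to be reachable at all
  (the screens correlate across subclasses, not cells), and quantile
  normalization needs a few hundred gene features to preserve
  correlation structure.
* :func:`null_config` — no planted structure, for calibration checks.
"""

from __future__ import annotations

from .genome import GenomeConfig
from .truth import TruthConfig

__all__ = ["atlas_config", "grn_config", "null_config"]


def atlas_config() -> tuple[GenomeConfig, TruthConfig, int, int]:
    """(genome, truth, n_subclasses, cells_per_subclass) for structural recovery."""
    return GenomeConfig(), TruthConfig(), 5, 40


def grn_config() -> tuple[GenomeConfig, TruthConfig, int, int]:
    """(genome, truth, n_subclasses, cells_per_subclass) for network recovery.

    The contact background is kept free of planted compartment switches
    and differential boundaries so the highly variable interactions are
    loop-driven and the gene-interaction correlation family stays small.
    """
    genome = GenomeConfig(chromosomes=(("chr1", 8_000_000),), n_genes=220, n_tfs=10)
    truth = TruthConfig(
        n_switch_blocks=0,
        n_shared_boundaries=6,
        n_differential_boundaries=0,
        n_boundary_couplings=0,
        n_subset_loops=4,
        n_negative_coupled_loops=3,
        n_master_tfs=2,
        master_targets=5,
        n_triple_tfs=6,
        targets_per_tf=2,
        n_decoy_dmrs=150,
        module_noise=0.08,
    )
    return genome, truth, 30, 16


def null_config(n_genes: int = 60, chrom_mb: int = 10) -> tuple[GenomeConfig, TruthConfig]:
    """A genome with no planted structure beyond the consensus blocks."""
    genome = GenomeConfig(chromosomes=(("chr1", chrom_mb * 1_000_000),), n_genes=n_genes)
    truth = TruthConfig(
        n_switch_blocks=0,
        n_shared_boundaries=0,
        n_differential_boundaries=0,
        n_boundary_couplings=0,
        n_subset_loops=0,
        n_negative_coupled_loops=0,
        n_master_tfs=0,
        master_targets=0,
        n_triple_tfs=0,
        targets_per_tf=0,
        n_decoy_dmrs=30,
        dms_fraction=0.0,
    )
    return genome, truth
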