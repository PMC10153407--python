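"""Miniature genome model: chromosomes, bins, CpG density, genes, motifs.

Coordinates are 0-based half-open throughout; the bin holding position
``p`` at resolution ``r`` is ``p // r``.  Genes longer than 100 kb are
"long" genes — the class whose gene-body domains and mCH coupling the
boundary and interaction analyses focus on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

RESOLUTIONS = (100_000, 25_000, 10_000)
LONG_GENE_BP = 100_000

__all__ = ["Gene", "Motif", "GenomeConfig", "GenomeModel", "simulate_genome", "RESOLUTIONS"]


@dataclass(frozen=True)
class Gene:
    id: str
    chrom: str
    start: int
    end: int
    strand: str
    is_tf: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def is_long(self) -> bool:
        return self.length > LONG_GENE_BP

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tts(self) -> int:
        return self.end if self.strand == "+" else self.start


@dataclass(frozen=True)
class Motif:
    id: str
    tfs: tuple[str, ...]


@dataclass(frozen=True)
class GenomeConfig:
    chromosomes: tuple[tuple[str, int], ...] = (("chr1", 20_000_000),)
    n_genes: int = 60
    long_gene_fraction: float = 0.35
    n_tfs: int = 10
    compartment_block_bins: int = 10  # 100-kb bins per A/B block (1 Mb)
    cpg_base: float = 60.0  # expected CpG count per 100-kb bin in B
    cpg_block_boost: float = 70.0  # extra CpG density in A blocks
    short_gene_bp: tuple[int, int] = (15_000, 80_000)
    long_gene_bp: tuple[int, int] = (120_000, 400_000)
    gene_gap_bp: tuple[int, int] = (20_000, 120_000)


@dataclass
class GenomeModel:
    chromosomes: tuple[tuple[str, int], ...]
    cpg_density: dict[str, np.ndarray]  # per 100-kb bin
    compartment_blocks: dict[str, np.ndarray]  # +1 = A, -1 = B, per 100-kb bin
    genes: list[Gene]
    motifs: list[Motif]
    config: GenomeConfig = field(repr=False, default=None)

    def chrom_length(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(chrom)

    def n_bins(self, chrom: str, resolution: int) -> int:
        return math.ceil(self.chrom_length(chrom) / resolution)

    def bin_starts(self, chrom: str, resolution: int) -> np.ndarray:
        return np.arange(self.n_bins(chrom, resolution)) * resolution

    def tf_genes(self) -> list[Gene]:
        return [g for g in self.genes if g.is_tf]

    def genes_by_id(self) -> dict[str, Gene]:
        return {g.id: g for g in self.genes}

    def block_labels(self, chrom: str, resolution: int) -> np.ndarray:
        """Consensus A/B signs resampled from 100 kb to ``resolution``."""
        labels = self.compartment_blocks[chrom]
        factor = 100_000 // resolution
        return np.repeat(labels, factor)[: self.n_bins(chrom, resolution)]


def simulate_genome(config: GenomeConfig = GenomeConfig(), seed: int = 0) -> GenomeModel:
    """Draw a deterministic genome model from the configuration and seed.

    A/B architecture is planted as alternating blocks of
    ``compartment_block_bins`` 100-kb bins; CpG density is elevated in A
    blocks so that compartment orientation by CpG density is meaningful.
    """
    if not config.chromosomes:
        raise ValueError("configuration error: need at least one chromosome")
    if config.n_genes < 1:
        raise ValueError("configuration error: need at least one gene")
    for name, length in config.chromosomes:
        if length < 1_000_000:
            raise ValueError(f"chromosome {name} shorter than 1 Mb")
    if not 0 <= config.long_gene_fraction <= 1:
        raise ValueError("long_gene_fraction must be in [0, 1]")

    rng = np.random.default_rng(seed)
    blocks: dict[str, np.ndarray] = {}
    cpg: dict[str, np.ndarray] = {}
    for ci, (name, length) in enumerate(config.chromosomes):
        n100 = math.ceil(length / 100_000)
        block_idx = np.arange(n100) // config.compartment_block_bins
        start_sign = 1 if (ci % 2 == 0) else -1
        labels = np.where(block_idx % 2 == 0, start_sign, -start_sign).astype(np.int8)
        blocks[name] = labels
        lam = config.cpg_base + config.cpg_block_boost * (labels == 1)
        cpg[name] = rng.poisson(lam).astype(float)

    # place genes sequentially with random gaps, round-robin over chromosomes
    genes: list[Gene] = []
    cursors = {name: rng.integers(50_000, 150_000) for name, _ in config.chromosomes}
    chrom_cycle = [name for name, _ in config.chromosomes]
    lengths = dict(config.chromosomes)
    gi = 0
    exhausted: set[str] = set()
    while gi < config.n_genes:
        chrom = chrom_cycle[gi % len(chrom_cycle)]
        long = rng.random() < config.long_gene_fraction
        lo, hi = config.long_gene_bp if long else config.short_gene_bp
        glen = int(rng.integers(lo, hi))
        if chrom in exhausted:
            # layout full: further genes overlap at random positions, as
            # real transcripts do in gene-dense regions
            start = int(rng.integers(50_000, lengths[chrom] - glen - 50_000))
        else:
            start = int(cursors[chrom])
            if start + glen > lengths[chrom] - 50_000:
                exhausted.add(chrom)
                continue
        end = start + glen
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(Gene(f"gene{gi:04d}", chrom, start, end, strand))
        if chrom not in exhausted:
            cursors[chrom] = end + int(rng.integers(*config.gene_gap_bp))
        gi += 1

    short_idx = [i for i, g in enumerate(genes) if not g.is_long]
    if len(short_idx) < config.n_tfs:
        short_idx = list(range(len(genes)))
    tf_idx = rng.choice(short_idx, size=min(config.n_tfs, len(short_idx)), replace=False)
    for i in sorted(tf_idx):
        g = genes[i]
        genes[i] = Gene(g.id, g.chrom, g.start, g.end, g.strand, is_tf=True)
    motifs = [Motif(f"motif_{genes[i].id}", (genes[i].id,)) for i in sorted(tf_idx)]

    return GenomeModel(
        chromosomes=tuple(config.chromosomes),
        cpg_density=cpg,
        compartment_blocks=blocks,
        genes=genes,
        motifs=motifs,
        config=config,
    )
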