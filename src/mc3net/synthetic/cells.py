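"""Per-cell cis contact-pair simulation.

Pairs are drawn per cell from a fixed per-subclass pixel distribution at
10-kb resolution: a power-law distance decay (default exponent -1)
modulated by planted compartment blocks (same-label pixels enriched),
attenuated across planted domain boundaries, and multiplied by loop
enrichment at planted loop pixels.  A cell's contact count is fixed, so
pixel counts are a multinomial draw, and base-pair positions are uniform
within the chosen bins.  Only cis contacts are generated — the analyses
in scope all operate on cis matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import GenomeModel
from .truth import PlantedTruth

__all__ = ["ContactCell", "ContactCellSet", "simulate_contact_cells", "expected_pixel_rates"]

_SIM_RES = 10_000


@dataclass
class ContactCell:
    cell_id: str
    subclass: str
    pairs: dict[str, tuple[np.ndarray, np.ndarray]]  # chrom -> (pos_a, pos_b)

    @property
    def n_contacts(self) -> int:
        return sum(a.size for a, _ in self.pairs.values())


@dataclass
class ContactCellSet:
    cells: list[ContactCell]

    @property
    def labels(self) -> list[str]:
        return [c.subclass for c in self.cells]

    def __iter__(self):
        return iter(self.cells)

    def __len__(self) -> int:
        return len(self.cells)


def _flat_upper_index(i: np.ndarray, j: np.ndarray, n: int) -> np.ndarray:
    """Index of (i < j) into the row-major upper triangle (k=1) of n x n."""
    i = np.asarray(i)
    j = np.asarray(j)
    return (i * (2 * n - i - 1)) // 2 + (j - i - 1)


def expected_pixel_rates(
    genome: GenomeModel,
    truth: PlantedTruth,
    subclass: str,
    chrom: str,
    decay_exponent: float = -1.0,
    compartment_delta: float = 0.6,
    boundary_attenuation: float = 0.4,
    max_boundary_cross: int = 2,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unnormalized pixel weights (rows, cols, weight) at 10 kb, i < j.

    This is the generator's own expected-rate table; tests use it as the
    oracle for planted-loop enrichment over distance-matched background.
    """
    if subclass not in truth.subclasses:
        raise ValueError(f"unknown subclass {subclass!r}")
    n = genome.n_bins(chrom, _SIM_RES)
    rows, cols = np.triu_indices(n, k=1)
    d = (cols - rows).astype(float)
    w = d**decay_exponent
    if compartment_delta != 0.0:
        labels100 = truth.compartment_labels[subclass][chrom].astype(float)
        s = np.repeat(labels100, 100_000 // _SIM_RES)[:n]
        w = w * (1.0 + compartment_delta * s[rows] * s[cols])
    edges = (np.sort(truth.boundaries[subclass][chrom]) + 1) * 25_000
    if edges.size:
        centers = np.arange(n) * _SIM_RES + _SIM_RES // 2
        cum = np.searchsorted(edges, centers, side="right")
        ncross = np.minimum(cum[cols] - cum[rows], max_boundary_cross)
        w = w * boundary_attenuation**ncross
    si = truth.subclass_index(subclass)
    for loop in truth.loops:
        if loop.chrom != chrom:
            continue
        # loop "dots" span a 3x3 pixel neighborhood (~30 kb), as chromatin
        # loops do at 10-kb resolution
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                i, j = loop.bin_i + di, loop.bin_j + dj
                if 0 <= i < j < n:
                    w[_flat_upper_index(i, j, n)] *= loop.enrichment[si]
    return rows, cols, w


def simulate_contact_cells(
    genome: GenomeModel,
    truth: PlantedTruth,
    n_cells_per_subclass: int,
    contacts_per_cell: int = 100_000,
    seed: int = 0,
    subclasses: list[str] | None = None,
    decay_exponent: float = -1.0,
    compartment_delta: float = 0.6,
    boundary_attenuation: float = 0.4,
) -> ContactCellSet:
    """Draw per-cell cis contact pairs for every subclass."""
    if contacts_per_cell < 100:
        raise ValueError("contacts_per_cell must be >= 100")
    subclasses = list(subclasses) if subclasses is not None else list(truth.subclasses)
    for s in subclasses:
        if s not in truth.subclasses:
            raise ValueError(f"unknown subclass {s!r}")
    rng = np.random.default_rng(seed)
    chrom_lengths = dict(genome.chromosomes)
    cells: list[ContactCell] = []
    for s in subclasses:
        per_chrom = []
        totals = []
        for chrom, _ in genome.chromosomes:
            rows, cols, w = expected_pixel_rates(
                genome,
                truth,
                s,
                chrom,
                decay_exponent=decay_exponent,
                compartment_delta=compartment_delta,
                boundary_attenuation=boundary_attenuation,
            )
            cdf = np.cumsum(w)
            totals.append(cdf[-1])
            per_chrom.append((chrom, rows, cols, cdf))
        totals = np.asarray(totals)
        chrom_p = totals / totals.sum()
        for k in range(n_cells_per_subclass):
            counts = rng.multinomial(contacts_per_cell, chrom_p)
            pairs: dict[str, tuple[np.ndarray, np.ndarray]] = {}
            for (chrom, rows, cols, cdf), m in zip(per_chrom, counts):
                if m == 0:
                    continue
                u = rng.random(m) * cdf[-1]
                idx = np.searchsorted(cdf, u, side="right")
                bi, bj = rows[idx], cols[idx]
                L = chrom_lengths[chrom]
                size_a = np.minimum(_SIM_RES, L - bi * _SIM_RES)
                size_b = np.minimum(_SIM_RES, L - bj * _SIM_RES)
                pos_a = bi * _SIM_RES + rng.integers(0, size_a)
                pos_b = bj * _SIM_RES + rng.integers(0, size_b)
                pairs[chrom] = (pos_a.astype(np.int32), pos_b.astype(np.int32))
            cells.append(ContactCell(f"{s}_cell{k:03d}", s, pairs))
    return ContactCellSet(cells=cells)
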