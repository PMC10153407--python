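"""Base-level CpG count table simulation (ALLC-style input).

Each CpG is emitted as a +/- strand pair at (pos, pos+1); the site's
total coverage per sample is Poisson around ``mean_cov``, split
binomially between strands, and methylated calls are
Binomial(strand coverage, true level).  Planted DMS carry between-sample
level differences recorded in the truth table; all other sites share one
level across samples.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import GenomeModel
from .truth import PlantedTruth

__all__ = ["simulate_base_counts"]


def simulate_base_counts(
    genome: GenomeModel,
    truth: PlantedTruth,
    samples: int | None = None,
    mean_cov: int = 60,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample a strand-resolved site x sample count table.

    Returns a DataFrame with index (chrom, pos, strand) and MultiIndex
    columns (sample, {mc, cov}).  The '+' row of a CpG sits at the site
    position and the '-' row at position + 1.
    """
    level_cols = [c for c in truth.dms_sites.columns if c.startswith("level_")]
    sample_names = [c.removeprefix("level_") for c in level_cols]
    if samples is None:
        samples = len(sample_names)
    if samples < 2:
        raise ValueError("need at least 2 samples")
    if samples != len(sample_names):
        raise ValueError(
            f"truth table has levels for {len(sample_names)} samples, requested {samples}"
        )
    if mean_cov < 5:
        raise ValueError("mean_cov must be >= 5")

    rng = np.random.default_rng(seed)
    sites = truth.dms_sites
    levels = sites[level_cols].to_numpy()  # sites x samples
    n_sites, n_samp = levels.shape
    cov_total = rng.poisson(mean_cov, size=(n_sites, n_samp))
    cov_plus = rng.binomial(cov_total, 0.5)
    cov_minus = cov_total - cov_plus
    mc_plus = rng.binomial(cov_plus, levels)
    mc_minus = rng.binomial(cov_minus, levels)

    chroms = np.repeat(sites["chrom"].to_numpy(), 2)
    pos = np.empty(2 * n_sites, dtype=np.int64)
    pos[0::2] = sites["pos"].to_numpy()
    pos[1::2] = sites["pos"].to_numpy() + 1
    strand = np.tile(["+", "-"], n_sites)
    index = pd.MultiIndex.from_arrays([chroms, pos, strand], names=["chrom", "pos", "strand"])
    data = {}
    for j, s in enumerate(sample_names):
        mc = np.empty(2 * n_sites, dtype=np.int64)
        cov = np.empty(2 * n_sites, dtype=np.int64)
        mc[0::2], mc[1::2] = mc_plus[:, j], mc_minus[:, j]
        cov[0::2], cov[1::2] = cov_plus[:, j], cov_minus[:, j]
        data[(s, "mc")] = mc
        data[(s, "cov")] = cov
    table = pd.DataFrame(data, index=index)
    table.columns = pd.MultiIndex.from_tuples(table.columns, names=["sample", "field"])
    return table
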