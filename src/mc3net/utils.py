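"""Small shared helpers (interval/bin bookkeeping)."""

from __future__ import annotations

import numpy as np

__all__ = ["blacklist_bin_mask", "intervals_overlap"]


def blacklist_bin_mask(
    blacklist: list[tuple[str, int, int]] | None,
    chrom: str,
    chrom_length: int,
    resolution: int,
) -> np.ndarray:
    """Boolean mask, True for bins overlapping a blacklist interval."""
    n = -(-chrom_length // resolution)
    mask = np.zeros(n, dtype=bool)
    if not blacklist:
        return mask
    for c, start, end in blacklist:
        if c != chrom or end <= start:
            continue
        lo = max(start // resolution, 0)
        hi = min(-(-end // resolution), n)
        mask[lo:hi] = True
    return mask


def intervals_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    """Half-open interval overlap."""
    return a_start < b_end and b_start < a_end
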