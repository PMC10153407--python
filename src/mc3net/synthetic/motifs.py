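"""Synthetic DMR x motif score matrix.

Stands in for an HMM motif scan of DMR sequences: each planted triple's
TF motif receives a score above the occurrence threshold in that
triple's DMR, while decoy motifs (and planted motifs outside their own
DMRs) draw exchangeable background scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeModel
from .truth import PlantedTruth

__all__ = ["MotifScoreMatrix", "simulate_motif_db"]


@dataclass
class MotifScoreMatrix:
    scores: pd.DataFrame  # DMR x motif, nonnegative
    thresholds: pd.Series  # occurrence threshold per motif
    annotation: dict[str, tuple[str, ...]]  # motif -> annotated TF gene ids

    def __post_init__(self) -> None:
        if (self.scores.to_numpy() < 0).any():
            raise ValueError("motif scores must be nonnegative")
        if set(self.scores.columns) != set(self.thresholds.index):
            raise ValueError("threshold index must match motif columns")

    def motifs_for_tf(self, tf_id: str) -> list[str]:
        return [m for m, tfs in self.annotation.items() if tf_id in tfs]


def simulate_motif_db(
    genome: GenomeModel,
    truth: PlantedTruth,
    n_decoy_motifs: int = 100,
    seed: int = 0,
    threshold: float = 3.0,
) -> MotifScoreMatrix:
    """Draw motif scores over the planted DMR catalog."""
    if n_decoy_motifs < 0:
        raise ValueError("n_decoy_motifs must be >= 0")
    rng = np.random.default_rng(seed)
    dmr_ids = [d.id for d in truth.dmrs]
    planted_tfs = sorted({t.tf_id for t in truth.triples})
    catalog = [m for m in genome.motifs if any(tf in planted_tfs for tf in m.tfs)]
    tf_ids = [g.id for g in genome.tf_genes()] or ["none"]
    decoys = [f"decoy{k:03d}" for k in range(n_decoy_motifs)]
    motif_ids = [m.id for m in catalog] + decoys
    annotation: dict[str, tuple[str, ...]] = {m.id: m.tfs for m in catalog}
    for d in decoys:
        annotation[d] = (tf_ids[int(rng.integers(len(tf_ids)))],)

    # exchangeable background scores for every (DMR, motif) cell
    scores = rng.exponential(1.0, size=(len(dmr_ids), len(motif_ids)))
    df = pd.DataFrame(scores, index=dmr_ids, columns=motif_ids)
    # planted occurrences: the TF's motif is elevated in its triples' DMRs
    tf_motif = {m.tfs[0]: m.id for m in catalog}
    for t in truth.triples:
        motif = tf_motif.get(t.tf_id)
        if motif is not None:
            df.loc[t.dmr_id, motif] = threshold + 2.0 + rng.exponential(1.0)
    thresholds = pd.Series(threshold, index=motif_ids)
    return MotifScoreMatrix(scores=df, thresholds=thresholds, annotation=annotation)
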