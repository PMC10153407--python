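"""Plain-text writers for the synthetic atlas.

All coordinates are 0-based half-open (BED convention).
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cells import ContactCellSet
from .genome import GenomeModel
from .truth import PlantedTruth

__all__ = [
    "write_contact_pairs",
    "write_allc",
    "write_genes_bed12",
    "write_dmrs_bed",
    "write_fraction_matrix",
    "write_truth_json",
]

_HEADER = "# coordinates: 0-based half-open\n"


def write_contact_pairs(cellset: ContactCellSet, path: str | Path) -> Path:
    """Gzip TSV of (cell, chrom_a, pos_a, chrom_b, pos_b); cis pairs only."""
    path = Path(path)
    with gzip.open(path, "wt") as fh:
        fh.write(_HEADER)
        fh.write("cell\tchrom_a\tpos_a\tchrom_b\tpos_b\n")
        for cell in cellset:
            for chrom, (a, b) in cell.pairs.items():
                for pa, pb in zip(a.tolist(), b.tolist()):
                    fh.write(f"{cell.cell_id}\t{chrom}\t{pa}\t{chrom}\t{pb}\n")
    return path


def write_allc(table: pd.DataFrame, sample: str, path: str | Path) -> Path:
    """ALLC-style TSV (chrom, pos, strand, context, mc, cov, 1) for one sample."""
    path = Path(path)
    sub = table[sample]
    with open(path, "w") as fh:
        for (chrom, pos, strand), row in sub.iterrows():
            fh.write(f"{chrom}\t{pos}\t{strand}\tCGN\t{int(row['mc'])}\t{int(row['cov'])}\t1\n")
    return path


def write_genes_bed12(genome: GenomeModel, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_HEADER)
        for g in genome.genes:
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.id}\t{int(g.is_tf)}\t{g.strand}\t"
                f"{g.start}\t{g.end}\t0\t1\t{g.length},\t0,\n"
            )
    return path


def write_dmrs_bed(truth: PlantedTruth, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_HEADER)
        for d in truth.dmrs:
            fh.write(f"{d.chrom}\t{d.start}\t{d.end}\t{d.id}\n")
    return path


def write_fraction_matrix(frame: pd.DataFrame, path: str | Path) -> Path:
    """TSV with a header row of subclass ids; index columns are preserved."""
    path = Path(path)
    frame.to_csv(path, sep="\t")
    return path


def write_truth_json(truth: PlantedTruth, path: str | Path) -> Path:
    def _arr(a):
        return np.asarray(a).tolist()

    payload = {
        "subclasses": truth.subclasses,
        "compartment_labels": {
            s: {c: _arr(v) for c, v in d.items()} for s, d in truth.compartment_labels.items()
        },
        "switch_bins": {c: _arr(v) for c, v in truth.switch_bins.items()},
        "boundaries": {s: {c: _arr(v) for c, v in d.items()} for s, d in truth.boundaries.items()},
        "boundary_presence": [
            {"chrom": c, "bin": int(b), "presence": _arr(p)} for c, b, p in truth.boundary_presence
        ],
        "boundary_couplings": [
            {"gene": bc.gene_id, "chrom": bc.chrom, "bin": int(bc.bin25), "presence": _arr(bc.presence)}
            for bc in truth.boundary_couplings
        ],
        "loops": [
            {
                "chrom": lp.chrom,
                "bin_i": int(lp.bin_i),
                "bin_j": int(lp.bin_j),
                "enrichment": _arr(lp.enrichment),
                "kind": lp.kind,
                "gene": lp.gene_id,
                "dmr": lp.dmr_id,
            }
            for lp in truth.loops
        ],
        "dmrs": [
            {
                "id": d.id,
                "chrom": d.chrom,
                "start": int(d.start),
                "end": int(d.end),
                "latent_mcg": _arr(d.latent_mcg),
                "tf": d.tf_id,
                "gene": d.gene_id,
            }
            for d in truth.dmrs
        ],
        "triples": [
            {
                "tf": t.tf_id,
                "dmr": t.dmr_id,
                "gene": t.gene_id,
                "model_class": t.model_class,
                "loop_index": t.loop_index,
            }
            for t in truth.triples
        ],
        "master_tfs": truth.master_tfs,
        "dms_sites": truth.dms_sites.to_dict(orient="list"),
    }
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(payload, fh)
    return path
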