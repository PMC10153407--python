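"""Configuration, orchestration and reporting.

The pipeline binds the synthetic generator and the analysis stages into
a reproducible run: a validated configuration (all thresholds carry
their standard defaults), stages executed in dependency order, plain
text outputs, and a manifest with per-stage output checksums so
identical config + seed reproduces identical deterministic outputs.
"""

from __future__ import annotations

import difflib
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import workflow
from .synthetic import (
    GenomeConfig,
    TruthConfig,
    io as synth_io,
    simulate_base_counts,
    simulate_contact_cells,
    simulate_genome,
    simulate_methylomes,
    simulate_motif_db,
)

logger = logging.getLogger("mc3net")

__all__ = ["PipelineConfig", "RunManifest", "validate_config", "run_pipeline", "write_report"]

STAGE_DEPS = {
    "simulate": [],
    "contacts": ["simulate"],
    "compartments": ["contacts"],
    "boundaries": ["contacts"],
    "interactions": ["contacts"],
    "dmr": ["simulate"],
    "grn": ["interactions"],
    "pagerank": ["grn"],
    "report": [],
}

_DEFAULTS = {
    "outdir": "mc3net_out",
    "seed": 0,
    "n_subclasses": 6,
    "n_cells_per_subclass": 8,
    "contacts_per_cell": 20_000,
    "genome": {},
    "truth": {},
    "stages": list(STAGE_DEPS),
    # thresholds at their standard values
    "min_cis_distance": 2_500,
    "f_min": 3.0,
    "nes_min": 3.0,
    "fdr_boundary": 1e-3,
    "fdr_interaction": 1e-3,
    "fdr_edge": 1e-3,
    "dms_q": 0.01,
    "merge_gap": 250,
    "merge_pcc": 0.3,
    "site_cap": 50,
    "total_cap": 3_000,
    "quantile_range": (0.1, 0.9),
    "n_shuffles": 1000,
    "n_perm": 1000,
    "topdom_w": 5,
}


@dataclass
class PipelineConfig:
    values: dict = field(default_factory=dict)

    def __getattr__(self, name):
        try:
            return self.values[name]
        except KeyError as e:  # pragma: no cover
            raise AttributeError(name) from e


@dataclass
class RunManifest:
    config_hash: str
    version: str
    stages: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({"config_hash": self.config_hash, "version": self.version, "stages": self.stages}, indent=2)


def validate_config(source) -> PipelineConfig:
    """Load and validate a YAML/JSON/dict configuration.

    Unknown keys are rejected with a suggestion; thresholds must be
    positive; all errors are aggregated into one message.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    elif isinstance(source, dict):
        raw = dict(source)
    else:
        raise TypeError("config source must be a path or dict")
    errors = []
    for key in raw:
        if key not in _DEFAULTS:
            hint = difflib.get_close_matches(key, _DEFAULTS, n=1)
            suffix = f" (did you mean {hint[0]!r}?)" if hint else ""
            errors.append(f"unknown key {key!r}{suffix}")
    values = dict(_DEFAULTS)
    values.update({k: v for k, v in raw.items() if k in _DEFAULTS})
    for key in ("f_min", "nes_min", "fdr_boundary", "fdr_interaction", "fdr_edge", "dms_q", "merge_gap", "site_cap", "total_cap", "n_shuffles", "n_perm"):
        if not (isinstance(values[key], (int, float)) and values[key] > 0):
            errors.append(f"{key} must be a positive number")
    unknown_stages = [s for s in values["stages"] if s not in STAGE_DEPS]
    if unknown_stages:
        errors.append(f"unknown stages: {unknown_stages}")
    if errors:
        raise ValueError("invalid configuration: " + "; ".join(errors))
    return PipelineConfig(values=values)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, sep="\t", index=False)
    return path


def run_pipeline(config: PipelineConfig, stages: list[str] | None = None) -> RunManifest:
    """Execute stages in dependency order, writing outputs and a manifest."""
    from . import __version__

    stages = list(stages or config.stages)
    done: set[str] = set()
    order = []
    for s in stages:
        for dep in STAGE_DEPS.get(s, []):
            if dep not in stages and dep not in done:
                raise ValueError(f"stage {s!r} requires missing dependency {dep!r}")
    for s in STAGE_DEPS:  # canonical order
        if s in stages:
            order.append(s)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = hashlib.sha256(json.dumps(config.values, sort_keys=True, default=str).encode()).hexdigest()[:16]
    manifest = RunManifest(config_hash=cfg_hash, version=__version__)
    ctx: dict = {}
    for stage in order:
        t0 = time.time()
        outputs = _run_stage(stage, config, ctx, outdir)
        rec = {
            "stage": stage,
            "wall_seconds": round(time.time() - t0, 3),
            "outputs": {str(p.name): _sha256(p) for p in outputs},
        }
        logger.info("stage %s finished in %.2fs", stage, rec["wall_seconds"])
        manifest.stages.append(rec)
    (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest


def _run_stage(stage: str, cfg: PipelineConfig, ctx: dict, outdir: Path) -> list[Path]:
    seed = int(cfg.seed)
    if stage == "simulate":
        genome = simulate_genome(GenomeConfig(**cfg.genome), seed=seed)
        methylome, truth = simulate_methylomes(
            genome, TruthConfig(**cfg.truth), n_subclasses=int(cfg.n_subclasses), seed=seed + 1
        )
        cells = simulate_contact_cells(
            genome, truth, int(cfg.n_cells_per_subclass), int(cfg.contacts_per_cell), seed=seed + 2
        )
        counts = simulate_base_counts(genome, truth, seed=seed + 3)
        motifs = simulate_motif_db(genome, truth, seed=seed + 4)
        ctx.update(genome=genome, truth=truth, methylome=methylome, cells=cells, counts=counts, motifs=motifs)
        return [
            synth_io.write_genes_bed12(genome, outdir / "genes.bed12"),
            synth_io.write_dmrs_bed(truth, outdir / "dmrs_planted.bed"),
            synth_io.write_fraction_matrix(methylome.gene_mch, outdir / "gene_mch.tsv"),
            synth_io.write_truth_json(truth, outdir / "planted_truth.json"),
        ]
    if stage == "contacts":
        chrom = ctx["genome"].chromosomes[0][0]
        ctx["features"] = workflow.collect_contact_features(
            ctx["genome"], ctx["cells"], chrom, w=int(cfg.topdom_w)
        )
        out = outdir / "boundary_calls.tsv"
        pd.DataFrame(ctx["features"].calls25.astype(int), index=ctx["features"].cell_ids).to_csv(out, sep="\t")
        return [out]
    if stage == "compartments":
        track, corr = workflow.run_compartment_analysis(
            ctx["genome"], ctx["features"], ctx["methylome"], n_shuffles=int(cfg.n_shuffles), seed=seed
        )
        ctx["compartments"] = (track, corr)
        paths = [track.scores.to_csv(outdir / "compartment_scores.tsv", sep="\t") or outdir / "compartment_scores.tsv"]
        if corr is not None:
            paths.append(_write(corr, outdir / "compartment_mc_correlation.tsv"))
        return paths
    if stage == "boundaries":
        track, diff, corr = workflow.run_boundary_analysis(
            ctx["genome"], ctx["features"], ctx["methylome"], n_shuffles=int(cfg.n_shuffles), seed=seed,
            q_threshold=float(cfg.fdr_boundary),
        )
        ctx["boundaries"] = (track, diff, corr)
        paths = [_write(diff, outdir / "differential_boundaries.tsv")]
        if corr is not None:
            paths.append(_write(corr, outdir / "boundary_mc_correlation.tsv"))
        return paths
    if stage == "interactions":
        table, corr = workflow.run_interaction_analysis(
            ctx["genome"], ctx["features"], ctx["methylome"], f_min=float(cfg.f_min),
            q_max=float(cfg.fdr_interaction), n_shuffles=int(cfg.n_shuffles), seed=seed,
        )
        ctx["interactions"] = (table, corr)
        paths = [_write(table[table["highly_variable"]], outdir / "hvi.tsv")]
        if corr is not None:
            paths.append(_write(corr, outdir / "interaction_mc_correlation.tsv"))
        return paths
    if stage == "dmr":
        dms, regions = workflow.run_dmr_analysis(
            ctx["counts"], site_cap=int(cfg.site_cap), total_cap=int(cfg.total_cap),
            n_perm=int(cfg.n_perm), seed=seed, q_threshold=float(cfg.dms_q),
            max_gap=int(cfg.merge_gap), min_pcc=float(cfg.merge_pcc),
        )
        ctx["dmr"] = (dms, regions)
        return [_write(dms, outdir / "dms.tsv"), _write(regions, outdir / "dmr.tsv")]
    if stage == "grn":
        truth = ctx["truth"]
        dmr_intervals = pd.DataFrame(
            [{"dmr": d.id, "chrom": d.chrom, "start": d.start, "end": d.end} for d in truth.dmrs]
        )
        res = workflow.run_grn_analysis(
            ctx["genome"], ctx["methylome"], ctx["motifs"], ctx["interactions"][1],
            dmr_intervals, q_max=float(cfg.fdr_edge), nes_min=float(cfg.nes_min),
            n_shuffles=int(cfg.n_shuffles), seed=seed,
        )
        ctx["grn"] = res
        return [_write(res["triples"], outdir / "triples.tsv")]
    if stage == "pagerank":
        ranks = ctx["grn"]["pagerank"]
        paths = []
        if ranks is not None:
            for key, df in ranks.items():
                p = outdir / f"pagerank_{key}.tsv"
                df.to_csv(p, sep="\t")
                paths.append(p)
        return paths
    if stage == "report":
        report = write_report(ctx, outdir / "report.json")
        return [report]
    raise ValueError(f"unknown stage {stage!r}")


def write_report(ctx: dict, path: str | Path) -> Path:
    """Summary counts of discoveries per stage, as JSON."""
    summary: dict = {}
    if "boundaries" in ctx:
        _, diff, corr = ctx["boundaries"]
        summary["variable_boundary_bins"] = int(diff["variable"].sum())
        if corr is not None:
            summary["significant_boundary_correlations"] = int(corr["significant"].sum())
    if "interactions" in ctx:
        table, corr = ctx["interactions"]
        summary["highly_variable_interactions"] = int(table["highly_variable"].sum())
        if corr is not None and len(corr):
            summary["interaction_categories"] = (
                corr.loc[corr["significant"], "category"].value_counts().to_dict()
            )
    if "dmr" in ctx:
        dms, regions = ctx["dmr"]
        summary["dms_called"] = int((dms["q"] < 0.01).sum())
        summary["dmrs"] = int(len(regions))
    if "grn" in ctx:
        res = ctx["grn"]
        summary["edges"] = {
            "dmr_target": int(len(res["dmr_target"])),
            "tf_target": int(len(res["tf_target"])),
            "tf_dmr": int(len(res["tf_dmr"])),
        }
        if len(res["triples"]):
            summary["triples_by_model"] = res["triples"]["model"].value_counts().to_dict()
    path = Path(path)
    path.write_text(json.dumps(summary, indent=2))
    return path
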