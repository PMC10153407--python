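"""Differentially methylated site and region calling.

Strand-combined CpG counts are downsampled to 50x per site and 3,000x
across samples, tested with the permutation RMS statistic, and chained
into DMRs (gap <= 250 bp, adjacent-site PCC > 0.3).
"""

from mc3net import workflow
from mc3net.synthetic import GenomeConfig, TruthConfig, simulate_base_counts, simulate_genome, simulate_methylomes

genome = simulate_genome(GenomeConfig(chromosomes=(("chr1", 10_000_000),)), seed=1)
truth_cfg = TruthConfig(n_cpg_sites=4000, dms_fraction=0.25, dms_delta=0.6)
_, truth = simulate_methylomes(genome, truth_cfg, n_subclasses=4, seed=2)
counts = simulate_base_counts(genome, truth, mean_cov=60, seed=3)

dms, regions = workflow.run_dmr_analysis(counts, n_perm=500, seed=4)
called = dms[dms["q"] < 0.01]
merged = dms.merge(truth.dms_sites[["chrom", "pos", "is_dms"]], on=["chrom", "pos"])
sens = (merged.loc[merged["is_dms"], "q"] < 0.01).mean()
fpr = (merged.loc[~merged["is_dms"], "q"] < 0.01).mean()
print(f"sites tested: {len(dms)}; called DMS at q < 0.01: {len(called)}")
print(f"sensitivity on planted sites: {sens:.3f}; false call rate on null sites: {fpr:.4f}")
print(f"DMRs after chaining: {len(regions)} "
      f"(median width {int((regions['end'] - regions['start']).median())} bp)")
# Planted sites differ by 0.6 in methylation fraction across samples;
# at 50x coverage the permutation test recovers essentially all of them
# while null sites stay at the nominal error level.
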