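# mc3net

Multi-scale analysis of single-cell chromatin conformation together with
DNA methylation, ending in a TF–DMR–target gene regulatory network.

Brain-wide single-cell methylome + chromatin-conformation assays measure,
in the same nuclei, cytosine methylation (gene-body mCH as an inverse
proxy of gene activity, mCG as a proxy of regulatory-element state) and
cis contact maps. `mc3net` implements the analysis stack such data
requires, as a reusable, tested library:

* **Contact imputation** — per-cell matrices at 100 kb / 25 kb / 10 kb
  from cis-long pairs (> 2,500 bp), smoothed by a pad-1 mean filter and a
  random walk with restart, `S = p_r I + (1 − p_r) S P` with `p_r = 0.5`,
  band-limited (whole chromosome / 10.05 Mb / 5.05 Mb).
* **A/B compartments** — distance-normalized correlation matrices, one
  shared incremental PCA across all subclasses, scores oriented so
  high-CpG (A) bins are positive; score–mCG correlation per bin.
* **Domain boundaries** — TopDom-style per-cell calls (w×w diamond
  `binSignal`, rank-sum filtered), boundary-probability tracks, per-bin
  chi-square differential test (FDR < 1e-3), transcript-body ± 2 Mb
  boundary–mC correlation.
* **Highly variable interactions** — one-way ANOVA across subclasses on
  imputed single-cell 10-kb pixels (50 kb–5 Mb), HVIs at F > 3 and
  FDR < 0.001, gene–interaction correlation with the six-way
  I / U / D / U-I / D-I / U-D categorization.
* **DMS/DMR calling** — strand-combined CpG counts downsampled to 50× per
  site and 3,000× across samples, permutation root-mean-square test,
  greedy merging (≤ 250 bp, adjacent PCC > 0.3), non-overlapping union
  with representative selection.
* **Regulatory network** — DMR–Target, TF–Target and TF–DMR correlation
  edges (pooled within-subclass shuffle null, normal-approximated p,
  BH FDR < 0.001), recovery-curve motif enrichment (NES > 3, leading-edge
  occurrence), triples scored `S_all = (|Sa||Sb||Sc||Sd|)^(1/4)` and
  classified into four sign models, and per-subclass personalized
  PageRank with inverted-methylation node weights
  `W_i = (max CH − CH_i)/(max CH − min CH)` and edge weights
  `(1/n) Σ_t S_t V_{i,t}`.
* **Synthetic atlas** — a first-class generator
  (`mc3net.synthetic`) that plants recoverable compartments, boundaries,
  loops, DMS/DMRs and regulatory triples with a complete truth record, so
  the whole stack is testable end-to-end without any download.

All shared statistics (quantile normalization, Pearson screens,
within-column shuffle nulls, Benjamini–Hochberg) live in
`mc3net.core_stats` and are used identically by every stage.

## Worked example

`examples/` contains one short script per capability. The network
example assembles the full GRN on the standard network conditions
(8 Mb gene-dense genome, 30 subclasses × 16 cells):

```bash
python examples/07_grn_pagerank.py
```

```
edges: DMR-target 24, TF-target 22, TF-DMR 22
triples: 24; model frequencies: {'Model 1': 14, 'Model 4': 4, 'Model 2': 4, 'Model 3': 2}
mean final score S_all: 0.913
planted triples recovered with the intended model: 22/22
planted master TF gene0191: PageRank rank 1 among 8 TFs in its hub subclass
planted master TF gene0206: PageRank rank 1 among 8 TFs in its hub subclass
```

All 22 planted triples are recovered with their intended regulatory model
(the sign pattern of the Sa/Sb/Sc correlations), two triples arise from
correlated-module cross-talk, and the planted hub TFs top the PageRank
ranking in exactly their hub subclass. A pipeline wrapper
(`mc3net run --outdir out --seed 1`, or `mc3net.pipeline.run_pipeline`
from Python) chains simulation and all analysis stages with a checksum
manifest.

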