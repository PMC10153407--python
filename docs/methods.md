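# Methods

`mc3net` reconstructs, at desk scale, a multi-scale analysis of single-cell
chromatin conformation (snm3C-style cis contact maps) together with
pseudo-bulk DNA methylomes, ending in a TF–DMR–target regulatory network.
This note describes the models and procedures, the synthetic data the
package is exercised on, the numerical choices, and what the results do and
do not demonstrate.

## Coordinate and data conventions

All coordinates are 0-based half-open (BED convention); the bin holding
position `p` at resolution `r` is `p // r`. Methylation fractions are
methylated base calls over covered base calls: gene-body mCH is the
(inverse) proxy for gene activity, mCG the proxy for regulatory-element
state. Pseudo-bulk matrices are features × subclasses.

## Contact matrices and imputation

Per cell and chromosome, cis contact pairs with anchor separation
> 2,500 bp accumulate into symmetric matrices at 100 kb, 25 kb and 10 kb.
Single-cell matrices are extremely sparse, so each is imputed by

1. a (2·pad+1)² mean filter with zero padding (pad = 1), the practical form
   of the "Gaussian convolution" used by single-cell Hi-C imputation
   pipelines (a true Gaussian kernel is available behind `sigma=`);
2. a random walk with restart on the row-normalized filtered matrix:
   `S = p_r·I + (1 − p_r)·S·P` with restart probability `p_r = 0.5`.
   Because rows of `S` are independent, the fixed point is
   `S = p_r (I − (1 − p_r) P)⁻¹`; the default `method="direct"` solves this
   linear system exactly, while `method="iterative"` iterates to a
   max-abs-change tolerance (1e-6 by default). The two agree to the
   tolerance (checked explicitly in the test suite); the direct solve is
   simply much faster on a single CPU at 2,000-bin chromosomes.
3. symmetrization `(S + Sᵀ)/2` and band masking: the whole chromosome at
   100 kb, 10.05 Mb at 25 kb, 5.05 Mb at 10 kb.

Rows with no contacts keep the walker at its start bin. Group (subclass)
matrices are the element-wise mean of member cells' imputed matrices, so
groups of different sizes are comparable.

## Compartments (100 kb)

Bins overlapping a blacklist or with outlying coverage are removed: with
`R` the row sums of the group matrix, kept bins satisfy
`2·median(R) − Q99(R) ≤ R_i ≤ Q99(R)`. Note the lower bound only bites for
strongly right-skewed coverage; a single low-coverage outlier is kept if it
clears the bound — this is the rule as stated, not a symmetric trim.

Each subclass's kept-bin matrix is distance-normalized
(observed/expected per diagonal) and converted to a bin–bin Pearson
correlation matrix. The rows of all subclasses' correlation matrices are
pooled as observations for one two-component PCA (sklearn
`IncrementalPCA`, one subclass batch at a time), so every subclass is
scored with the same loadings and cross-subclass correlation of scores is
meaningful. The component with the larger pooled |correlation| with CpG
density is the compartment score, signed so high-CpG (A) bins are
positive. Incremental and exact PCA agree to cosine > 0.999 on the sizes
used here (verified in tests).

Per-bin score–mCG/mCH correlation across subclasses runs on quantile
normalized matrices with the pooled shuffle null described below; the
per-bin cross-subclass score standard deviation is reported alongside,
since subclass-variable (switching) bins both anti-correlate with mCG and
have elevated score dispersion.

## Domain boundaries (25 kb)

A TopDom-style detector runs per cell: `binSignal(i)` is the mean of the
w×w diamond between bins `i−w+1..i` and `i+1..i+w` (w = 5 bins = 125 kb by
default; the window is evaluated only where it fits entirely, because
clipped windows at chromosome ends create artifactual minima). Local
minima of the signal within ±w are kept when a one-sided rank-sum test
finds the diamond significantly weaker (α = 0.05, the detector's customary
default) than the flanking within-domain contacts. Blacklisted bins are
suppressed.

Boundary probability per subclass is the fraction of member cells calling
the bin. Differential boundaries use the per-bin chi-square statistic on
the subclasses × {boundary, not} table (no continuity correction; expected
counts < 5 raise a warning, not a method switch), BH-corrected, flagged at
FDR < 1e-3. Transcript–boundary correlation pairs each transcript (same-
gene transcripts with > 90% mutual overlap collapsed to their spanned
range) with the differential bins inside the body ± 2 Mb.

## Highly variable interactions (10 kb)

Every pixel with anchor distance between 50 kb and 5 Mb (inclusive) is
tested by one-way ANOVA across subclasses on the imputed single-cell
strengths (imputed, because raw single-cell 10-kb pixels are nearly always
0/1). HVIs require F > 3 (strict) and BH FDR < 0.001 (strict). HVIs with
an anchor overlapping a transcript body are correlated with its mCH at
group level and categorized strand-aware by anchor position into
I, U, D, U-I, D-I, U-D (an anchor touching the body is always I).

## Correlation screens and their null

All correlation screens share one recipe (`core_stats`): quantile
normalize both matrices along subclasses (ties receive the mean of their
span of target values, making the operation deterministic and
idempotent); Pearson correlation per feature pair; a pooled null built by
independently permuting feature rows *within every subclass column* of
both matrices, which destroys the genomic pairing but preserves
subclass-level global differences; a single normal fitted to the pooled
shuffled correlations for smooth small-p estimation (1,000 shuffles by
default — the normal approximation is what stabilizes small p at reduced
shuffle counts, and it matches 10⁵-shuffle empirical p-values at Spearman
ρ ≈ 1 in the tests); BH FDR per analysis family. The null is pooled
across all pairs of a family rather than stratified; stratification is
not implemented because the pooled normal matched the empirical null on
every family examined.

Two practical consequences of this construction shaped the study design:

* the null standard deviation of a PCC over `n` subclasses is ≈ 1/√(n−1),
  so FDR < 0.001 in families of thousands of pairs is only reachable with
  a few dozen subclasses — five subclasses can never clear it no matter
  how strong the signal;
* quantile normalization is rank-based, so it only preserves
  cross-subclass correlation structure when the matrix has enough
  overlapping features for ranks to move smoothly (a few hundred gene
  features suffice; a few dozen do not), and it removes genuinely global
  shifts (all features moving together) by construction.

## DMS / DMR calling

CpG strand pairs (+ at `pos`, − at `pos+1`) are combined, then coverage is
downsampled: per site and sample to 50 base calls (hypergeometric, which
preserves the expected fraction), then per site across samples to a total
of 3,000 (proportional rounding, redrawn). The DMS statistic is
`S = sqrt(meanₛ (p̂ₛ − p̄)²)` over covered samples with `p̄` the pooled
fraction. The null permutes individual base calls across samples
preserving each sample's coverage — a sequential hypergeometric allocation
of the pooled methylated calls; sites sharing a coverage vector and pooled
total share a null distribution, so permutations (1,000 by default) are
drawn per signature. p-values use the add-one correction; significance
defaults to q < 0.01 before merging. Significant sites chain greedily into
DMRs when within 250 bp and adjacent fraction vectors have PCC > 0.3
(adjacent-pair gating keeps the chaining O(n) and deterministic);
overlapping DMR sets from multiple rounds merge at distance 0 with
bookended intervals merging, and representatives are the max-|statistic|
candidate (ties: leftmost, then shortest).

## The regulatory network

Edges at FDR < 0.001 each:

* **DMR–Target (Sa)** — candidate DMRs lie in anchors of the gene's
  significant, positively correlated HVIs ("positive" follows the stated
  selection; `sign_filter` also accepts "negative"/"both" since distal
  element–gene contacts can plausibly carry either sign). Overlapping
  DMRs collapse to the max-|Sa| representative. The supporting
  interaction's gene–contact correlation is attached as Sd, choosing the
  lowest (most negative) value when several interactions qualify.
* **TF–Target (Sc)** — TF gene-body mCH against all variable genes
  (cross-subclass variance filter standing in for an expression-derived
  variable-gene list, which requires clustering outside this package's
  scope); TF rows are normalized *within* the full gene matrix, never as a
  tiny separate matrix, so their quantile-normalized profiles stay
  comparable.
* **TF–DMR (Sb)** — significant DMRs split by sign(Sb); recovery-curve
  motif enrichment runs per sign set: DMRs ranked by motif score, AUC =
  mean recovery of the query over the top `rank_fraction` (5%) of the
  collection but never fewer than 25 regions (tiny windows degenerate on
  miniature catalogs), NES = standardized AUC across the motif
  collection; edges survive only for DMRs in the leading edge (ranks up
  to the maximum of recovery minus uniform expectation) of a motif
  annotated to the TF with NES strictly > 3 and a score above the
  occurrence threshold.

Triples are the intersection of the three edge lists on (TF, DMR, gene),
scored `S_all = (|Sa|·|Sb|·|Sc|·|Sd|)^(1/4)` and classified by the sign
pattern of (Sa, Sb, Sc): (+,+,+) Model 1, (+,−,−) Model 2, (−,−,+)
Model 3, (−,+,−) Model 4 — exactly the four sign-consistent patterns
(product +1) — and "Unknown" otherwise (including any zero or undefined
correlation).

**PageRank.** The network keeps TF and target nodes. Gene mCH and DMR
mCG are quantile normalized, robust-scaled per feature with quantile
range (10, 90), and inverted per feature across subclasses:
`W_i = (max − x_i)/(max − min)` (genes) and `V_i` likewise (DMRs). The
edge weight between a TF and target in subclass i is
`(1/n) Σ_t S_all,t · V_{i,t}` over the n connecting triples. The
personalization vector is `W_i`. Edges point target → TF by default, so
importance propagates from regulated genes to their regulators and hub
TFs of active modules rank highly; `edge_direction="tf_to_target"` is
available, but with a depth-one TF→target graph the TF ranking would
collapse to the teleport weights alone, which defeats the purpose of
propagating network structure. Damping is 0.85, solved to 1e-9; raw
scores are per-subclass probability distributions and the normalized
score is a per-TF min–max across subclasses.

## The synthetic atlas

The generator emulates the *inputs* of all of the above with planted,
recorded ground truth; analysis code never reads the truth record.

* **Genome** — 1–2 chromosomes (default one 20 Mb chromosome), alternating
  1 Mb A/B blocks with CpG density elevated in A; genes placed
  sequentially with gaps, overlapping placement once the layout is full
  (as transcripts do in gene-dense regions); > 100 kb genes are "long";
  a subset of short genes are TFs with one annotated motif each.
* **Methylomes** — every feature carries a latent per-subclass pattern;
  observed fractions are Binomial(coverage, latent)/coverage with
  Poisson coverages (defaults: 20,000 calls for gene mCH, 1,500 for DMR
  mCG, 3,000/30,000 for 100-kb bin mCG/mCH — pseudo-bulk scale). Gene
  mCH sits at 3% ± 1% (the neuronal gene-body range); DMR mCG at
  0.6 ± 0.18.
* **Contacts** — per-cell pixel distribution at 10 kb: power-law distance
  decay (exponent −1), same-block factor (1 ± 0.6 compartment contrast),
  attenuation 0.4 per crossed planted boundary (capped at two crossings),
  and loop "dots" spanning 3×3 pixels (~30 kb, as loops appear at 10-kb
  resolution) with per-subclass enrichment 8 at the planted loops. Cells
  draw a fixed 100,000 cis pairs from this distribution (multinomial);
  on a miniature genome this keeps per-pixel counts at the magnitude a
  ~400k-contact cell provides per equivalent genome fraction. Planted
  boundaries avoid compartment block edges, where the block transition
  would mask or mimic the insulation minimum.
* **Couplings** — planted loops are enrichment-coupled to gene activity
  patterns through rank scaling (robust to outlying subclasses): triple
  loops positively with gene mCH (insulation-style, matching the positive
  interaction filter upstream of DMR–Target edges), plus a set of
  negatively coupled (activity-style) loops and pure subclass-subset
  loops. Boundary couplings tie a differential boundary at a long gene's
  TSS to that gene's mCH (present ⇒ active ⇒ low mCH). Triples plant the
  intended sign model exactly: target pattern t, TF pattern sign(Sc)·t,
  DMR pattern sign(Sa)·t (+ module noise), which realizes precisely the
  four product-+1 models. Master TFs ride a deep dip in one subclass on a
  shared smooth background, so the module correlates across all
  subclasses, not only via the dip.
* **Base counts** — CpGs emitted as strand pairs; planted DMS carry a
  0.6 between-sample fraction difference in half the samples; null sites
  share one level. 25% of sites are differential by default (real brains
  put ~40% of CpGs inside DMRs, so this is conservative).
* **Motifs** — exchangeable exponential background scores; each planted
  triple's TF motif is elevated above the occurrence threshold in that
  triple's DMR; 100 decoy motifs by default.

**Study conditions.** Two presets fix the standard experiments
(`mc3net.synthetic.presets`): the *atlas* conditions (20 Mb, 5 subclasses
× 40 cells) for compartment/boundary/HVI recovery, whose statistics are
powered by cell counts; and the *network* conditions (8 Mb gene-dense
genome with 220 genes, 30 subclasses × 16 cells, quiet contact
background) for the cross-subclass correlation screens, which need tens
of subclasses for FDR < 0.001 to be reachable and a few hundred gene
features for quantile normalization to preserve correlations (see the
two consequences above). A third preset plants nothing, for calibration.
Problem sizes throughout (chromosome lengths, cell counts, shuffle and
permutation counts) were chosen so the full suite and the acceptance
script each run in minutes on a single CPU.

**What the generator does not emulate:** genome sequence and real motif
scanning, read-level noise and mapping artifacts, trans contacts,
cell-to-cell coverage imbalance, batch or dissection structure, doublets,
clustering uncertainty (subclass labels are taken as given), and the
correlated mosaic of real methylomes beyond the planted modules. Passing
recovery tests therefore demonstrates that the estimators and thresholds
behave as specified under controlled signal and calibrated noise — not
that they would achieve the same sensitivities on real tissue.

## Known limitations

* The RMS DMS statistic is the unweighted root mean square of per-sample
  deviations from the pooled mean; published frameworks weight samples
  differently, so absolute S values are not interchangeable across tools.
* The pooled correlation null is not distance-stratified; strongly
  distance-structured families could in principle deviate from it.
* `dmr_target_edges` matches anchors to DMRs by interval overlap per
  gene; with very large HVI families this screen is the slowest step.
* Boundary calls within w bins of a chromosome end are not attempted.
* The six-way interaction category sign fractions printed by full-scale
  studies are population statistics of real genomes and are out of reach
  of the miniature atlas; the package reports its own category counts
  instead.
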