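# Methods

`modref` benchmarks strategies for integrating single-nucleus RNA-seq
(snRNA-seq) cell types into single-cell RNA-seq (scRNA-seq) references
for bulk deconvolution. snRNA-seq measures nuclear transcripts only, so
a nucleus-derived expression profile is a biased stand-in for the
whole-cell profile that bulk RNA-seq mixtures are composed of. The
package implements the full experimental loop — simulate paired data,
build pseudobulks with known composition, detect cross-modality
differentially expressed genes (DEGs), harmonize nucleus profiles,
deconvolve, and score — so each integration strategy can be ranked
under controlled conditions.

## Study design

For each run, one scRNA-seq sample provides the pseudobulk cells and an
independent sample of the same tissue (same expression programs,
disjoint donors) provides the scRNA/snRNA reference pair. One cell type
at a time is *held out* of the scRNA reference and re-supplied from
snRNA-seq, raw or transformed; any model used by a transform is trained
without ever seeing that type. Reference variants (the benchmark's
arms):

| key | cells | genes removed | transform |
|---|---|---|---|
| `pos_ctrl` | all scRNA | none | none |
| `neg_ctrl` | all snRNA | none | none |
| `sn_all_deg_int` | all snRNA | cross-dataset DEG intersection | none |
| `sn_raw` | scRNA + held-out from snRNA | none | none |
| `sn_deg` | same | per-dataset DEG union (held-out type's own list excluded) | none |
| `pca` / `pca_deg` | same | none / DEG union | PCA neighbour shift |
| `scvi_ls` / `scvi_ls_deg` | same | none / DEG union | VAE latent shift |
| `scvi_cond` / `scvi_cond_deg` | same | none / DEG union | conditional VAE label switch |
| `deg_int` | same | DEG intersection minus held-out type's list | none |
| `deg_other` | same | union of the *other* datasets' DEG unions | none |
| `random_genes` | same | random set matched in size to the DEG union | none |

Per-type cell counts are equalized across variants (the smaller of the
two modality pools per type), so performance differences reflect the
strategy, not reference size.

## Synthetic data generator

Counts are negative binomial (NB), mean/dispersion parameterization
(var = μ + μ²/θ, single θ, default 10). The per-cell mean for gene *g*
is

    μ = s_i · d_{donor(i),g} · c_t · b_g · exp(Λ_g·a_i − σ_w²‖Λ_g‖²/2)
        · m_g,t^{1[nucleus]}

* **Expression manifold.** Cell identity lives on shared programs: one
  identity axis per type plus 6 shared modules. Gene loadings Λ_g are
  N(0, 0.4²); each type's activity b_t is the unit vector on its own
  axis plus N(0,1) activities on the shared modules; each cell draws
  a_i ~ N(b_t, σ_w² I) with σ_w = 0.3. This matters for the held-out
  protocol: a basis fitted without one type can still span that type's
  identity direction, because it appears as within-type covariation in
  the remaining types — as in real tissues. Markers (200 per type,
  disjoint, round-robin) are genes loaded at log 2^3 on their type's
  identity axis, so the marker mean boost is 8-fold.
* **Transcript budgets.** Per-type totals are equalized, so cell-count
  proportions and read-mass proportions coincide and deconvolution
  accuracy is not confounded by RNA-content differences between types.
* **Abundances.** Default types have 350/280/220/150 cells per
  modality — skewed, as real tissues are. Equal abundances would make
  the empirical-proportion pseudobulk scheme degenerate (a constant
  truth vector has no Pearson correlation).
* **Modality effect.** A fraction (default 10%) of genes carries a
  nucleus multiplier 2^(±u), u ~ U(1, 2), sign symmetric. Effect genes
  are sampled with probability proportional to baseline expression:
  nuclear enrichment (lncRNA, nascent transcripts) and cytoplasmic
  depletion (ribosomal, mitochondrial mRNA) both concentrate in
  abundant transcripts. Around the shared per-gene multiplier each type
  receives a log2-N(0, 0.5²) interaction, since per-type modality DEG
  profiles differ in real data. The truth object records the shared
  per-gene multiplier (what DEG detection should find) and the full
  per-type matrix (what the data were generated with).
* **Donors and libraries.** Per-donor log-normal gene multipliers
  (sd 0.1, 3 donors) and per-cell log-normal library factors (sd 0.3).
* Not modelled: doublets, ambient RNA, UMI saturation, tissue-specific
  DEG counts. Passing tests therefore show the pipeline's logic and the
  strategies' relative behaviour under NB noise with realistic mean
  structure — not absolute performance on any real tissue.

## Pseudobulks

1000 cells per mixture; 500 mixtures from a flat Dirichlet (α = 1) and
500 from the source's empirical proportions plus N(0, 0.01) noise,
renormalized. Proportion vectors become integer counts by floor plus
largest-remainder top-up (sums are exact); draws assigning any type
zero cells are repeated (up to 1000 attempts). Cells are sampled
without replacement when possible, summed, N(0, 0.05) noise added
entrywise on the summed-count scale (configurable — on raw counts this
is nearly negligible, which we read as intended: the clipping rule
exists for the noise's sake), negatives clipped. Sampled cell indices
are persisted so a zero-noise build can be reproduced bit-exactly.

## Cross-modality DEG detection

Cells of each (type, modality) stratum are shuffled and summed into
10-cell pseudo-replicates (remainders dropped; strata with fewer than 3
aggregates flagged). The default engine is an NB Wald test:
median-of-ratios size factors (library-ratio fallback when no gene is
expressed everywhere), gene-wise moment dispersion pooled within groups
with a 1e-8 floor, per-group NB mean MLE by Newton iteration with the
exact per-group Fisher information, Wald statistic on log(m_nuc/m_cell).
BH adjustment is applied within each (dataset, cell type) test; DEGs
are genes at padj < 0.01, union-ed per dataset after thresholding.
The engine is pluggable; a DESeq2-compatible implementation can be
substituted and is used as a logged, non-blocking cross-check in the
test suite (engines differ in dispersion shrinkage).

Under the synthetic null (20 aggregates/side, 2000 genes) the measured
mean fraction of padj < 0.01 calls is far below 0.02; 4-fold spiked
genes are detected with power above 0.8.

## PCA neighbour shift

The training pool (scRNA cells + overlapping-type snRNA cells, held-out
type excluded from both) is log1p-transformed and standardized per gene
(zero-variance genes get sd 1 to avoid division blow-ups). PCA retains
the minimum number of components capturing ≥ 75% of variance. Each
overlapping nucleus cell stores a shift vector to its **own type's**
scRNA centroid — the local modality correction, in the lineage of
mutual-nearest-neighbour batch correction. (A global-centroid variant
is available as `centroid_mode="global"`; it mixes type identity into
the shifts — each stored vector then also points away from the cell's
own type toward the average of the training types — and we measured
catastrophic missing-type imputation with it, so per-type is the
default.) A missing-type cell is projected, its k = 10 nearest
overlapping nucleus neighbours found (Euclidean, stable index
tie-break), the mean of their stored shifts added, and the result
inverse-projected, un-standardized, expm1-ed, clipped at zero and
rescaled so each cell totals L — the median library size of the scRNA
training cells (the mean is available via `library_stat="mean"`).
The alternative "displacement" shift semantics (mean query→neighbour
displacement) is implemented for sensitivity checks but moves cells
into the neighbour cluster and erases identity.

Known limitation: reconstruction through a truncated basis in log space
followed by expm1 flattens expression profiles (high-expression genes
lose relative mass after the final rescale). This is inherent to the
stated pipeline and is why the PCA arms trail the gene-pruning arms.

## NB variational autoencoder

Implemented directly in numpy (forward pass, analytic gradients, Adam):
encoder and decoder with two 128-unit ReLU layers, 30 latent
dimensions, softmax decoder over genes scaled by the observed library,
NB likelihood with a per-gene-per-modality ("gene-batch") dispersion
parameter. The conditional variant one-hot encodes the modality at the
encoder input and again at the latent space. Training: Adam at 1e-3,
minibatch 64 (small batches keep the step count useful on
reference-sized pools and short schedules), 90/10 train/validation
split, early stopping with patience 10, best-validation weights
restored; gradients are verified against finite differences in the test
suite. All randomness flows through one seeded generator, so training
is exactly reproducible.

Two transforms: the **latent shift** (non-conditional model) repeats
the PCA shift in latent space using encoder posterior means (sampling
off, for determinism); the **label switch** (conditional model) encodes
missing nucleus cells with the nucleus label and decodes with the cell
label. Both rescale decoded means to L per cell.

## Deconvolution

The built-in solver CPM-normalizes each reference cell, averages per
type into a signature S (types × genes), CPM-normalizes each bulk
sample b, solves w = argmin_{w≥0} ‖Sᵀw − b‖₂ (scipy NNLS) and returns
w/Σw. An all-zero solution falls back to uniform proportions with a
warning so evaluation tables stay rectangular. NNLS is deterministic
and adequate for *ranking* reference variants; it does not reproduce a
Bayesian tool's absolute accuracy. An external tool can be plugged in
through a file-exchange adapter (reference genes × cells CSV + type
map, bulks genes × samples CSV, config with iteration count, default
5000; proportions back as samples × types CSV).

## Evaluation and composite scores

Per-sample Pearson and RMSE between true and estimated proportions in
three scenarios: all types; non-removed (held-out entry dropped from
both vectors); removed-only — the held-out type's proportions pooled
across samples into a single record per dataset × transform × held-out
type, since per-sample correlation on a scalar is undefined. Constant
vectors yield a missing Pearson with a log entry. Uncertainty: 95%
percentile bootstrap of the mean (1000 resamples). Control comparisons
use the pooled-variance two-sample t-test (two-tailed, pairwise
missing-value deletion); the default significance level is a
deliberately conservative 0.005 and is configurable.

Robustness without ground truth: cosine similarity between flattened
predicted-proportion matrices, between transforms (same donors) and
between donors (same transform). Composite scores: within each dataset,
per-sample Pearson and inverted RMSE (dataset max minus value) are
min-max scaled, averaged per transform, then across datasets; accuracy
is the mean of the two. Robustness min-max scales the pooled donor-pair
and off-diagonal transform-pair cosines, averages each per transform
and takes the mean. Degenerate (constant) min-max populations map to 0
with a warning. Missing records are excluded listwise from composite
averaging, with a warning.

## Numerical and design choices

* Gene order after alignment is lexicographic; every stochastic
  operation draws from a generator derived from (master seed, stage,
  entity) via SHA-256, so stages reproduce independently of execution
  order.
* NNLS ties and k-NN distance ties break by stable index order.
* The cosine profile comparison (50-cell aggregates, CPM, log1p) seeds
  one generator per side, so comparing a dataset with itself returns
  exactly 1; types with fewer than 50 cells are sampled with
  replacement and logged.
* The profile-recovery property of the decoder-based transforms is
  tested under a pronounced modality-effect regime (30% of genes,
  |log2FC| 2–4 — the scale real tissues show). Under mild effects the
  cosine metric on log1p-CPM profiles is nearly saturated (raw nucleus
  profiles already exceed 0.997) and any decode path loses more than it
  corrects; deconvolution accuracy, not profile cosine, is the
  discriminating metric there.
* Benchmark problem sizes (2000 genes, 4 types, 1000 cells per modality,
  100 pseudobulks per run, 5 seeds; VAE arms at 500 cells per modality
  and 30 epochs) were chosen so a full run completes on a laptop-class
  single core in minutes.

## Limitations

The generator's modality effect is a per-gene multiplier with a mild
per-type interaction; real nuclear/cytoplasmic partitioning also
correlates with transcript length, intron content and stability, none
of which are modelled. The NNLS solver understates what a Bayesian
deconvolution method achieves in absolute terms, so only relative
statements across reference variants carry over. DEG-based pruning
results depend on which cell types the two modalities share; with
fewer than about four shared types, or fewer than ~50 cells per type,
the per-dataset DEG unions become unstable — consistent with the
guidance this framework was built to test.
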