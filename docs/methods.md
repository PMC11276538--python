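# Methods

## Problem and model

`crossmp` translates between the two modalities of a paired single-cell
multiome: given a cell's chromatin accessibility profile (binary cell-by-peak
matrix) it predicts the cell's gene expression profile, and vice versa. The
network has four encoders and two decoders.

**Expression-side encoders.** The normalised expression matrix `X_RNA` and its
significant-gene column subset `X_SG` each pass through two fully connected
layers, each followed by batch normalisation and ReLU, ending in a
16-dimensional latent vector per cell.

**Accessibility-side encoders.** The binary peak matrix `X_ATAC` and the gene
activity score matrix `X_GAS` are split into per-chromosome column blocks.
Each block has its own two-layer fully connected sub-network (PReLU
activations) ending at 16 dimensions; the per-chromosome latents are
concatenated (22 blocks × 16 = 352 dimensions for a human autosome-only peak
set) and projected back to 16 dimensions with a PReLU. The per-chromosome
partition restricts first-layer interactions to intrachromosomal structure.
The GAS matrix is gene-indexed, so its blocks group genes (not peaks) by
chromosome; a dense two-layer alternative is available via
`gas_encoder_mode="dense"`.

**Merge.** Same-side latents are merged by element-wise addition
(`Z_ATAC + Z_GAS`, `Z_RNA + Z_SG`), keeping the 16-dimensional width the
decoders expect. A concatenate-and-project variant is available via
`merge_mode="concat_project"`.

**Decoders.** The RNA decoder expands the merged latent to 64 dimensions
(ReLU) and emits two heads of input dimensionality: an exponential head for
the negative-binomial mean and a softplus head for the dispersion. The ATAC
decoder expands the latent to 352 dimensions (PReLU), splits it into the 22
per-chromosome blocks of 16, and restores each chromosome's peak count with a
per-block linear layer and sigmoid.

**Loss.** One forward pass produces all four translation paths
(ATAC→ATAC, ATAC→RNA, RNA→ATAC, RNA→RNA). Training minimises

    L = L_NB(ATAC→RNA, X_RNA) + L_NB(RNA→RNA, X_RNA)
      + w_BCE · [ L_BCE(ATAC→ATAC, X_ATAC) + L_BCE(RNA→ATAC, X_ATAC) ]
      + w_KL  · KL( softmax(Z_ATAC+GAS) ‖ softmax(Z_RNA+SG) )

with `w_BCE = 1.33`, `w_KL = 1.0`. The NB negative log-likelihood uses the
(mean μ, dispersion θ) parameterisation,
`lgamma(θ) + lgamma(x+1) − lgamma(x+θ) − θ·log(θ/(θ+μ)) − x·log(μ/(θ+μ))`,
against the raw counts. The embeddings are deterministic (this is not a
VAE), so the KL term reads each latent row as a point on the simplex through
a row-wise softmax; `kl_symmetric=True` averages both divergence directions.

## Preprocessing

**ATAC** (in fixed order): peaks on excluded chromosomes are dropped
(default chrX/chrY/X/Y only; mitochondrial or scaffold contigs are removed
only when listed explicitly); overlapping peaks (connected components of the
half-open interval-overlap graph, per chromosome) are merged to their union,
aggregating member columns by elementwise maximum so that merging and
binarisation commute; the matrix is binarised (any nonzero → 1); peaks
supported by fewer than 5 cells or by more than 10% of cells are removed.
Boundary semantics are strict readings of "fewer than"/"more than": support
exactly 5 and support exactly 0.10·n are kept. A per-peak audit table
(support, kept, reason) makes the filter reproducible.

**RNA**: genes on excluded chromosomes are dropped when a gene-model table is
available; cells expressing fewer than 200 or more than 7000 genes are
removed (boundaries kept, same strict reading); counts are scaled per cell to
the median library size, log(1+x)-transformed, z-scored per gene (the
conventional axis; zero-variance genes map to 0 and are flagged), and finally
all entries are clipped to the global 0.5%/99.5% quantiles of the
standardised distribution. Clipping after the z-score treats it as the
outlier guard on standardised values; `clip_stage="post_log"` applies it to
the log values instead. The fitted statistics (median total, per-gene
mean/sd, clip bounds) replay the identical transform on new cells.

**Significant genes.** The auxiliary `X_SG` channel is the normalised matrix
restricted to the top-k genes of a ranking. An externally supplied ranking
(e.g. from an RNA-velocity analysis) is used verbatim; without one, genes are
ranked by the variance of their normalised expression (ties broken by gene
id). Velocity scoring itself needs raw reads and is out of scope. Default
k = min(2000, number of genes).

**Gene activity scores.** The regulatory-potential model: each accessible
peak within ±`window_factor·d0` of a gene's TSS contributes
`2^(−d/d0)` with `d0 = 10 kb` (so a peak at the TSS contributes 1, at 10 kb
contributes 0.5) and `d` measured from the peak midpoint
(`distance_reference="nearest_edge"` available). Peaks overlapping any exon
are treated as sitting at the TSS: their summed presence is divided by the
gene's total exon length, and they are excluded from the decay term so
nothing is counted twice. The scan window is 10·d0 (±100 kb); beyond it the
contribution is exactly 0. Promoter-specific weight caps used by some
regulatory-potential implementations are deliberately not modelled — only
the decay-plus-exon rule above.

## Training

Adam (lr 0.01), shuffled mini-batches of 512 (the last incomplete batch is
kept), at most 500 epochs, 70/15/15 train/validation/test split
(floor/floor/remainder). Early stopping monitors the total validation loss
(min-delta 0, patience in epochs, default 25) and restores the
best-validation weights. Batch normalisation uses batch statistics during
training and running statistics at inference. Numerical guards: probabilities
clamped to [1e-8, 1−1e-8] inside the BCE, dispersion floored at 1e-8, the
exponential mean head's pre-activation capped at ±30, and gradients clipped
to a global L2 norm of 10 — without the last, the 0.01 learning rate can
overflow the exponential head in the first batches. All arithmetic is
float64 single-threaded numpy (the network and its reverse-mode autodiff
live in `crossmp.autodiff`), so fixed-seed runs are bit-reproducible.

## Evaluation

RNA predictions are reported as the NB mean and compared against the
normalised expression truth after a log1p transform (correlations are
otherwise dominated by the mean's heavy right tail); both an overall Pearson
and Spearman on the flattened matrices and per-gene correlations across cells
are reported. ATAC predictions are probabilities scored by AUROC, overall and
per peak. Features whose truth is constant across the evaluated cells (and
RNA features with constant predictions, where a correlation is undefined) are
excluded and counted rather than propagated as NaN. A shuffled-pairing
baseline (truth rows permuted) calibrates every overall metric. Spearman ties
use average ranks.

## Synthetic data

The generator emulates a QC'd paired multiome at desk scale. Cells belong to
`n_cell_types` discrete types; each type has a gene-expression program (gene
abundance fractions `∝ base_g · exp(τ·u_{t,g})`, with lognormal base
abundances, σ=0.7, and program effects `u ~ N(0,1)`, τ=1.0) and each cell
additionally carries a continuous program-intensity state
(`m_c ~ N(1, 0.5)`) that scales its type's program in both modalities — real
tissues have such within-type gradients, and without them the within-type
Bernoulli noise of a purely type-level accessibility model caps attainable
peak-wise AUROC near chance-diluted levels. Counts are drawn NB (Gamma–
Poisson, dispersion θ=2) with per-cell library sizes lognormal around 4000;
at the default 300-gene panel this leaves ~90% of cells passing the
200-expressed-genes QC bound. A fraction `peak_gene_coupling` (default 0.6)
of peaks is linked each to one gene and placed within 1–50 kb of its TSS on
the same chromosome, so the RP score is informative; the peak's Bernoulli
logit tracks the linked gene's standardised program across types (scale 3.0)
and the cell state (scale 0.8), with the most accessible type at a frequency
of 8–18% of cells. Uncoupled peaks are type- and state-independent noise at
1–8% frequency, as is the whole peak set when coupling is 0. The genome is
`n_chromosomes` 10-Mb chromosomes; peaks are 500 bp and non-overlapping,
genes have 2–5 exons and random strand.

Not emulated: doublets, ambient contamination, batch effects, fragment-count
(non-binary) accessibility, peak co-accessibility beyond the shared programs,
and realistic feature counts (hundreds, not tens of thousands, of features).
Passing the synthetic recovery checks therefore demonstrates that the
pipeline learns genuine cross-modality structure end to end at these scales,
not that it reaches any particular accuracy on real tissue data.

## Default problem sizes

The standard study conditions used by the tests and the reproduction script
are 1500 cells, 300 genes, 800 peaks on 4 chromosomes, 3 cell types,
coupling 0.6, seed 7. At this scale a full training run (early stopping from
500 epoch cap) takes on the order of a minute on one CPU core. Under these
conditions the Bayes-optimal predictor (the true generating probabilities)
achieves a mean held-out peak-wise AUROC of ≈0.74 — 40% of peaks are
uncoupled noise at AUROC 0.5 by construction — which bounds what any trained
model can reach; the shipped configuration trains to within ~0.01 of that
bound.

## Known limitations

- Matrices are densified for normalisation and training; the implementation
  targets desk-scale data (thousands of cells, hundreds to a few thousand
  features), not full-genome peak sets.
- The per-chromosome encoder requires peak columns grouped by chromosome;
  the pipeline sorts them (and the GAS gene columns) accordingly.
- No hyperparameter search, multi-GPU, doublet detection, batch correction,
  or peak calling. Inputs must already be count/peak matrices.
- The early-stopping phrase "set to N epochs" is interpreted as patience
  (epochs without validation improvement), exposed in `TrainConfig`.
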