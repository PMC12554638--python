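# dropfuse

Dropout imputation for single-cell RNA-seq count matrices that fuses
**linear** and **non-linear** expression structure, and imputes **only the
zeros it can defend as technical**.

## The problem

scRNA-seq count matrices are dominated by zeros, and the zeros are of two
kinds: *biological zeros* (the gene is genuinely silent in that cell) and
*technical zeros* or "dropouts" (the transcript was present but not
captured). Imputing every zero smears real biology; imputing none leaves
downstream clustering and differential expression degraded. dropfuse
addresses both failure modes for analysts working with genes × cells count
matrices from any platform that yields MatrixMarket or dense CSV output.

## The method

1. **Preprocess & partition.** Genes detected in < 3% of cells are removed;
   the matrix is library-size normalized to 10⁴ and log1p-transformed;
   genes are ranked by VST-standardized variance and split into groups
   G₁…G_r of 2000. Cells are clustered by spectral clustering on the PCA
   embedding of G₁, with the cluster count k chosen by mean silhouette over
   k ∈ 4…15; the matrix is tiled into gene-group × cell-cluster blocks M_gc.
2. **Zero classification.** Within each gene group, for the three best-
   silhouette clusterings, each zero of gene *i* in cluster *c* is marked a
   *false zero* if the gene's expression rate R₁ in that cluster satisfies
   R₁ ≥ min(R₂(block), R₂(group)), and a *true zero* if
   0 < R₁ ≤ min(R₂(block), R₂(group))/10, where R₂ is a non-zero rate.
   Marks are intersected across the three clusterings: only consensus
   false zeros are ever imputed; consensus true zeros join the non-zero
   entries as training data; everything else is left untouched.
3. **Feature learning per block.** A fused cell–cell similarity
   SC = (∏_d SC″_d)^{1/3} (row-min-max-scaled, symmetrized Pearson,
   Spearman and cosine similarities) and a gene–gene Jaccard similarity SG
   feed two variational graph autoencoders with two-layer GCN encoders
   μ = S̃ ReLU(S̃AW₀)W_μ (S̃ = D^{-1/2}SD^{-1/2}), trained jointly through
   the shared inner-product decoder Ã = Z_g Z_cᵀ under the loss
   L = λ·L_mse + (1−λ)·L_cos. In parallel, L2-regularized NMF
   (½‖X−WH‖²_F + (ω₁/2)‖W‖²_F + (ω₂/2)‖H‖²_F, multiplicative updates)
   extracts linear factors W, H.
4. **Fusion.** For each entry, the concatenation [Z_g(i) | Z_c(j) | W(i,·)
   | H(·,j)] feeds a per-block fully connected regressor trained on the
   training entries; predictions (clamped at 0, lognorm scale) replace the
   consensus false zeros only.

## Worked example

```bash
python examples/02_impute.py
```

```
preprocessed matrix: 266 x 200, 40720 zeros (76.5%)
best k selected: 3 (top-3 per group: [[3, 4, 2], [2, 3, 6]])
zeros imputed as dropouts: 9023 (22.2% of zeros)
zeros kept (biological or undecided): 31697
imputed-value range: [3.516, 6.537] (lognorm)
```

On a simulated 300 × 200 matrix with 3 planted clusters the pipeline
recovers k = 3, imputes 22% of the zeros — the consensus dropouts — and
leaves the rest at zero. `examples/03_masked_recovery.py` hides 10% of the
non-zero entries and scores the reconstruction:

```
mean over replicates at 10% masking:
  Pearson r = 0.480 (1 = perfect recovery)
  RMSE      = 2.787 lognorm units
  ARI/NMI vs true clusters after imputation: 0.949 / 0.927
```

`examples/04_ablation.py` compares full fusion against VGAE-only and
NMF-only feature sets on the same protocol.

There is also a thin CLI: `dropfuse impute`, `dropfuse benchmark`,
`dropfuse simulate` (see `dropfuse --help`).

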