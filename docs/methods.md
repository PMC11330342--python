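# Methods

## The problem

miRNAs act in specific subcellular compartments — cytoplasm, exosome,
nucleolus, nucleus, extracellular vesicle, microvesicle, mitochondrion — and
one miRNA commonly occupies several at once. Experimental localization assays
are expensive, so the package predicts, for each miRNA, a *set* of
compartments (a multi-label problem over 7 classes) from heterogeneous
evidence: the miRNA's sequence, and its associations with diseases, drugs and
target mRNAs.

## Pipeline

1. **Similarities.** Four miRNA×miRNA similarity matrices are computed:

   * GIP kernel on binary disease-association profiles,
     `GM(i,j) = exp(-λ‖A_i−A_j‖²)`, bandwidth `λ = n / Σ_k‖A_k‖²`;
   * normalized Smith–Waterman similarity
     `SW(i,j) = sp(i,j)/√(sp(i,i)·sp(j,j))` with local alignment scores `sp`
     (defaults match +2 / mismatch −1 / linear gap −2, via
     `Bio.Align.PairwiseAligner`; a precomputed `sp` matrix is also accepted);
   * Wang-style functional similarity `mFS` between disease sets over the
     disease ontology: each disease contributes decay-weighted semantic
     values `D_di(dt)` (decay Δ = 0.5) over its ancestor closure, pairs of
     diseases are compared through shared ancestors, and miRNA pairs through
     best-match sums over their disease sets;
   * `SW_GM` and `mFS_GM` replace exact zeros in SW/mFS with the GIP value,
     since alignment and disjoint disease sets leave many pairs at 0.

2. **Networks.** The sequence-similarity network `N_S` connects every pair
   with positive `SW_GM`, weighted by the similarity. The functional network
   `N_F` binarizes `mFS_GM` at threshold T. Three bipartite association
   networks link miRNAs to diseases, drugs and mRNAs (unweighted).

3. **Embeddings.** node2vec — second-order biased random walks (defaults
   p = q = 1, 10 walks/node, length 80) followed by skip-gram with 5 negative
   samples, window 5, 5 epochs — embeds `N_S` to 64 dimensions and each
   bipartite network to 128 dimensions; partner rows are discarded.

4. **Graph attention auto-encoder.** Each 128-D association embedding is
   refined along `N_F`: the encoder replaces each node's vector by an
   attention-weighted combination of its neighbors' transformed vectors
   (`e_ij = σ(v_s·act(Wh_i) + v_r·act(Wh_j))`, softmax over the neighborhood
   including a self-loop), the decoder mirrors it with transposed weights,
   and training minimizes feature reconstruction error plus a structure term
   `−Σ_edges log σ(z_i·z_j)` (weight 1, Adam 1e-3, 200 epochs).

5. **Co-localization ratios.** For each miRNA with target set M(m), the
   fraction of targets annotated to each of the four mRNA compartments
   (cytoplasm, exosome, nucleolus, nucleus). A target-less miRNA gets the
   zero vector: an empty target set carries no evidence, and 0 is the
   least-informative value that keeps the pipeline total.

6. **Classifier.** The five blocks (64+128+128+128+4 = 452 columns) become
   five tokens, each linearly projected to a common width; scaled dot-product
   self-attention across the tokens lets the model weigh evidence sources per
   miRNA; the attended tokens feed two ReLU hidden layers (256, 64) and a
   7-unit sigmoid output trained with binary cross-entropy (predictions
   clipped at 1e-7) under Adam. Scores ≥ θ = 0.5 become predicted labels
   (ties predict).

## Design choices in the open parts

* **Auto-encoder activations.** Hidden layers use tanh and the final decoder
  layer is linear. Node-embedding inputs are signed and roughly unit-scale;
  a sigmoid-range decoder cannot reconstruct them even in principle — its
  loss plateaus and the latent code degrades to near-chance discriminative
  value. tanh preserves sign symmetry in the hidden layers; the linear output
  removes the range constraint.

* **Functional-network threshold.** The default T is "auto": the 90th
  percentile of off-diagonal `mFS_GM`, targeting ~10% edge density. The fused
  similarity concentrates in a narrow band (GIP back-fill pushes most pairs
  above 0.4), so any fixed absolute cut-off either isolates every node or
  connects almost all pairs. A near-complete graph is degenerate for
  attention: coefficients pass through a bounded sigmoid, so softmax weights
  over hundreds of neighbors are nearly uniform, and the encoder output
  collapses toward the global mean. A density-targeted threshold yields a
  meaningful neighborhood graph for any similarity distribution. An absolute
  float T remains available.

* **Classifier capacity and regularization.** Defaults (token projection
  width 128, decoupled weight decay 0.3, 300 full-batch epochs, lr 1e-3) were
  selected by 10-fold-CV grid search on the synthetic benchmark — the same
  selection protocol the method prescribes for real data. Without weight
  decay the network drives training BCE to ~0 at a few hundred training
  samples and held-out ranking quality drops below a linear baseline.

* **Attention granularity.** Tokens are the five feature-type blocks rather
  than single features: a 5×5 attention map captures cross-source dependence
  without estimating an ill-conditioned 452×452 interaction, and it makes the
  feature-type ablation structurally clean.

* **Decision threshold.** How probabilities become label sets is unstated in
  the method's description; θ = 0.5 with a "≥" tie rule is used everywhere.

* **Set metrics.** Aiming/coverage/accuracy/absolute-true/absolute-false
  follow the standard set-based definitions (intersection over predicted set,
  over true set, over union; exact-match rate; normalized symmetric
  difference). An empty predicted set contributes 0 to aiming.

* **Cross-validation.** Plain shuffled k-fold (k = 10), seeded; out-of-fold
  scores are pooled over all samples before computing metrics and one
  ROC/PR curve per label.

* **Strongly/weakly split.** miRNAs are ranked by decreasing association
  count and halved; ties at the boundary resolve by index order and an odd
  element goes to the weakly group. The reported count threshold is
  data-driven (the smallest count inside the strongly group), not hard-coded.

* **Seeding.** One master seed is split per stage by CRC-32 hashing of the
  stage name, so any stage can be re-run in isolation yet full runs are
  bit-reproducible. Skip-gram, the auto-encoder and the classifier are
  single-threaded numpy/numba, which keeps training deterministic.

## Synthetic data: what it emulates and what it does not

The generator mimics the structure of the real inputs: 1041-miRNA-scale
entity tables (default 300 miRNAs, 120 diseases, 40 drugs, 400 mRNAs), a
skewed 7-label prevalence profile (exosome-like label most frequent,
nucleolus-like least), three bipartite association networks with realistic
mean degrees (≈15 disease, ≈3 drug, ≈8 mRNA associations per miRNA), a
random-tree disease ontology with occasional multiple parents, ~22-nt
sequences, and a 4-label mRNA localization table.

Localization signal is planted *indirectly*: every partner entity carries a
latent compartment affinity; with probability `signal` (benchmark: 0.8) an
association is drawn from affinity-matched partners, otherwise uniformly.
mRNA labels correlate with mRNA affinity, and sequences receive one fixed
6-mer motif per held compartment with probability `signal`. Features are
never written directly, so a model can only succeed if the embedding,
auto-encoder and ratio stages genuinely extract the shared-partner structure.
An optional `label_coupling` scales a miRNA's association count with its
label count, reproducing the empirical pattern that heavily-annotated miRNAs
carry more localizations.

What passing tests on this generator do **not** show: performance on real
RNALocate-derived data (real disease ontologies are deeper and unbalanced,
association degrees are heavy-tailed, sequence families share far richer
structure than single motifs), robustness to miRNA ID mismatches across
databases, or the method's published benchmark figures, which require the
authors' dataset.

## Problem sizes used by the test suite and acceptance script

The canonical benchmark runs 300 miRNAs with full pipeline defaults. The
31-subset feature ablation uses a reduced protocol (5 folds, 60 classifier
epochs, 2–3 seeds) — the quantity of interest there is the *trend* of mean
AUC across subset sizes, which is stable under the reduction. The
group-analysis dataset uses 200 miRNAs with shorter walks (5 walks of length
40, 3 skip-gram epochs). These sizes are the package's chosen benchmark
conditions; all are configurable.

## Known limitations

* The graph attention auto-encoder necessarily smooths along `N_F`: with
  bounded attention logits the refined vector is close to a neighborhood
  mean. On the synthetic benchmark this improves the drug and mRNA blocks but
  costs disease-block separability — `N_F` is itself derived from disease
  associations, so for that block the smoothing is redundant. At benchmark
  scale the net effect of the auto-encoder on the full model is negative
  (removing it raises average AUC by several points); its benefit is expected
  only where the functional network carries information the raw embedding of
  a given source lacks.
* At a few hundred training samples the self-attention classifier is at best
  on par with a well-regularized linear model; its advantage is expected at
  the real dataset's scale.
* AUC/AUPR for a label with a single class in the evaluated split are
  undefined; such labels are excluded from averages with a warning.
* Smith–Waterman is quadratic in the number of miRNAs (all-vs-all); for very
  large panels supply a precomputed score matrix.
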