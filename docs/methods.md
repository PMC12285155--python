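# Methods

## Model

The correction model is a fully connected variational autoencoder.
Encoder and decoder mirror each other: hidden layers of sizes 800 and 800
with ReLU activations and dropout 0.05 (training mode only), a Gaussian
latent of dimension 10, and a linear output layer. The output layer is
linear rather than ReLU because the targets are capped log1p values —
bounded below by 0 but with no reason to constrain the pre-clipping
decoder output. The loss is

    L = MSE(x, x̂) + α · KL[ Q(z|x) ‖ N(0, I) ]

with the KL term averaged per cell and α = 0.005 by default. α is
deliberately small: the latent is used for arithmetic (centroid shifts),
not for generation, so reconstruction fidelity is weighted over prior
matching. Optimization is Adam (learning rate 10⁻³, batch size 32). All
training is bit-reproducible: epoch *t* of a run draws its shuffle,
dropout masks and reparameterization noise from `default_rng([seed, t])`.

Desk-scale experiments in the tests and the acceptance script use hidden
layers (64, 64) or (32, 32); with a few hundred cells and genes the wide
default would be heavily over-parameterized and slower without changing
any qualitative behavior. The layer widths are ordinary configuration and
scale up unchanged.

### Correction semantics

One published description of the correction step reads "subtract the
dominant-batch mean from every cell of the type", which would center each
cell type at the origin rather than align batches. The canonical
batch-removal semantics — and what this package implements — is the
per-(type, batch) δ-shift

    z_i' = z_i + (M^t − mean latent of the cell's own (type, batch) group),

whose fixed point is exact coincidence of per-batch type centroids and
which leaves the dominant batch untouched (δ = 0). The literal
subtraction is retained behind `literal_subtraction=True` for comparison.
Under the δ-shift reading, correcting all cells of a type or only
non-dominant batches is numerically identical.

Correction uses the deterministic encoder output (the posterior mean μ),
never a sample: this removes stochasticity from the correction path and
makes federated/centralized equivalence exactly testable.

## Federation

Training follows FedAvg with sample-size weights N_c / ΣN (the
normalized form; an unnormalized variant that appears in some write-ups
is not weight-conserving). Each client's minibatch stream is seeded by
(federation seed, client id) with epoch offsets advancing across rounds,
and local Adam moments persist per client between rounds. Both choices
together make a one-client federation with R rounds × e epochs reproduce
an unbroken centralized run of R·e epochs bit for bit — the package's
core correctness oracle for the federated loop. Held-out clients never
contribute to training; they join only the correction workflow, where
they count toward dominance and receive the broadcast centroids.

Dominance ties resolve to the lexicographically smallest batch
identifier in both the centralized and the federated path, so the two
paths cannot disagree on tie cases.

## Secure aggregation

Values are encoded in fixed point with f = 16 fractional bits on the
ring Z_{2^64} (two's-complement signs) and split into additive shares:
n−1 shares uniform on the ring, the last the difference. With parameter
magnitudes ≤ 10 and ≤ ~50-way weighted sums, encodings stay far below
the 2⁶³ overflow boundary, and reconstruction error is ≤ 2⁻¹⁶ per
element per summand — well inside the 10⁻³ agreement budget with
plaintext FedAvg. Weight division happens after reconstruction; the
total cell count is public to the coordinator in FedAvg anyway.

Secure dominance detection shares per-type counts and opens only the
signs of pairwise share differences. A consequence, documented
deliberately: the coordinator learns the outcome of each comparison it
orchestrates — the ordering of clients for that type — but never any
count. The protocol is an honest-but-curious, in-process simulation with
instrumented transcripts; it is not hardened against malicious parties
and performs no networking.

## Preprocessing

The pipeline is ordered and state-checked: coverage filter (cells with
≥ 200 expressed genes kept, where "expressed" means strictly positive)
→ per-cell total-count normalization (default target 10,000) → highly
variable gene selection → log1p capped at 10. HVG selection computes
per-gene dispersion (variance/mean on the normalized layer) z-scored
within 20 equal-frequency mean bins, keeping genes with mean strictly
inside (0.0125, 2.5) and normalized dispersion strictly above 0.7. HVG
selection is global, not per-batch.

The standard thresholds assume transcriptome-scale panels (~15–20k
genes) where a cell's share of a 10,000-count budget puts typical gene
means inside the (0.0125, 2.5) window. Desk-scale synthetic panels have
hundreds of genes, so the orchestration layer scales the target sum to
the gene count and the coverage floor to a third of the panel — keeping
both filters in the same operating regime rather than degenerate.

Minority cell types (for the Combined/Dropped inclusion scenarios)
default to "fewer than 10 cells globally", a configurable stand-in:
the upstream literature delegates this definition without a number.
Standalone types are always flagged.

## Synthetic data

The generator draws counts from a gamma-Poisson (negative binomial)
model: expected count = type program × batch factor × library size, with
per-gene dispersion log-uniform in [0.1, 1.0], log-normal library sizes
(σ = 0.3), and uniform dropout zeroing (rate 0.1). Type programs share a
log-normal baseline (σ = 1) with 30 up-regulated marker genes per type
(6-fold); batch effects are gene-wise multiplicative log-normal factors
(σ_b per batch) affecting all types in a batch equally — exactly the
additive-in-log structure a latent shift can capture, which is the
method's own modeling assumption.

The benchmark preset (`two_batch_shared`) fixes the study conditions of
the recovery experiment: 1,000 cells, two batches, four shared types
(125 cells per batch and type), σ_b = 0.8 on one batch. Other presets
plant standalone types, minority types, five batches with differing
dominant batches, and a held-out batch.

What the generator does *not* emulate: platform-specific chemistry,
ambient RNA, doublets, mean-dependent dropout, continuous trajectories,
or batch effects that interact with cell type. Passing tests therefore
demonstrate the mechanics and internal consistency of the method under
its own assumptions, not performance on any real dataset.

## Metrics

All metrics consume the top 20 principal components (deterministic sign
convention: the largest-magnitude loading of each component is made
positive). kBET is the per-cell χ² acceptance variant: neighborhood
batch composition against global proportions, acceptance = fraction of
cells with p ≥ 0.05, median over neighborhood sizes of 5–25% of the
dataset (a single small fraction is appropriate for very large data).
LISI calibrates a per-cell Gaussian kernel to perplexity 30 (a standard
default; reduced with a warning on small data) and reports the inverse
Simpson index of neighbor label weights; iLISI is restricted to
shared-type cells. ASW_C maps mean silhouette to (s+1)/2; ASW_B is the
cell-type-stratified reversed form, mean of 1 − |s| over types spanning
≥ 2 batches. ARI compares a Louvain partition (union kNN graph, k = 15,
resolution 1.0) to type labels; NMI (arithmetic normalization) and
isolated-label F1 maximize over a resolution grid 0.1–2.0 in steps of
0.1. EBM normalizes neighbor-batch entropy by log(#batches) — which
also cancels the entropy base — over 50 pools of 100 sampled cells.
Isolated labels are the types present in the fewest batches; when every
type spans the same number of batches no label is isolated and ILF1 is
reported as not applicable rather than 0.

The comparison harness runs a two-sided Wilcoxon–Mann–Whitney test per
(metric, dataset) pair over per-seed values and applies
Benjamini–Hochberg correction across all pairs jointly; with 8 metrics
and 7 datasets exactly 56 tests enter the correction. Identical samples
short-circuit to p = 1 (the rank test is undefined under total ties).

## Downstream classification

The utility probe is an MLP (hidden 800–800 by default, batch
normalization + ReLU, softmax cross-entropy, Adam) on z-score-normalized
corrected latents under leave-one-batch-out cross-validation. Test folds
are standardized with training-fold statistics only; test cells whose
type never appeared in training count as errors. Epochs (50) and batch
size (64) are ordinary defaults; the tests use narrower layers for
speed.

## Numerical choices and degenerate inputs

- Encoder log-variances are clipped to ±15 before exponentiation.
- Decoded corrected expression is clipped at 0.
- Zero-sum cells pass through normalization as zeros.
- Zero-variance features in the classifier standardize to 0.
- Batch-norm minibatches of size 1 are skipped.
- Louvain is seeded through Python's global RNG (igraph's source of
  randomness); all other randomness flows through numpy Generators.

## Known limitations

- Fully connected VAEs on a handful of clients; no batch-norm layers in
  the VAE (they are known to interact badly with non-IID federation).
- The secure layer simulates parties in one process; transcripts are a
  testing device, not a security proof.
- The secure comparison reveals pairwise orderings (see above).
- Metrics are computed centrally on pooled corrected data; a real
  deployment would need federated evaluation, which is out of scope.
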