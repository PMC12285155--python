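# fedbatch

Privacy-aware federated batch-effect correction for single-cell RNA-seq.

Single-cell expression atlases are assembled from batches produced by
different labs, platforms and protocols. The technical variation between
batches (the *batch effect*) can swamp the biological differences of
interest, yet the raw data often cannot be pooled: hospitals and biobanks
are barred from sharing patient-level measurements. `fedbatch` corrects
batch effects **without moving raw data**: each data holder (client) keeps
its own batch, a coordinator orchestrates model training and the exchange
of a handful of aggregate latent vectors, and an optional secure-aggregation
layer hides even the per-client model parameters and cell counts.

## Method

The core model is a variational autoencoder trained on log-transformed,
highly-variable-gene expression. An encoder maps each cell *x<sub>i</sub>*
to a Gaussian posterior *Q(z|x<sub>i</sub>; φ)* over a low-dimensional
latent *z<sub>i</sub> ∈ ℝ<sup>k</sup>* (k = 10 by default); a mirrored
decoder reconstructs expression. The loss is mean-squared-error
reconstruction plus an α-weighted KL divergence to the standard normal
prior.

**Federated training.** Over *R* communication rounds, every client trains
the shared model locally for *e* epochs and uploads its parameters
θ<sub>c</sub>; the coordinator aggregates by sample-size-weighted averaging
(FedAvg),

&nbsp;&nbsp;&nbsp;&nbsp;θ<sub>r+1</sub> ← Σ<sub>c</sub> (N<sub>c</sub> / Σ N) · θ<sub>c</sub>,

and broadcasts the result. Defaults are R = 8 rounds and e = 2 local epochs.

**δ-vector correction.** For every *shared* cell type *t* (present in at
least two batches) the *dominant* batch b\* = argmax<sub>b</sub>
N<sub>b</sub><sup>t</sup> is detected — securely, if requested, revealing
only the winner's identity. The dominant client broadcasts the latent
centroid M<sup>t</sup> of its own type-*t* cells. Each client then shifts
every local cell of type *t* by the δ-vector

&nbsp;&nbsp;&nbsp;&nbsp;z<sub>i</sub>′ = z<sub>i</sub> + (M<sup>t</sup> − mean of the client's type-*t* latents),

which aligns all batches' type-*t* centroids exactly, and decodes the
shifted latents into corrected expression. Standalone types (one batch
only) are left untouched. New sites can join the correction step without
retraining (held-out batches), or correct entirely offline from an exported
centroid artifact.

**Secure aggregation.** Parameter averages and dominance detection can run
on additive secret shares over a 2<sup>64</sup> fixed-point ring (16
fractional bits, 3 computational parties by default): no single party ever
sees a client's parameters or counts, and the secure path agrees with the
plaintext path to ~10<sup>−5</sup>.

**Evaluation.** Ten standard integration metrics on the top 20 principal
components — kBET acceptance, iLISI/cLISI, ASW_C and batch-stratified
reversed ASW_B, ARI and NMI against Louvain clusterings, entropy of batch
mixing (EBM), isolated-label F1, graph connectivity, and kNN label accuracy
— plus a comparison harness (per-pair Wilcoxon–Mann–Whitney tests with
Benjamini–Hochberg correction) and a leave-one-batch-out MLP classifier
measuring downstream utility of the corrected latents.

## Worked example

```python
from fedbatch.pipeline import PipelineConfig, run_pipeline

out = run_pipeline(PipelineConfig(preset="two_batch_shared", seed=1))
for m in ("kbet", "ilisi", "ebm", "asw_b", "clisi"):
    print(f"{m:6s}  raw {out['metrics_raw'][m]:.3f} -> corrected {out['metrics_corrected'][m]:.3f}")
```

This simulates 1,000 cells in two batches sharing four cell types, with a
strong gene-wise multiplicative batch effect injected into one batch,
preprocesses (coverage filter, total-count normalization, HVG selection,
capped log1p), trains the VAE federatedly (8 rounds × 2 local epochs, one
client per batch) and applies the federated δ-vector correction. It prints:

```
kbet    raw 0.134 -> corrected 0.840
ilisi   raw 1.197 -> corrected 1.810
ebm     raw 0.254 -> corrected 0.892
asw_b   raw 0.807 -> corrected 0.885
clisi   raw 1.111 -> corrected 1.166
```

Before correction the batches barely mix (kBET acceptance 0.13, mean iLISI
1.20 where 2.0 would be perfect two-batch mixing); after correction the
mixing metrics approach their ideals while cLISI — the purity of cell-type
neighborhoods, ideally 1.0 — degrades only marginally, i.e. the biological
structure survives the correction.

The same workflow is available from the shell:

```bash
fedbatch simulate --preset two_batch_shared --seed 1 --out sim.h5ad
fedbatch preprocess sim.h5ad --out pp.h5ad --min-genes 100 --target-sum 300
fedbatch train-federated pp.h5ad --out run/ --rounds 8 --local-epochs 2 --hidden 64,64
fedbatch evaluate run/corrected.h5ad --out metrics.csv
```

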