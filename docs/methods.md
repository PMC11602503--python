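# Methods

## Problem and model

`smmsn` clusters patients from several omics views — e.g. mRNA expression,
DNA methylation and miRNA expression measured on the same cohort — into
molecular subtypes without labels. The model combines four ingredients:

1. **Per-view feature representations.** Each view X_v (N patients × m_v
   features) passes through a stacked autoencoder (SAE): a mirrored
   encoder/decoder stack of affine + LeakyReLU layers trained on the
   reconstruction loss L_res = (1/2N) Σ_v ‖X̂_v − X_v‖²_F. The encoder output
   Z_v (N × d) is the view's feature representation.

2. **Per-view structural representations.** A heat-kernel similarity
   S_ij = exp(−‖x_i − x_j‖²/σ) over the standardized view yields a binary
   K-nearest-neighbour graph (union-symmetrized); a graph convolution
   network (GCN) propagates over the self-looped, symmetrically normalized
   adjacency D^(−1/2)(A+I)D^(−1/2). Before every convolution after the
   first, the previous GCN output G is blended with the matching encoder
   activation, H = (1−ε)G + εZ with ε = 0.5, so layer-diverse autoencoder
   features keep deep propagation from over-smoothing. The last GCN layer
   emits c-way logits.

3. **Two fusion strategies.** The per-view GCN logits are concatenated and
   multiplied by a learnable (V·c) × c matrix, then row-softmaxed into the
   fused probability matrix G ("adaptive weighting"). The per-view SAE
   latents are fused by learning a free matrix Z minimizing
   L_fus = Σ_v ‖Z − Z_v‖²_F ("error reconstruction"); for fixed latents its
   minimizer is the elementwise mean across views, which is also how Z is
   initialized.

4. **Dual self-supervision.** Soft assignments
   q_ij ∝ (1 + ‖z_i − μ_j‖²/δ)^(−(δ+1)/2) (Student-t kernel, δ = 1) compare
   the fused latent to learnable centres μ; the sharpened, frequency-
   normalized target p_ij ∝ q_ij²/f_j (f_j = Σ_i q_ij) supervises both
   branches at once through L_clu = KL(P‖Q) and L_gcn = KL(P‖G). The total
   objective is L = L_res + λ1·L_fus + λ2·L_clu + λ3·L_gcn. Labels are
   y_i = argmax_j g_ij.

Training proceeds in stages: (1) reconstruction-only SAE pretraining;
(2) Z initialized to the latent mean, centres by seeded K-means on Z;
(3) joint full-batch Adam training of every parameter with P refreshed each
epoch (detached — targets are constants within a step); (4) labels from the
final forward pass.

## Parameters, defaults, rationale

| parameter | default | meaning |
|---|---|---|
| latent dim d | 100 | shared width of every view's encoder output |
| encoder widths | 512, 256, 100 | hidden stack per view; mirrored decoder |
| K (neighbours) | 40 | KNN graph degree before symmetrization |
| σ | median pairwise squared distance | heat-kernel bandwidth; per view, configurable fixed value |
| ε | 0.5 | GCN/SAE blending weight in H = (1−ε)G + εZ |
| δ | 1 | Student-t degrees of freedom (standard deep-embedded-clustering choice) |
| λ1, λ2, λ3 | 1.0, 0.1, 0.01 | loss balance; common deep-clustering scaling where the largest-magnitude term (fusion) keeps weight 1 and the KL terms are damped |
| learning rate | 1e-4 | Adam, joint phase |
| weight decay | 1e-15 | Adam L2 coefficient |
| epochs | 500 joint | full-batch |
| pretraining | 200 epochs, lr 1e-3 | reconstruction only; the larger rate compensates for the short schedule |
| missingness thresholds | 20% / 20% | drop patients first, then features, strictly above threshold; residual gaps mean-imputed |

The λ values, pretraining schedule, SAE depth and σ rule are implementation
choices — they are deliberately exposed in the config because no single
published setting exists for them; the defaults above were fixed once against
the synthetic benchmarks and are not tuned per dataset.

## Numerical choices

- **Feature normalization** divides by the population standard deviation
  (unit spread), the standard reading of z-score normalization; zero-variance
  columns are dropped with a warning rather than producing NaNs.
- Equal-similarity KNN ties resolve to the lowest sample index (stable
  argsort); argmax label ties likewise.
- Softmax and its KL losses run through **log-sum-exp**: in single precision
  a softmax entry can underflow to exactly zero, and `log` of it would poison
  the loss. `kl_divergence` treats 0·log(0/r) as 0 and raises on true
  infinite divergence (r = 0 where p > 0).
- The target distribution P for the GCN-only ablation is computed from
  double-precision probabilities reconstructed from the log-softmax, so a
  nearly-empty cluster column does not collapse to an exact zero frequency.
- Training defaults to **float32** (the unit-level API and tests run in
  float64); all arithmetic is deterministic, so one config + seed always
  reproduces the same label vector bit for bit.
- The gradients come from a small reverse-mode autodiff over numpy arrays
  written for this package; every operation is verified against central
  finite differences in the test suite.

## Ablation modes

`ablation_mode` reproduces the model's component study:

- `full` — everything above; labels from G.
- `sae_only` — SAE branch with single self-supervision
  (L_res + λ1 L_fus + λ2 L_clu); labels from argmax Q.
- `gcn_only` — GCN branch with single self-supervision: P is built from G
  itself and only λ3·KL(P‖G) is trained; labels from G. λ2 > 0 is a config
  error here because no fused latent exists.

## What the synthetic generator does and does not emulate

Samples share a 12-dimensional latent space: cluster centres are isotropic
Gaussian draws scaled so their expected pairwise distance equals
`separation`, points get unit Gaussian scatter around their centre, and each
view observes the latents through its own random linear map (rows scaled to
unit output variance) plus Gaussian noise of SD `noise_sd`; a `missing_rate`
fraction of entries can be blanked. This reproduces the *shape* of subtype
cohorts — a few hundred patients, views of different dimensionality, one
shared partition, per-view noise — and makes recovery difficulty a single
controlled quantity. It does **not** emulate heavy-tailed expression
distributions, methylation beta values bounded in [0,1], count data,
view-specific (non-shared) structure, or batch effects; passing the
benchmarks shows the pipeline recovers planted linear-Gaussian structure,
not that it handles those real-data pathologies.

Named fixtures (all runnable in minutes on one CPU):

- `easy3` — N=150, V=2, c=3, separation 6 (≈6 within-cluster SDs between
  centres): near-perfect recovery expected.
- `noisy4` — N=200, V=3, c=4, separation 3: overlapping clusters; plain
  K-means on the concatenated raw views lands well between chance and
  perfect, leaving headroom for integration.
- `null2` — separation 0: no structure; accuracy should sit at chance 1/c,
  a guard against hallucinated clusters.

Benchmark problem sizes follow these fixtures (five seeds each, every seed
changing both the generated data and the model initialization).

## Known limitations

- Full-batch training only; cohorts beyond a few thousand patients would
  need minibatching, which the patient-graph convolution complicates.
- The number of clusters c is an input, not estimated.
- With 500 joint epochs at learning rate 1e-4, the per-view latents are only
  partially aligned by L_fus; on heavily overlapping data the fused mean can
  blur structure that a single view retains, and the pipeline does not
  always beat plain K-means on concatenated features there. The ablation
  ordering (dual ≥ single-branch) is still observed on the benchmarks.
- The GCN-only ablation self-trains from its own targets and can collapse
  clusters on weak-structure data; that fragility is expected and is part of
  what the component study demonstrates.
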