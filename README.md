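# smmsn

Self-supervised multi-fusion network clustering of multi-omics data, for
discovering molecular subtypes (e.g. cancer subtypes) from several omics
matrices — mRNA expression, DNA methylation, miRNA expression — measured on
the same patients, without any labels.

## The method

Each omics view X_v ∈ R^(N×m_v) contributes two representations:

- a **feature representation** Z_v from a stacked autoencoder trained on the
  reconstruction loss L_res = (1/2N) Σ_v ‖X̂_v − X_v‖²_F, and
- a **structural representation** from a graph convolutional network over
  the patient K-nearest-neighbour graph built from heat-kernel similarities
  S_ij = exp(−‖x_i − x_j‖²/σ), with the autoencoder activations injected at
  every layer, H^(l) = (1−ε)·G^(l) + ε·Z^(l), to counter over-smoothing.

Views are fused twice: the per-view GCN logits through a learnable adaptive
weighting matrix followed by a row softmax (giving a probability matrix G),
and the per-view latents through an error-reconstruction objective
L_fus = Σ_v ‖Z − Z_v‖²_F whose free minimizer Z is the consensus latent.
A dual self-supervised objective then refines both: Student-t soft
assignments Q of Z to learnable cluster centres are sharpened into targets
p_ij ∝ q_ij²/f_j, and the same P supervises both branches,

    L = L_res + λ1·L_fus + λ2·KL(P‖Q) + λ3·KL(P‖G).

Cluster labels are y_i = argmax_j g_ij. Accuracy against ground truth is
mapped clustering accuracy (ACC): the best one-to-one matching of clusters
to classes, found by the Hungarian algorithm.

The package is pure scientific Python (numpy/scipy/pandas/scikit-learn) and
ships its own compact reverse-mode autodiff engine for the network training,
plus a synthetic multi-omics generator so every stage is testable offline.

## Worked example

```python
from smmsn.eval import evaluate_run
from smmsn.preprocess import PreprocessConfig, preprocess_views
from smmsn.selfsup import TrainConfig, train_smmsn
from smmsn.synthetic import fixture_catalog, generate_multiomics

spec = fixture_catalog()["easy3"]          # 150 patients, 2 views, 3 subtypes
views, labels = generate_multiomics(spec)
pviews, graphs, _ = preprocess_views(views, PreprocessConfig())
result = train_smmsn(pviews, graphs,
                     TrainConfig(n_clusters=3, seed=0), truth=labels)
print(evaluate_run(result, labels))
```

Running `python examples/02_train_and_cluster.py` (the same computation)
prints:

```
epochs: 500 joint + 200 pretraining
total loss: 17586.9 -> 533.5
cluster sizes: [50, 50, 50]
mapped accuracy (ACC): 1.000  ARI: 1.000  NMI: 1.000
```

The loss falls by two orders of magnitude over joint training and the three
planted subtypes of 50 patients each are recovered exactly (ACC = 1.0 means
every patient lands in the right group after optimal cluster-to-class
matching). `examples/` holds two more narrative scripts: graph construction
diagnostics and the ablation comparison of the full dual-supervised model
against its single branches.

## Command line

```bash
smmsn simulate --spec easy3 --out data/          # write TSV views + labels
smmsn run --config cfg.yaml --out results/       # preprocess, train, cluster
smmsn evaluate --labels results/labels.tsv --truth data/labels.tsv --out m.json
```

`run` writes `labels.tsv`, `metrics.json`, `loss_trace.csv`, a preprocessing
report and a model checkpoint. Input matrices are TSV/CSV with sample IDs in
the first column and feature IDs in the header; missing entries are empty or
`NA`. See `smmsn/config.py` for the YAML layout.

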