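"""YAML run configuration: file paths, preprocessing, network and training
hyperparameters, loss weights.

Example
-------
::

    data:
      views:
        mrna: data/mrna.tsv
        methylation: data/methylation.tsv
      truth: data/labels.tsv        # optional
    preprocess:
      k_neighbors: 40
    networks:
      encoder_dims: [512, 256, 100]
      epsilon: 0.5
    loss_weights: {lambda1: 1.0, lambda2: 0.1, lambda3: 0.01}
    train:
      n_clusters: 3
      epochs: 500
      seed: 0
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .preprocess import PreprocessConfig
from .selfsup import LossWeights, TrainConfig


def load_config(path: str | Path) -> dict:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    data = raw.get("data", {})
    views = data.get("views")
    if not views:
        raise ValueError(f"{path}: config must list at least one view under data.views")
    net = raw.get("networks", {})
    train_kwargs = dict(raw.get("train", {}))
    if "encoder_dims" in net:
        train_kwargs["encoder_dims"] = tuple(net["encoder_dims"])
    if "epsilon" in net:
        train_kwargs["epsilon"] = float(net["epsilon"])
    if "leaky_slope" in net:
        train_kwargs["leaky_slope"] = float(net["leaky_slope"])
    return {
        "views": dict(views),
        "truth": data.get("truth"),
        "preprocess": PreprocessConfig(**raw.get("preprocess", {})),
        "train": TrainConfig(**train_kwargs),
        "loss_weights": LossWeights(**raw.get("loss_weights", {})),
    }
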