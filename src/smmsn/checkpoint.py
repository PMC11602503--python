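"""Model checkpointing: all learnable arrays plus the run config in one
``.npz`` file."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .autodiff import Tensor
from .fusion import FusionState
from .networks import GcnState, SaeState
from .selfsup import ClusterHead, SmmsnModel, TrainConfig


def save_checkpoint(model: SmmsnModel, path: str | Path) -> None:
    arrays: dict[str, np.ndarray] = {}
    for i, s in enumerate(model.sae_states):
        for l, (W, b) in enumerate(s.encoder):
            arrays[f"sae{i}_enc{l}_W"] = W.data
            arrays[f"sae{i}_enc{l}_b"] = b.data
        for l, (W, b) in enumerate(s.decoder):
            arrays[f"sae{i}_dec{l}_W"] = W.data
            arrays[f"sae{i}_dec{l}_b"] = b.data
    for i, g in enumerate(model.gcn_states):
        for l, W in enumerate(g.weights):
            arrays[f"gcn{i}_w{l}"] = W.data
    if model.fusion.W_fusion is not None:
        arrays["fusion_W"] = model.fusion.W_fusion.data
    if model.fusion.Z_fused is not None:
        arrays["fusion_Z"] = model.fusion.Z_fused.data
    if model.head is not None:
        arrays["centers"] = model.head.centers.data
        arrays["delta"] = np.asarray(model.head.delta)
    meta = dataclasses.asdict(model.config)
    meta["n_views_sae"] = len(model.sae_states)
    meta["n_views_gcn"] = len(model.gcn_states)
    meta["sae_slopes"] = [s.slope for s in model.sae_states]
    meta["gcn_epsilons"] = [g.epsilon for g in model.gcn_states]
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8)
    np.savez(Path(path), **arrays)


def load_checkpoint(path: str | Path) -> SmmsnModel:
    with np.load(Path(path)) as data:
        arrays = {k: data[k] for k in data.files}
    meta = json.loads(bytes(arrays.pop("meta_json")).decode("utf-8"))
    n_sae = meta.pop("n_views_sae")
    n_gcn = meta.pop("n_views_gcn")
    slopes = meta.pop("sae_slopes")
    epsilons = meta.pop("gcn_epsilons")
    cfg = TrainConfig(**{k: (tuple(v) if k == "encoder_dims" else v)
                         for k, v in meta.items()})

    def _param(key):
        return Tensor(arrays[key], requires_grad=True)

    sae_states = []
    for i in range(n_sae):
        enc, dec, l = [], [], 0
        while f"sae{i}_enc{l}_W" in arrays:
            enc.append((_param(f"sae{i}_enc{l}_W"), _param(f"sae{i}_enc{l}_b")))
            l += 1
        l = 0
        while f"sae{i}_dec{l}_W" in arrays:
            dec.append((_param(f"sae{i}_dec{l}_W"), _param(f"sae{i}_dec{l}_b")))
            l += 1
        sae_states.append(SaeState(encoder=enc, decoder=dec,
                                   encoder_dims=cfg.encoder_dims,
                                   slope=slopes[i]))
    gcn_states = []
    for i in range(n_gcn):
        weights, l = [], 0
        while f"gcn{i}_w{l}" in arrays:
            weights.append(_param(f"gcn{i}_w{l}"))
            l += 1
        gcn_states.append(GcnState(weights=weights, epsilon=epsilons[i],
                                   slope=cfg.leaky_slope))
    fusion = FusionState(
        W_fusion=_param("fusion_W") if "fusion_W" in arrays else None,
        Z_fused=_param("fusion_Z") if "fusion_Z" in arrays else None,
    )
    head = None
    if "centers" in arrays:
        head = ClusterHead(centers=_param("centers"),
                           delta=float(arrays["delta"]))
    return SmmsnModel(sae_states=sae_states, gcn_states=gcn_states,
                      fusion=fusion, head=head, config=cfg)
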