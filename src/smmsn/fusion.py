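"""Multi-view fusion: adaptive weighting of GCN logits, error-reconstruction
fusion of SAE latents.

The GCN branch of each view ends in N x c logits.  Adaptive fusion
concatenates the V logit blocks column-wise and multiplies by a learnable
(V*c) x c weight matrix, then applies a row softmax, giving the fused
probability matrix G whose entry g_ij is the probability that sample i
belongs to cluster j.  The SAE branch ends in per-view N x d latents; their
fusion Z is a free learnable matrix pulled toward every view's latent by the
error-reconstruction loss  L_fus = sum_v ||Z - Z_v||_F^2,  whose minimizer
(for fixed latents) is the elementwise mean across views.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, log_row_softmax, row_softmax

__all__ = ["FusionState", "init_fusion_weights", "init_fused_latent",
           "adaptive_fusion", "fusion_reconstruction_loss"]


@dataclass
class FusionState:
    """Learnable fusion parameters: W_fusion ((V*c) x c) and Z_fused (N x d)."""

    W_fusion: Tensor | None = None
    Z_fused: Tensor | None = None

    def parameters(self) -> list[Tensor]:
        return [t for t in (self.W_fusion, self.Z_fused) if t is not None]


def init_fusion_weights(n_views: int, n_clusters: int) -> Tensor:
    """Stacked identity blocks scaled 1/V: fusion starts as the plain average
    of the per-view logits, biased toward no view."""
    blocks = np.tile(np.eye(n_clusters), (n_views, 1)) / n_views
    return Tensor(blocks, requires_grad=True)


def init_fused_latent(per_view_latents: list[np.ndarray]) -> Tensor:
    """Elementwise mean across views — the analytic minimizer of L_fus."""
    stack = np.stack([np.asarray(z, dtype=np.float64) for z in per_view_latents])
    return Tensor(stack.mean(axis=0), requires_grad=True)


def adaptive_fusion(per_view_logits, state: FusionState, return_log: bool = False):
    """Row-stochastic fused assignment G from the per-view GCN logits.

    With ``return_log=True`` also returns log G computed by log-sum-exp,
    which KL losses should consume (stable where softmax entries underflow).
    """
    tensors = [z if isinstance(z, Tensor) else Tensor(z) for z in per_view_logits]
    shapes = {t.shape for t in tensors}
    if len(shapes) != 1:
        raise ValueError(f"per-view logits disagree in shape: {sorted(shapes)}")
    (n, c), = shapes
    if state.W_fusion is None:
        raise ValueError("FusionState.W_fusion is not initialized")
    if state.W_fusion.shape != (len(tensors) * c, c):
        raise ValueError(
            f"W_fusion has shape {state.W_fusion.shape}; expected "
            f"({len(tensors) * c}, {c}) for {len(tensors)} views"
        )
    fused = concat(tensors, axis=1) @ state.W_fusion
    G = row_softmax(fused)
    tensor_in = any(isinstance(z, Tensor) for z in per_view_logits)
    if return_log:
        logG = log_row_softmax(fused)
        return (G, logG) if tensor_in else (G.data, logG.data)
    return G if tensor_in else G.data


def fusion_reconstruction_loss(Z_fused, per_view_latents):
    """L_fus = sum_v ||Z_fused - Z_v||_F^2."""
    Z = Z_fused if isinstance(Z_fused, Tensor) else Tensor(Z_fused)
    total = None
    for z_v in per_view_latents:
        z_v = z_v if isinstance(z_v, Tensor) else Tensor(z_v)
        if z_v.shape != Z.shape:
            raise ValueError(f"shape mismatch: {z_v.shape} vs {Z.shape}")
        diff = Z - z_v
        term = (diff * diff).sum()
        total = term if total is None else total + term
    if total is None:
        raise ValueError("need at least one view latent")
    return total
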