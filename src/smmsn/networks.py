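"""Per-view stacked autoencoder and graph-convolution branches.

The SAE learns a feature representation of each view through a mirrored
encoder/decoder stack of affine + LeakyReLU layers; the GCN learns a
structural representation by propagating over the normalized patient-KNN
adjacency.  The two branches are coupled layer-wise: before each graph
convolution after the first, the previous GCN output G and the matching SAE
encoder activation Z are blended into a joint representation

    H = (1 - eps) * G + eps * Z,

which feeds the convolution.  Injecting the (layer-diverse) autoencoder
features counteracts GCN over-smoothing, where deep propagation drives all
node representations within a component toward the same vector.  The final
GCN layer emits c-way logits (one column per cluster) with no activation;
the softmax is applied downstream in the fusion step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, leaky_relu
from .preprocess import OmicsView, SimilarityGraph

__all__ = [
    "SaeState",
    "GcnState",
    "init_sae",
    "init_gcn",
    "sae_forward",
    "reconstruction_loss",
    "joint_representation",
    "gcn_forward",
]

DEFAULT_ENCODER_DIMS = (512, 256, 100)  # hidden widths; last entry is latent d
DEFAULT_LEAKY_SLOPE = 0.01


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


@dataclass
class SaeState:
    """Weights of one view's stacked autoencoder (mirrored encoder/decoder)."""

    encoder: list[tuple[Tensor, Tensor]]  # (W, b) per layer
    decoder: list[tuple[Tensor, Tensor]]
    encoder_dims: tuple[int, ...]
    slope: float = DEFAULT_LEAKY_SLOPE

    @property
    def latent_dim(self) -> int:
        return self.encoder_dims[-1]

    def parameters(self) -> list[Tensor]:
        return [t for pair in self.encoder + self.decoder for t in pair]


@dataclass
class GcnState:
    """Weights of one view's GCN branch.

    One weight matrix per encoder layer plus a final classification layer of
    width c; hidden widths match the encoder so G and Z can be blended.
    """

    weights: list[Tensor]
    epsilon: float = 0.5
    slope: float = DEFAULT_LEAKY_SLOPE

    def parameters(self) -> list[Tensor]:
        return list(self.weights)


def init_sae(
    n_features: int,
    encoder_dims: tuple[int, ...] = DEFAULT_ENCODER_DIMS,
    rng: np.random.Generator | None = None,
    slope: float = DEFAULT_LEAKY_SLOPE,
) -> SaeState:
    rng = rng or np.random.default_rng(0)
    dims = (n_features, *encoder_dims)
    encoder = [
        (Tensor(_glorot(rng, dims[i], dims[i + 1]), requires_grad=True),
         Tensor(np.zeros(dims[i + 1]), requires_grad=True))
        for i in range(len(dims) - 1)
    ]
    rev = dims[::-1]
    decoder = [
        (Tensor(_glorot(rng, rev[i], rev[i + 1]), requires_grad=True),
         Tensor(np.zeros(rev[i + 1]), requires_grad=True))
        for i in range(len(rev) - 1)
    ]
    return SaeState(encoder=encoder, decoder=decoder,
                    encoder_dims=tuple(encoder_dims), slope=slope)


def init_gcn(
    n_features: int,
    n_clusters: int,
    encoder_dims: tuple[int, ...] = DEFAULT_ENCODER_DIMS,
    rng: np.random.Generator | None = None,
    epsilon: float = 0.5,
    slope: float = DEFAULT_LEAKY_SLOPE,
) -> GcnState:
    rng = rng or np.random.default_rng(0)
    dims = (n_features, *encoder_dims, n_clusters)
    weights = [
        Tensor(_glorot(rng, dims[i], dims[i + 1]), requires_grad=True)
        for i in range(len(dims) - 1)
    ]
    return GcnState(weights=weights, epsilon=epsilon, slope=slope)


def sae_forward(
    view: OmicsView | np.ndarray, state: SaeState
) -> tuple[list[Tensor], Tensor]:
    """Run the autoencoder; return all encoder activations and the output.

    The encoder stack starts from the raw matrix (Z^(0) = X); every layer is
    affine + LeakyReLU.  The decoder mirrors the widths; its last layer is
    linear, since standardized inputs take values on all of R.
    """
    X = view.X if isinstance(view, OmicsView) else np.asarray(view)
    if X.shape[1] != state.encoder[0][0].shape[0]:
        raise ValueError(
            f"input has {X.shape[1]} features but the first encoder layer "
            f"expects {state.encoder[0][0].shape[0]}"
        )
    z = Tensor(X)
    latents: list[Tensor] = []
    for W, b in state.encoder:
        z = leaky_relu(z @ W + b, state.slope)
        latents.append(z)
    for i, (W, b) in enumerate(state.decoder):
        z = z @ W + b
        if i < len(state.decoder) - 1:
            z = leaky_relu(z, state.slope)
    return latents, z


def reconstruction_loss(
    views: list[OmicsView | np.ndarray], reconstructions: list[Tensor | np.ndarray]
) -> Tensor:
    """L_res = (1 / 2N) * sum_v ||Xhat_v - X_v||_F^2."""
    if len(views) != len(reconstructions):
        raise ValueError("views and reconstructions must pair up")
    total = None
    n = None
    for X, Xhat in zip(views, reconstructions):
        X = X.X if isinstance(X, OmicsView) else np.asarray(X)
        Xhat = Xhat if isinstance(Xhat, Tensor) else Tensor(Xhat)
        if Xhat.shape != X.shape:
            raise ValueError(f"shape mismatch: {Xhat.shape} vs {X.shape}")
        if n is None:
            n = X.shape[0]
        diff = Xhat - Tensor(X)
        term = (diff * diff).sum()
        total = term if total is None else total + term
    return total * (1.0 / (2 * n))


def joint_representation(G_prev, Z_prev, epsilon: float):
    """H = (1 - eps) * G + eps * Z, blending structure and features."""
    G = G_prev if isinstance(G_prev, Tensor) else Tensor(G_prev)
    Z = Z_prev if isinstance(Z_prev, Tensor) else Tensor(Z_prev)
    if G.shape != Z.shape:
        raise ValueError(f"shape mismatch: G {G.shape} vs Z {Z.shape}")
    out = G * (1.0 - epsilon) + Z * epsilon
    return out if (isinstance(G_prev, Tensor) or isinstance(Z_prev, Tensor)) else out.data


def gcn_forward(
    graph: SimilarityGraph | np.ndarray,
    view: OmicsView | np.ndarray,
    latents: list[Tensor] | None,
    state: GcnState,
) -> Tensor:
    """Propagate a view through the GCN branch; return N x c logits.

    Layer 1 convolves the raw matrix; each later layer first blends the
    previous GCN output with the matching encoder activation (H = (1-eps)G +
    eps*Z) and then convolves H.  With ``latents=None`` or ``epsilon=0`` this
    reduces to a plain multi-layer GCN.  The last layer is linear.
    """
    A = graph.A_norm if isinstance(graph, SimilarityGraph) else np.asarray(graph)
    X = view.X if isinstance(view, OmicsView) else np.asarray(view)
    n_hidden = len(state.weights) - 1
    if latents is not None and len(latents) != n_hidden:
        raise ValueError(
            f"got {len(latents)} encoder activations for {n_hidden} hidden GCN layers"
        )
    A_t = Tensor(A)
    G = leaky_relu(A_t @ (Tensor(X) @ state.weights[0]), state.slope)
    for layer in range(1, len(state.weights)):
        if latents is not None and state.epsilon != 0.0:
            H = joint_representation(G, latents[layer - 1], state.epsilon)
        else:
            H = G
        G = A_t @ (H @ state.weights[layer])
        if layer < len(state.weights) - 1:
            G = leaky_relu(G, state.slope)
    return G
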