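"""Dual self-supervised clustering objective and the end-to-end trainer.

The fused SAE latent Z is compared against learnable cluster centres with a
Student-t kernel, giving soft assignments Q; sharpening and frequency
normalization turn Q into the target distribution P.  P then supervises both
branches at once: KL(P || Q) pulls the latent representation toward the
centres, KL(P || G) pulls the fused GCN probabilities toward the same
targets.  Because P is recomputed from Q as training proceeds, the procedure
is self-supervised — no labels enter the loop.  The overall objective is

    L = L_res + lambda1 * L_fus + lambda2 * L_clu + lambda3 * L_gcn

combining SAE reconstruction, error-reconstruction fusion, and the two KL
terms.  Cluster labels are read off the fused GCN probabilities by row-wise
argmax.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .autodiff import Adam, Tensor
from .eval import ClusteringResult, clustering_accuracy
from .fusion import (FusionState, adaptive_fusion, fusion_reconstruction_loss,
                     init_fused_latent, init_fusion_weights)
from .networks import (DEFAULT_ENCODER_DIMS, DEFAULT_LEAKY_SLOPE, GcnState,
                       SaeState, gcn_forward, init_gcn, init_sae,
                       reconstruction_loss, sae_forward)
from .preprocess import OmicsView, SimilarityGraph

__all__ = [
    "ClusterHead", "LossWeights", "TrainConfig", "SmmsnModel",
    "soft_assignment", "target_distribution", "kl_divergence", "total_loss",
    "init_centers", "assign_labels", "train_smmsn",
]

ABLATION_MODES = ("full", "sae_only", "gcn_only")


@dataclass
class ClusterHead:
    """Learnable cluster centres and the Student-t degrees of freedom."""

    centers: Tensor
    delta: float = 1.0

    def __post_init__(self):
        if not isinstance(self.centers, Tensor):
            self.centers = Tensor(self.centers, requires_grad=True)
        if self.centers.shape[0] < 2:
            raise ValueError("need at least 2 cluster centres")
        if not np.isfinite(self.centers.data).all():
            raise ValueError("cluster centres must be finite")
        if self.delta <= 0:
            raise ValueError("Student-t degrees of freedom must be positive")


@dataclass
class LossWeights:
    """Balance coefficients (lambda1, lambda2, lambda3) of the total loss."""

    lambda1: float = 1.0
    lambda2: float = 0.1
    lambda3: float = 0.01

    def __post_init__(self):
        vals = (self.lambda1, self.lambda2, self.lambda3)
        if any(v < 0 for v in vals):
            raise ValueError("loss weights must be nonnegative")
        # L_res always participates, so all-zero lambdas are still a valid
        # (reconstruction-only) objective except in gcn_only mode.


@dataclass
class TrainConfig:
    """Hyperparameters of one training run."""

    n_clusters: int = 3
    learning_rate: float = 1e-4
    weight_decay: float = 1e-15
    epochs: int = 500
    pretrain_epochs: int = 200
    pretrain_lr: float = 1e-3
    p_update_interval: int = 1
    seed: int = 0
    ablation_mode: str = "full"
    encoder_dims: tuple[int, ...] = DEFAULT_ENCODER_DIMS
    epsilon: float = 0.5
    leaky_slope: float = DEFAULT_LEAKY_SLOPE
    delta: float = 1.0
    dtype: str = "float32"  # training precision; the unit-level API is float64

    def __post_init__(self):
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.ablation_mode not in ABLATION_MODES:
            raise ValueError(f"ablation_mode must be one of {ABLATION_MODES}")
        if self.dtype not in ("float32", "float64"):
            raise ValueError("dtype must be 'float32' or 'float64'")
        self.encoder_dims = tuple(self.encoder_dims)


@dataclass
class SmmsnModel:
    """All learnable state of a trained model."""

    sae_states: list[SaeState]
    gcn_states: list[GcnState]
    fusion: FusionState
    head: ClusterHead | None
    config: TrainConfig

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for s in self.sae_states:
            params += s.parameters()
        for g in self.gcn_states:
            params += g.parameters()
        params += self.fusion.parameters()
        if self.head is not None:
            params.append(self.head.centers)
        return params


# --------------------------------------------------------------------------
# objective pieces
# --------------------------------------------------------------------------

def soft_assignment(Z, head: ClusterHead):
    """Student-t soft assignments Q of each sample to each centre.

        q_ij = (1 + ||z_i - mu_j||^2 / delta)^(-(delta+1)/2) , row-normalized.

    Accepts a Tensor (differentiable path) or ndarray; returns the same kind.
    """
    is_tensor = isinstance(Z, Tensor)
    Zt = Z if is_tensor else Tensor(np.asarray(Z, dtype=np.float64))
    mu = head.centers
    if mu.shape[0] < 2:
        raise ValueError("soft assignment needs at least 2 centres")
    zz = (Zt * Zt).sum(axis=1, keepdims=True)            # N x 1
    mm = (mu * mu).sum(axis=1, keepdims=True).T          # 1 x c
    d2 = zz + mm - (Zt @ mu.T) * 2.0
    kernel = (d2 * (1.0 / head.delta) + 1.0) ** (-(head.delta + 1.0) / 2.0)
    Q = kernel / kernel.sum(axis=1, keepdims=True)
    return Q if is_tensor else Q.data


def target_distribution(Q: np.ndarray) -> np.ndarray:
    """Sharpened, frequency-normalized targets:

        p_ij = (q_ij^2 / f_j) / sum_j' (q_ij'^2 / f_j'),  f_j = sum_i q_ij.

    Squaring boosts high-confidence assignments; dividing by the soft cluster
    frequency f_j keeps large clusters from swallowing the targets.
    """
    Q = np.asarray(Q, dtype=np.float64)
    f = Q.sum(axis=0)
    if np.any(f <= 0):
        raise ValueError("empty soft cluster: a column of Q sums to zero")
    weight = Q**2 / f
    return weight / weight.sum(axis=1, keepdims=True)


def kl_divergence(P, R):
    """KL(P || R) = sum_ij p_ij log(p_ij / r_ij) for row-stochastic matrices.

    0 * log(0/r) is treated as 0; r_ij = 0 where p_ij > 0 is an error
    (infinite divergence).  A Tensor ``R`` gives a differentiable scalar with
    P held constant (the self-supervision targets are not back-propagated
    through).
    """
    P = np.asarray(P.data if isinstance(P, Tensor) else P, dtype=np.float64)
    mask = P > 0
    r_data = R.data if isinstance(R, Tensor) else np.asarray(R, dtype=np.float64)
    if np.any(r_data[mask] <= 0):
        raise ValueError("KL divergence is infinite: r_ij = 0 where p_ij > 0")
    logp = np.zeros_like(P)
    logp[mask] = np.log(P[mask])
    if isinstance(R, Tensor):
        # entries with p_ij = 0 contribute nothing; replace r there by 1 so
        # log never sees a (numerically underflowed) zero
        maskf = mask.astype(R.data.dtype)
        R_safe = R * Tensor(maskf) + Tensor(1.0 - maskf)
        return (Tensor(P) * (Tensor(logp) - R_safe.log())).sum()
    return float(np.sum(P[mask] * (logp[mask] - np.log(r_data[mask]))))


def _kl_from_log(P: np.ndarray, logR: Tensor) -> Tensor:
    """KL(P || R) given log R (from a log-softmax); P is a constant target."""
    mask = P > 0
    logp = np.zeros_like(P)
    logp[mask] = np.log(P[mask])
    return (Tensor(P) * (Tensor(logp) - logR)).sum()


def total_loss(parts: dict, w: LossWeights):
    """L = L_res + lambda1 L_fus + lambda2 L_clu + lambda3 L_gcn.

    Absent parts count as zero; a NaN part raises, naming the offender.
    """
    coeff = {"L_res": 1.0, "L_fus": w.lambda1, "L_clu": w.lambda2, "L_gcn": w.lambda3}
    unknown = set(parts) - set(coeff)
    if unknown:
        raise ValueError(f"unknown loss parts: {sorted(unknown)}")
    total = None
    for name, lam in coeff.items():
        part = parts.get(name)
        if part is None:
            continue
        val = part.data if isinstance(part, Tensor) else part
        if not np.isfinite(val):
            raise FloatingPointError(f"loss part {name} is not finite")
        if lam == 0.0:
            continue
        term = part * lam
        total = term if total is None else total + term
    if total is None:  # every present part had zero weight
        total = Tensor(0.0) if any(isinstance(p, Tensor) for p in parts.values()) else 0.0
    return total


def init_centers(Z_fused, c: int, seed: int) -> ClusterHead:
    """K-means centroids of the fused latent as initial cluster centres."""
    Z = np.asarray(Z_fused.data if isinstance(Z_fused, Tensor) else Z_fused)
    if Z.shape[0] < c:
        raise ValueError(f"cannot place {c} centres with only {Z.shape[0]} samples")
    km = KMeans(n_clusters=c, n_init=10, random_state=int(seed) % (2**31))
    km.fit(Z)
    return ClusterHead(centers=Tensor(km.cluster_centers_.astype(np.float64),
                                      requires_grad=True))


def assign_labels(G) -> np.ndarray:
    """y_i = argmax_j g_ij; ties resolve to the lowest index."""
    G = np.asarray(G.data if isinstance(G, Tensor) else G)
    return np.argmax(G, axis=1)


# --------------------------------------------------------------------------
# training loop
# --------------------------------------------------------------------------

def _rowsum_dev(M: np.ndarray) -> float:
    return float(np.abs(M.sum(axis=1) - 1.0).max())


def _pretrain_saes(Xs, sae_states, cfg: TrainConfig) -> list[float]:
    params = [p for s in sae_states for p in s.parameters()]
    opt = Adam(params, lr=cfg.pretrain_lr, weight_decay=cfg.weight_decay)
    losses: list[float] = []
    for _ in range(cfg.pretrain_epochs):
        recon = [sae_forward(x, s)[1] for x, s in zip(Xs, sae_states)]
        loss = reconstruction_loss(Xs, recon)
        opt.zero_grad()
        loss.backward()
        opt.step()
        losses.append(float(loss.data))
    return losses


def _cast_params(states, dtype) -> None:
    for s in states:
        for p in s.parameters():
            p.data = p.data.astype(dtype, copy=False)


def train_smmsn(
    views: list[OmicsView],
    graphs: list[SimilarityGraph],
    cfg: TrainConfig,
    w: LossWeights | None = None,
    truth=None,
    return_model: bool = False,
):
    """Train the full model (or an ablated variant) and cluster the samples.

    Stages: (1) reconstruction-only SAE pretraining; (2) fused-latent and
    centre initialization (mean of per-view latents, then K-means);
    (3) joint training of every parameter on the combined objective with
    Adam, the targets P refreshed every ``p_update_interval`` epochs;
    (4) labels by argmax of the fused probabilities.  Fully deterministic
    for a fixed config and seed.
    """
    w = w or LossWeights()
    mode = cfg.ablation_mode
    if mode == "gcn_only" and w.lambda2 > 0:
        raise ValueError(
            "gcn_only has no fused latent, so lambda2 (the KL(P||Q) weight) "
            "must be 0"
        )
    if mode == "gcn_only" and w.lambda3 == 0:
        raise ValueError("gcn_only requires lambda3 > 0 (its only loss term)")
    if len(views) != len(graphs):
        raise ValueError("need one graph per view")
    n = views[0].n_samples
    if any(v.n_samples != n for v in views):
        raise ValueError("views disagree in sample count")

    ss = np.random.SeedSequence(cfg.seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(2 * len(views))]
    dtype = np.dtype(cfg.dtype)
    Xs = [v.X.astype(dtype, copy=False) for v in views]
    As = [g.A_norm.astype(dtype, copy=False) for g in graphs]

    use_sae = mode in ("full", "sae_only")
    use_gcn = mode in ("full", "gcn_only")

    sae_states = [
        init_sae(v.n_features, cfg.encoder_dims, rngs[i], cfg.leaky_slope)
        for i, v in enumerate(views)
    ] if use_sae else []
    gcn_states = [
        init_gcn(v.n_features, cfg.n_clusters, cfg.encoder_dims,
                 rngs[len(views) + i], cfg.epsilon, cfg.leaky_slope)
        for i, v in enumerate(views)
    ] if use_gcn else []
    _cast_params(sae_states, dtype)
    _cast_params(gcn_states, dtype)

    head = None
    fusion = FusionState()
    pre_losses: list[float] = []
    if use_sae:
        pre_losses = _pretrain_saes(Xs, sae_states, cfg)
        latents0 = [sae_forward(x, s)[0][-1].data
                    for x, s in zip(Xs, sae_states)]
        fusion.Z_fused = init_fused_latent(latents0)
        fusion.Z_fused.data = fusion.Z_fused.data.astype(dtype, copy=False)
        head = ClusterHead(centers=init_centers(fusion.Z_fused, cfg.n_clusters,
                                                cfg.seed).centers,
                           delta=cfg.delta)
        head.centers.data = head.centers.data.astype(dtype, copy=False)
    if use_gcn:
        fusion.W_fusion = init_fusion_weights(len(views), cfg.n_clusters)
        fusion.W_fusion.data = fusion.W_fusion.data.astype(dtype, copy=False)

    model = SmmsnModel(sae_states=sae_states, gcn_states=gcn_states,
                       fusion=fusion, head=head, config=cfg)
    opt = Adam(model.parameters(), lr=cfg.learning_rate,
               weight_decay=cfg.weight_decay)

    P: np.ndarray | None = None
    trace: list[dict] = []

    def forward():
        """One full forward pass; returns (parts, Q, G, logG)."""
        parts: dict = {}
        latents = None
        Q = None
        G = None
        logG = None
        if use_sae:
            recon = []
            latents = []
            for x, s in zip(Xs, sae_states):
                zs, xhat = sae_forward(x, s)
                latents.append(zs)
                recon.append(xhat)
            parts["L_res"] = reconstruction_loss(Xs, recon)
            parts["L_fus"] = fusion_reconstruction_loss(
                fusion.Z_fused, [zs[-1] for zs in latents])
            Q = soft_assignment(fusion.Z_fused, head)
        if use_gcn:
            logits = [
                gcn_forward(a, x, latents[i] if (use_sae and mode == "full") else None,
                            gcn_states[i])
                for i, (x, a) in enumerate(zip(Xs, As))
            ]
            G, logG = adaptive_fusion(logits, fusion, return_log=True)
        return parts, Q, G, logG

    for epoch in range(cfg.epochs):
        parts, Q, G, logG = forward()
        if epoch % cfg.p_update_interval == 0:
            if Q is not None:
                source = Q.data.astype(np.float64)
            else:  # gcn_only: exact probabilities from the log-softmax
                source = np.exp(logG.data.astype(np.float64))
            P = target_distribution(source).astype(dtype, copy=False)
        if Q is not None and w.lambda2 > 0:
            parts["L_clu"] = kl_divergence(P, Q)
        if G is not None and w.lambda3 > 0:
            parts["L_gcn"] = _kl_from_log(P, logG)
        loss = total_loss(parts, w)
        opt.zero_grad()
        loss.backward()
        opt.step()
        rec = {"epoch": epoch, "total": float(loss.data)}
        rec.update({k: float(v.data) for k, v in parts.items()})
        rec["p_rowsum_dev"] = _rowsum_dev(P)
        if Q is not None:
            rec["q_rowsum_dev"] = _rowsum_dev(Q.data)
        if G is not None:
            rec["g_rowsum_dev"] = _rowsum_dev(G.data)
        trace.append(rec)

    _, Q, G, _ = forward()
    final = G if G is not None else Q
    labels = assign_labels(final)

    result = ClusteringResult(
        labels=labels,
        samples=list(views[0].samples),
        acc=None if truth is None else clustering_accuracy(truth, labels),
        loss_trace=trace,
        pretrain_trace=pre_losses,
        config_echo={**dataclasses.asdict(cfg),
                     "loss_weights": dataclasses.asdict(w)},
    )
    return (result, model) if return_model else result
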