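"""Preprocessing of multi-omics matrices and patient-similarity KNN graphs.

Each omics view is a samples x features real matrix measured on the same
ordered patient set.  Preprocessing (1) drops patients and then features with
more than 20% missing entries and mean-imputes the remainder, (2) standardizes
every feature column, (3) builds a heat-kernel similarity matrix, and
(4) derives a symmetric binary K-nearest-neighbour graph whose self-looped,
symmetrically normalized adjacency feeds the graph-convolution branch.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

__all__ = [
    "OmicsView",
    "SimilarityGraph",
    "PreprocessConfig",
    "filter_missing",
    "normalize_features",
    "heat_kernel_similarity",
    "build_knn_graph",
    "normalize_adjacency",
    "preprocess_views",
]


@dataclass
class OmicsView:
    """One omics modality: N samples x m_v features with aligned sample IDs."""

    name: str
    samples: list[str]
    features: list[str]
    X: np.ndarray

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.shape != (len(self.samples), len(self.features)):
            raise ValueError(
                f"view {self.name!r}: matrix shape {self.X.shape} does not match "
                f"{len(self.samples)} samples x {len(self.features)} features"
            )

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


@dataclass
class SimilarityGraph:
    """Heat-kernel similarity S, binary KNN adjacency A, and normalized A."""

    S: np.ndarray
    A: np.ndarray
    A_norm: np.ndarray


@dataclass
class PreprocessConfig:
    patient_missing_threshold: float = 0.20
    feature_missing_threshold: float = 0.20
    k_neighbors: int = 40
    sigma_mode: str = "median_sq_dist"
    sigma_value: float | None = None

    def __post_init__(self):
        for thr in (self.patient_missing_threshold, self.feature_missing_threshold):
            if not 0.0 < thr < 1.0:
                raise ValueError("missing-fraction thresholds must lie in (0, 1)")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.sigma_mode not in ("median_sq_dist", "fixed"):
            raise ValueError(f"unknown sigma_mode {self.sigma_mode!r}")
        if self.sigma_mode == "fixed" and (
            self.sigma_value is None or self.sigma_value <= 0
        ):
            raise ValueError("fixed sigma_mode requires a positive sigma_value")


def filter_missing(
    view: OmicsView, cfg: PreprocessConfig | None = None
) -> tuple[OmicsView, dict]:
    """Drop samples then features with too much missingness; impute the rest.

    Samples whose missing fraction strictly exceeds the patient threshold are
    removed first; features whose missing fraction over the *remaining*
    samples strictly exceeds the feature threshold are removed next.  Any
    residual gaps are filled with the feature mean over observed values.

    Returns the filtered view and a report dict with the dropped IDs.
    """
    cfg = cfg or PreprocessConfig()
    X = np.asarray(view.X, dtype=np.float64)
    miss = np.isnan(X)

    sample_frac = miss.mean(axis=1)
    keep_s = sample_frac <= cfg.patient_missing_threshold
    dropped_samples = [s for s, k in zip(view.samples, keep_s) if not k]
    if not keep_s.any():
        raise ValueError(f"view {view.name!r}: all samples exceed the missing threshold")

    X = X[keep_s]
    feat_frac = np.isnan(X).mean(axis=0)
    keep_f = feat_frac <= cfg.feature_missing_threshold
    dropped_features = [f for f, k in zip(view.features, keep_f) if not k]
    if not keep_f.any():
        raise ValueError(f"view {view.name!r}: all features exceed the missing threshold")

    X = X[:, keep_f]
    # mean-impute residual gaps feature by feature
    if np.isnan(X).any():
        col_mean = np.nanmean(X, axis=0)
        idx = np.where(np.isnan(X))
        X[idx] = col_mean[idx[1]]

    out = OmicsView(
        name=view.name,
        samples=[s for s, k in zip(view.samples, keep_s) if k],
        features=[f for f, k in zip(view.features, keep_f) if k],
        X=X,
    )
    report = {
        "view": view.name,
        "dropped_samples": dropped_samples,
        "dropped_features": dropped_features,
        "n_samples": out.n_samples,
        "n_features": out.n_features,
    }
    if dropped_samples or dropped_features:
        logger.info(
            "view %s: dropped %d samples, %d features by missingness",
            view.name, len(dropped_samples), len(dropped_features),
        )
    return out, report


def normalize_features(view: OmicsView) -> OmicsView:
    """Standardize each feature to mean 0 and unit population SD.

    Constant (zero-variance) columns cannot be scaled and are dropped with a
    warning so downstream code never sees degenerate features.
    """
    X = np.asarray(view.X, dtype=np.float64)
    if np.isnan(X).any():
        raise ValueError(f"view {view.name!r}: missing values present; filter first")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # population SD (ddof=0)
    keep = sd > 0
    if not keep.all():
        dropped = [f for f, k in zip(view.features, keep) if not k]
        warnings.warn(
            f"view {view.name!r}: dropping {len(dropped)} zero-variance feature(s)",
            stacklevel=2,
        )
    Xn = (X[:, keep] - mean[keep]) / sd[keep]
    return OmicsView(
        name=view.name,
        samples=list(view.samples),
        features=[f for f, k in zip(view.features, keep) if k],
        X=Xn,
    )


def resolve_sigma(X: np.ndarray, cfg: PreprocessConfig) -> float:
    """Heat-kernel bandwidth: fixed, or the median pairwise squared distance."""
    if cfg.sigma_mode == "fixed":
        return float(cfg.sigma_value)
    sq = pdist(X, metric="sqeuclidean")
    sigma = float(np.median(sq))
    if sigma <= 0:
        raise ValueError("degenerate data: median pairwise squared distance is 0")
    return sigma


def heat_kernel_similarity(
    view: OmicsView, cfg: PreprocessConfig | None = None
) -> np.ndarray:
    """S[i,j] = exp(-||x_i - x_j||^2 / sigma): symmetric, unit diagonal."""
    cfg = cfg or PreprocessConfig()
    sigma = resolve_sigma(view.X, cfg)
    if sigma <= 0:
        raise ValueError("heat kernel parameter sigma must be positive")
    sq = squareform(pdist(view.X, metric="sqeuclidean"))
    S = np.exp(-sq / sigma)
    np.fill_diagonal(S, 1.0)
    return (S + S.T) / 2.0


def build_knn_graph(S: np.ndarray, cfg: PreprocessConfig | None = None) -> SimilarityGraph:
    """Binary KNN adjacency from a similarity matrix, symmetrized by union.

    Each sample selects its K most similar *other* samples; A := max(A, A^T)
    then makes every edge mutual.  K is clamped to N-1 when it exceeds it.
    """
    cfg = cfg or PreprocessConfig()
    S = np.asarray(S, dtype=np.float64)
    n = S.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples to build a KNN graph")
    k = cfg.k_neighbors
    if k >= n:
        logger.warning("k_neighbors=%d >= N=%d; clamping to N-1", k, n)
        k = n - 1
    masked = S.copy()
    np.fill_diagonal(masked, -np.inf)  # the sample itself is never a neighbour
    # argsort is stable, so equal similarities resolve to the lowest index
    order = np.argsort(-masked, axis=1, kind="stable")[:, :k]
    A = np.zeros((n, n))
    A[np.repeat(np.arange(n), k), order.ravel()] = 1.0
    A = np.maximum(A, A.T)
    np.fill_diagonal(A, 0.0)
    return SimilarityGraph(S=S, A=A, A_norm=normalize_adjacency(A))


def normalize_adjacency(A: np.ndarray) -> np.ndarray:
    """Symmetric normalization D^{-1/2} (A + I) D^{-1/2} with self-loops."""
    A = np.asarray(A, dtype=np.float64)
    A_hat = A + np.eye(A.shape[0])
    d_inv_sqrt = 1.0 / np.sqrt(A_hat.sum(axis=1))  # degree >= 1 after self-loop
    return A_hat * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def align_views(views: list[OmicsView]) -> list[OmicsView]:
    """Restrict all views to the intersection of their sample sets, in the
    order of the first view, so matrices stay row-aligned."""
    common = set(views[0].samples)
    for v in views[1:]:
        common &= set(v.samples)
    if not common:
        raise ValueError("views share no samples after filtering")
    order = [s for s in views[0].samples if s in common]
    out = []
    for v in views:
        pos = {s: i for i, s in enumerate(v.samples)}
        idx = [pos[s] for s in order]
        out.append(OmicsView(v.name, list(order), list(v.features), v.X[idx]))
    return out


def preprocess_views(
    views: list[OmicsView], cfg: PreprocessConfig | None = None
) -> tuple[list[OmicsView], list[SimilarityGraph], dict]:
    """Full pipeline: missingness filters, sample alignment, standardization,
    heat-kernel similarity and normalized KNN graph per view.

    Returns (views, graphs, report); the report is JSON-serializable.
    """
    cfg = cfg or PreprocessConfig()
    filtered, reports = [], []
    for v in views:
        fv, rep = filter_missing(v, cfg)
        filtered.append(fv)
        reports.append(rep)
    aligned = align_views(filtered)
    out_views, graphs = [], []
    for v, rep in zip(aligned, reports):
        nv = normalize_features(v)
        sigma = resolve_sigma(nv.X, cfg)
        S = heat_kernel_similarity(nv, cfg)
        graphs.append(build_knn_graph(S, cfg))
        out_views.append(nv)
        rep.update(n_samples=nv.n_samples, n_features=nv.n_features, sigma=sigma)
    report = {"views": reports, "n_samples": out_views[0].n_samples,
              "k_neighbors": min(cfg.k_neighbors, out_views[0].n_samples - 1)}
    return out_views, graphs, report
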