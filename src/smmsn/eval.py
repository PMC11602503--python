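"""Clustering evaluation: mapped accuracy and companion indices.

Mapped clustering accuracy (ACC) relabels predicted clusters by the
one-to-one mapping to true classes that maximizes agreement,

    ACC = (1/n) * max_map  sum_i  1[t_i == map(y_i)],

found by optimal assignment (Hungarian algorithm) on the contingency table.
Adjusted Rand index and normalized mutual information are reported alongside
as permutation-free diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

__all__ = ["ClusteringResult", "clustering_accuracy", "evaluate_run"]

_MAX_CLASSES = 64


@dataclass
class ClusteringResult:
    """Output of one training run: labels plus diagnostics."""

    labels: np.ndarray
    samples: list[str] = field(default_factory=list)
    acc: float | None = None
    loss_trace: list[dict] = field(default_factory=list)
    pretrain_trace: list[float] = field(default_factory=list)
    config_echo: dict = field(default_factory=dict)


def _contingency(truth: np.ndarray, pred: np.ndarray) -> np.ndarray:
    t_vals, t_idx = np.unique(truth, return_inverse=True)
    p_vals, p_idx = np.unique(pred, return_inverse=True)
    table = np.zeros((len(t_vals), len(p_vals)), dtype=np.int64)
    np.add.at(table, (t_idx, p_idx), 1)
    return table


def clustering_accuracy(truth, pred) -> float:
    """Accuracy under the optimal one-to-one cluster-to-class mapping.

    The contingency table is implicitly padded with zero-count rows/columns
    when the numbers of classes differ, so unmatched clusters simply score 0.
    """
    truth = np.asarray(truth).ravel()
    pred = np.asarray(pred).ravel()
    if truth.shape != pred.shape:
        raise ValueError(f"length mismatch: {truth.shape[0]} vs {pred.shape[0]}")
    if truth.size == 0:
        raise ValueError("empty label vectors")
    table = _contingency(truth, pred)
    if max(table.shape) > _MAX_CLASSES:
        raise ValueError(f"more than {_MAX_CLASSES} distinct labels")
    rows, cols = linear_sum_assignment(table, maximize=True)
    return float(table[rows, cols].sum() / truth.size)


def evaluate_run(result: ClusteringResult, truth) -> dict:
    """Metrics report for one run against ground truth.

    ``truth`` is either a plain label vector aligned with ``result.labels``
    or a mapping / pandas Series keyed by sample ID.  ACC is the headline
    number; ARI and NMI are auxiliary diagnostics.
    """
    pred = np.asarray(result.labels)
    if hasattr(truth, "keys"):  # dict-like or Series: align by sample ID
        if not result.samples:
            raise ValueError("result carries no sample IDs to align on")
        missing = [s for s in result.samples if s not in truth]
        if missing:
            raise ValueError(f"sample IDs missing from truth: {missing[:10]}")
        t = np.asarray([truth[s] for s in result.samples])
    else:
        t = np.asarray(truth).ravel()
    report = {
        "acc": clustering_accuracy(t, pred),
        "ari": float(adjusted_rand_score(t, pred)),
        "nmi": float(normalized_mutual_info_score(t, pred)),
        "n_samples": int(pred.size),
        "n_clusters_pred": int(len(np.unique(pred))),
    }
    for key in ("n_clusters", "seed", "ablation_mode"):
        if key in result.config_echo:
            report[key] = result.config_echo[key]
    return report
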