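"""Recurring connectivity states: pooled k-means and system segregation.

All subjects' windowed matrices are vectorized (upper triangle, diagonal
excluded) and clustered with k = 2 under city-block distance. The centroid
with the higher system segregation,

    segregation = 1 - mean(between-network edges) / mean(within-network edges),

is labelled ``segregated``, the other ``integrated``; per-window state
prevalence is the fraction of subjects assigned to each state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .containers import NetworkAtlas
from .windows import WindowedFC

logger = logging.getLogger(__name__)

__all__ = ["StateModel", "StatePrevalence", "cluster_states",
           "system_segregation", "label_and_prevalence", "silhouette_by_k"]


@dataclass
class StateModel:
    """Fitted k-means solution over pooled (subject, window) matrices."""

    k: int
    centroids: np.ndarray                  # k x n_features (upper-triangle vectors)
    assignment: pd.DataFrame               # columns: subject_id, window, state
    n_nodes: int
    cost: float                            # total city-block distance
    replicates: int
    seed: int

    def centroid_matrix(self, state: int) -> np.ndarray:
        """Reconstruct the symmetric ``nodes x nodes`` centroid of one state."""
        m = np.zeros((self.n_nodes, self.n_nodes))
        iu = np.triu_indices(self.n_nodes, k=1)
        m[iu] = self.centroids[state]
        return m + m.T


@dataclass
class StatePrevalence:
    """Per-window occupation frequency of the labelled states."""

    prevalence: pd.DataFrame               # columns: window, integrated, segregated
    state_labels: dict[int, str]           # cluster id -> label
    centroid_segregation: dict[int, float]


def _vectorize(stacks: list[WindowedFC]) -> tuple[np.ndarray, pd.DataFrame, int]:
    n_nodes = stacks[0].n_nodes
    iu = np.triu_indices(n_nodes, k=1)
    rows, meta = [], []
    for fc in stacks:
        if fc.n_nodes != n_nodes:
            raise ValueError("all subjects must share the node dimension")
        for wi in range(fc.n_windows):
            rows.append(fc.matrices[wi][iu])
            meta.append((fc.subject_id, wi))
    X = np.asarray(rows)
    meta_df = pd.DataFrame(meta, columns=["subject_id", "window"])
    return X, meta_df, n_nodes


def _kmeans_cityblock(X: np.ndarray, k: int, rng: np.random.Generator,
                      max_iter: int = 300) -> tuple[np.ndarray, np.ndarray, float]:
    n = X.shape[0]
    centroids = X[rng.choice(n, size=k, replace=False)].copy()
    labels = np.full(n, -1)
    for _ in range(max_iter):
        D = cdist(X, centroids, metric="cityblock")
        new_labels = D.argmin(axis=1)
        # empty cluster: re-seed at the point farthest from its centroid
        for c in range(k):
            if not (new_labels == c).any():
                far = D[np.arange(n), new_labels].argmax()
                centroids[c] = X[far]
                new_labels[far] = c
        if (new_labels == labels).all():
            break
        labels = new_labels
        for c in range(k):
            centroids[c] = X[labels == c].mean(axis=0)
    D = cdist(X, centroids, metric="cityblock")
    labels = D.argmin(axis=1)
    cost = float(D[np.arange(n), labels].sum())
    return labels, centroids, cost


def cluster_states(stacks: list[WindowedFC], k: int = 2, replicates: int = 10,
                   seed: int = 0) -> StateModel:
    """Pool all subjects' windowed matrices and cluster them into ``k`` states.

    Best of ``replicates`` random restarts by total city-block cost (ties
    broken by the lowest replicate index); centroids are member means.
    """
    if not stacks:
        raise ValueError("no windowed matrices given")
    X, meta, n_nodes = _vectorize(stacks)
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds the {X.shape[0]} available matrices")
    if k == 1:
        labels = np.zeros(X.shape[0], dtype=int)
        centroids = X.mean(axis=0, keepdims=True)
        cost = float(cdist(X, centroids, metric="cityblock").sum())
        best = labels, centroids, cost
    else:
        rng = np.random.default_rng(seed)
        best = None
        for _ in range(replicates):
            labels, centroids, cost = _kmeans_cityblock(X, k, rng)
            if best is None or cost < best[2] - 1e-12:
                best = (labels, centroids, cost)
    meta = meta.assign(state=best[0])
    return StateModel(k, best[1], meta, n_nodes, best[2], replicates, seed)


def system_segregation(W: np.ndarray, atlas: NetworkAtlas) -> float:
    """``1 - mean(between-network edge) / mean(within-network edge)``.

    The diagonal is excluded. Returns NaN (logged) when the mean
    within-network strength is zero.
    """
    W = np.asarray(W, float)
    labels = atlas.labels()
    if W.shape != (len(labels), len(labels)):
        raise ValueError("matrix does not match atlas size")
    same = labels[:, None] == labels[None, :]
    off = ~np.eye(len(labels), dtype=bool)
    zw = W[same & off].mean()
    zb = W[~same].mean()
    if zw == 0:
        logger.warning("system segregation undefined: zero mean within-network strength")
        return float("nan")
    return float(1.0 - zb / zw)


def label_and_prevalence(model: StateModel, atlas: NetworkAtlas) -> StatePrevalence:
    """Label clusters by centroid segregation and compute per-window prevalence."""
    seg = {c: system_segregation(model.centroid_matrix(c), atlas) for c in range(model.k)}
    if model.k == 2 and seg[0] == seg[1]:
        raise ValueError("centroid segregation tie: states must be labelled manually")
    order = sorted(seg, key=seg.get)
    labels = {c: "integrated" for c in order[:-1]}
    labels[order[-1]] = "segregated"
    asg = model.assignment
    rows = []
    for w, grp in asg.groupby("window"):
        counts = grp["state"].value_counts()
        integrated = sum(counts.get(c, 0) for c, lab in labels.items() if lab == "integrated")
        segregated = sum(counts.get(c, 0) for c, lab in labels.items() if lab == "segregated")
        total = integrated + segregated
        rows.append((w, integrated / total, segregated / total))
    prev = pd.DataFrame(rows, columns=["window", "integrated", "segregated"])
    return StatePrevalence(prev, labels, seg)


def silhouette_by_k(stacks: list[WindowedFC], k_values: tuple[int, ...] = (2, 3, 4),
                    seed: int = 0) -> pd.DataFrame:
    """Mean city-block silhouette for alternative k (diagnostic, not the main path)."""
    X, _, _ = _vectorize(stacks)
    out = []
    for k in k_values:
        _, centroids, _ = _kmeans_cityblock(X, k, np.random.default_rng(seed))
        D = cdist(X, centroids, metric="cityblock")
        part = np.partition(D, 1, axis=1)
        a, b = part[:, 0], part[:, 1]
        out.append((k, float(np.mean((b - a) / np.maximum(a, b)))))
    return pd.DataFrame(out, columns=["k", "silhouette"])
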