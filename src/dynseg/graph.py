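"""Signed weighted community detection and node cartography.

Community structure is found by Louvain optimization of the signed quality
function with asymmetric positive/negative weighting: writing W+ and W- for
the positive and negative parts of the connectivity matrix, with total
weights v+ and v-, the objective is

    Q = Q+ / v+  -  Q- / (v+ + v-),

where Q± are Newman-Girvan modularity sums computed separately on W+ and
W- (resolution ``gamma`` scales the degree null model). Positive weight is
thereby dominant: the penalty for clustering negative edges is damped by the
total weight, the recommended default for signed functional connectivity.
For a purely positive matrix the objective reduces exactly to weighted
Newman-Girvan modularity.

Node roles are summarized by the participation coefficient (PC, between-
module strength distribution) and the module-degree Z score (MDZ, z-scored
within-module strength), both computed on positive weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import NetworkAtlas

logger = logging.getLogger(__name__)

__all__ = ["Partition", "signed_modularity_matrix", "modularity_q",
           "louvain_signed", "consensus_partition", "node_cartography",
           "network_summarize"]


@dataclass(frozen=True)
class Partition:
    """Node-to-module assignment with its modularity value."""

    modules: np.ndarray      # 1-based contiguous module id per node
    q: float
    gamma: float = 1.0
    variant: str = "signed_asymmetric"
    n_runs: int = 1

    @property
    def n_modules(self) -> int:
        return int(self.modules.max())

    def __post_init__(self) -> None:
        m = np.asarray(self.modules)
        if m.size and sorted(set(m.tolist())) != list(range(1, int(m.max()) + 1)):
            raise ValueError("module ids must be contiguous from 1")


def _check_matrix(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("W must be square")
    if not np.allclose(W, W.T, atol=1e-10):
        raise ValueError("W must be symmetric")
    if np.abs(np.diag(W)).max(initial=0.0) > 1e-12:
        raise ValueError("W must have a zero diagonal")
    return W


def signed_modularity_matrix(W: np.ndarray, gamma: float = 1.0) -> np.ndarray:
    """Dense modularity matrix B of the signed-asymmetric quality function.

    Q of a partition is the sum of B over all within-module node pairs
    (self-pairs included; the diagonal of W is zero).
    """
    W = _check_matrix(W)
    Wp = np.clip(W, 0.0, None)
    Wn = np.clip(-W, 0.0, None)
    sp, sn = Wp.sum(), Wn.sum()
    B = np.zeros_like(W)
    if sp > 0:
        kp = Wp.sum(axis=1)
        B += (Wp - gamma * np.outer(kp, kp) / sp) / sp
    if sn > 0:
        kn = Wn.sum(axis=1)
        B -= (Wn - gamma * np.outer(kn, kn) / sn) / (sp + sn)
    return B


def modularity_q(W: np.ndarray, modules: np.ndarray, gamma: float = 1.0) -> float:
    """Evaluate the signed-asymmetric Q of an arbitrary partition."""
    B = signed_modularity_matrix(W, gamma)
    modules = np.asarray(modules)
    q = 0.0
    for m in np.unique(modules):
        idx = np.flatnonzero(modules == m)
        q += B[np.ix_(idx, idx)].sum()
    return float(q)


def _relabel(modules: np.ndarray) -> np.ndarray:
    """Make module ids contiguous from 1, ordered by first appearance."""
    out = np.empty_like(modules)
    mapping: dict[int, int] = {}
    for i, m in enumerate(modules):
        mapping.setdefault(int(m), len(mapping) + 1)
        out[i] = mapping[int(m)]
    return out


def _louvain_on_b(B: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Two-phase greedy Louvain on a dense (aggregated) modularity matrix."""
    n = B.shape[0]
    comm = np.arange(n)
    mapping = np.arange(n)          # original node -> current super-node
    while True:
        # phase 1: local node moves
        improved = False
        while True:
            moved = False
            for i in rng.permutation(n):
                ci = comm[i]
                gains = np.bincount(comm, weights=B[i], minlength=n)
                gains[ci] -= B[i, i]
                best = int(gains.argmax())
                if gains[best] > gains[ci] + 1e-12:
                    comm[i] = best
                    moved = improved = True
            if not moved:
                break
        ids, comm = np.unique(comm, return_inverse=True)
        if not improved or len(ids) == n:
            return _relabel(comm[mapping])
        # phase 2: aggregate communities into super-nodes
        k = len(ids)
        H = np.zeros((n, k))
        H[np.arange(n), comm] = 1.0
        B = H.T @ B @ H
        mapping = comm[mapping]
        n = k
        comm = np.arange(n)


def louvain_signed(W: np.ndarray, gamma: float = 1.0,
                   seed: int | np.random.Generator = 0) -> Partition:
    """One Louvain optimization of the signed-asymmetric quality function."""
    W = _check_matrix(W)
    n = W.shape[0]
    if not np.any(W):
        return Partition(np.ones(n, dtype=int), 0.0, gamma)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    B = signed_modularity_matrix(W, gamma)
    modules = _louvain_on_b(B.copy(), rng)
    return Partition(modules, modularity_q(W, modules, gamma), gamma)


def _best_of(W: np.ndarray, gamma: float, rng: np.random.Generator,
             n_runs: int) -> tuple[list[np.ndarray], Partition]:
    runs: list[np.ndarray] = []
    best: Partition | None = None
    for _ in range(n_runs):
        p = louvain_signed(W, gamma, rng)
        runs.append(p.modules)
        if best is None or p.q > best.q:
            best = p
    return runs, best


def consensus_partition(W: np.ndarray, n_runs: int = 500, tau: float = 0.5,
                        gamma: float = 1.0, seed: int | np.random.Generator = 0,
                        max_consensus_iter: int = 100) -> Partition:
    """Consensus community structure over ``n_runs`` Louvain restarts.

    The co-assignment (agreement) matrix of the runs is thresholded at
    ``tau`` and re-clustered, iterating until all runs agree. Falls back to
    the best single run, with a logged warning, if consensus does not
    converge.
    """
    W = _check_matrix(W)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    runs, best = _best_of(W, gamma, rng, n_runs)
    for _ in range(max_consensus_iter):
        stacked = np.stack(runs)
        if all((r == runs[0]).all() for r in runs[1:]):
            modules = _relabel(runs[0])
            return Partition(modules, modularity_q(W, modules, gamma), gamma,
                             n_runs=n_runs)
        A = np.mean(stacked[:, :, None] == stacked[:, None, :], axis=0)
        A[A < tau] = 0.0
        np.fill_diagonal(A, 0.0)
        if not np.any(A):
            break
        runs, _ = _best_of(A, 1.0, rng, max(len(runs), 2))
    logger.warning("consensus did not converge; returning best single run")
    return Partition(_relabel(best.modules), best.q, gamma, n_runs=n_runs)


def node_cartography(W: np.ndarray, partition: Partition) -> pd.DataFrame:
    """Participation coefficient and module-degree Z per node (positive weights).

    ``PC_i = 1 - sum_s (k_is / k_i)^2`` over modules ``s``; isolated nodes
    (zero positive strength) get PC 0 with a warning. MDZ is the z score of
    a node's within-module strength within its module; a zero-variance
    module yields MDZ 0 for its nodes.
    """
    W = _check_matrix(W)
    modules = np.asarray(partition.modules)
    if len(modules) != W.shape[0]:
        raise ValueError("partition does not cover all nodes")
    Wp = np.clip(W, 0.0, None)
    k = Wp.sum(axis=1)
    n = len(k)
    uniq = np.unique(modules)
    k_im = np.stack([Wp[:, modules == m].sum(axis=1) for m in uniq], axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = k_im / k[:, None]
    pc = 1.0 - np.sum(frac**2, axis=1)
    isolated = k == 0
    if isolated.any():
        logger.warning("%d isolated node(s): PC set to 0", int(isolated.sum()))
        pc[isolated] = 0.0
    within = k_im[np.arange(n), np.searchsorted(uniq, modules)]
    mdz = np.zeros(n)
    for m in uniq:
        idx = modules == m
        mu, sd = within[idx].mean(), within[idx].std()
        if sd > 0:
            mdz[idx] = (within[idx] - mu) / sd
    return pd.DataFrame({"node": np.arange(n), "module": modules,
                         "pc": pc, "mdz": mdz})


def network_summarize(cartography: pd.DataFrame, atlas: NetworkAtlas) -> pd.DataFrame:
    """Mean PC and MDZ within each a-priori network."""
    if len(cartography) != atlas.n_nodes:
        raise ValueError("cartography does not match atlas size")
    labels = atlas.labels()
    nets = atlas.networks
    rows = []
    for i, net in enumerate(nets):
        idx = labels == i
        if not idx.any():
            logger.warning("network %s has no nodes; summary flagged missing", net)
            rows.append((net, float("nan"), float("nan")))
            continue
        rows.append((net, float(cartography["pc"].to_numpy()[idx].mean()),
                     float(cartography["mdz"].to_numpy()[idx].mean())))
    return pd.DataFrame(rows, columns=["network", "mean_pc", "mean_mdz"])
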