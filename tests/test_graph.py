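"""Signed Louvain, consensus partitioning, and node cartography."""

import numpy as np
import pytest

from dynseg.graph import (Partition, consensus_partition, louvain_signed,
                          modularity_q, network_summarize, node_cartography)
from dynseg.containers import NetworkAtlas

from conftest import block_matrix


def reference_signed_q(W: np.ndarray, modules: np.ndarray, gamma: float = 1.0) -> float:
    """Independent evaluation of the signed-asymmetric quality function."""
    Wp = np.where(W > 0, W, 0.0)
    Wn = np.where(W < 0, -W, 0.0)
    sp, sn = Wp.sum(), Wn.sum()
    delta = modules[:, None] == modules[None, :]
    q = 0.0
    if sp > 0:
        kp = Wp.sum(1)
        q += ((Wp - gamma * np.outer(kp, kp) / sp)[delta]).sum() / sp
    if sn > 0:
        kn = Wn.sum(1)
        q -= ((Wn - gamma * np.outer(kn, kn) / sn)[delta]).sum() / (sp + sn)
    return q


def all_partitions(n: int):
    """Every set partition of range(n) as a label vector (restricted growth)."""
    labels = np.zeros(n, dtype=int)

    def rec(i: int, maxlab: int):
        if i == n:
            yield labels.copy()
            return
        for lab in range(maxlab + 2):
            labels[i] = lab
            yield from rec(i + 1, max(maxlab, lab))

    yield from rec(1, 0)


def two_k3() -> np.ndarray:
    W = np.zeros((6, 6))
    for a, b in [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)]:
        W[a, b] = W[b, a] = 1.0
    return W


class TestLouvainSigned:
    def test_two_disjoint_cliques_closed_form(self):
        part = louvain_signed(two_k3(), seed=0)
        assert part.q == pytest.approx(0.5, abs=1e-12)
        assert part.n_modules == 2
        assert len(set(part.modules[:3])) == 1 and len(set(part.modules[3:])) == 1

    def test_uniform_complete_graph_null_model(self):
        W = np.ones((6, 6)) - np.eye(6)
        # single-module partition sits exactly at the null expectation
        assert modularity_q(W, np.ones(6, dtype=int)) == pytest.approx(0.0, abs=1e-12)
        assert louvain_signed(W, seed=0).q <= 1e-12

    def test_all_zero_matrix(self):
        part = louvain_signed(np.zeros((5, 5)))
        assert part.q == 0.0 and part.n_modules == 1

    def test_positive_only_reduces_to_newman_girvan(self, rng):
        for _ in range(20):
            n = 9
            W = rng.random((n, n))
            W = (W + W.T) / 2
            np.fill_diagonal(W, 0.0)
            modules = rng.integers(1, 4, n)
            k = W.sum(1)
            m2 = W.sum()
            q_ng = sum(W[np.ix_(modules == c, modules == c)].sum() / m2
                       - (k[modules == c].sum() / m2) ** 2
                       for c in np.unique(modules))
            assert modularity_q(W, modules) == pytest.approx(q_ng, abs=1e-12)

    def test_q_invariant_to_node_permutation_and_relabelling(self, rng):
        W = rng.standard_normal((10, 10))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0.0)
        modules = rng.integers(1, 4, 10)
        q = modularity_q(W, modules)
        perm = rng.permutation(10)
        assert modularity_q(W[np.ix_(perm, perm)], modules[perm]) == pytest.approx(q, abs=1e-12)
        relabel = np.array([5, 9, 2, 7])[modules]
        assert modularity_q(W, relabel) == pytest.approx(q, abs=1e-12)

    def test_matches_exhaustive_enumeration_on_small_signed_graphs(self, rng):
        hits = 0
        n_graphs = 15
        for _ in range(n_graphs):
            n = int(rng.integers(5, 8))
            W = rng.standard_normal((n, n))
            W = (W + W.T) / 2
            np.fill_diagonal(W, 0.0)
            best_q = max(reference_signed_q(W, p) for p in all_partitions(n))
            found = max(louvain_signed(W, seed=rng).q for _ in range(50))
            assert found <= best_q + 1e-9
            hits += found >= best_q - 1e-9
        assert hits >= 0.9 * n_graphs

    def test_deterministic_given_seed(self, rng):
        W = rng.standard_normal((12, 12))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0.0)
        a = louvain_signed(W, seed=42)
        b = louvain_signed(W, seed=42)
        assert a.q == b.q and (a.modules == b.modules).all()


class TestConsensus:
    def test_unambiguous_structure_matches_every_run(self):
        W = two_k3()
        cons = consensus_partition(W, n_runs=25, seed=1)
        single = louvain_signed(W, seed=7)
        assert cons.q == pytest.approx(single.q, abs=1e-12)
        assert (cons.modules == Partition(single.modules, single.q).modules).all()

    def test_single_run_degenerates_to_louvain(self, rng):
        W = rng.standard_normal((10, 10))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0.0)
        cons = consensus_partition(W, n_runs=1, seed=5)
        direct = louvain_signed(W, seed=np.random.default_rng(5))
        assert cons.q == pytest.approx(direct.q, abs=1e-12)

    def test_consensus_at_least_median_run(self, rng):
        labels = np.repeat([0, 1, 2], 6)
        W = block_matrix(labels, 0.8, -0.1) + 0.3 * rng.standard_normal((18, 18))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0.0)
        runs = [louvain_signed(W, seed=rng).q for _ in range(20)]
        cons = consensus_partition(W, n_runs=20, seed=3)
        assert cons.q >= np.median(runs) - 1e-9


class TestCartography:
    def test_pc_closed_forms(self):
        # node 4 splits its strength evenly across two 2-node modules
        W = np.zeros((5, 5))
        W[0, 1] = W[1, 0] = 1.0
        W[2, 3] = W[3, 2] = 1.0
        W[4, 0] = W[0, 4] = 1.0
        W[4, 2] = W[2, 4] = 1.0
        part = Partition(np.array([1, 1, 2, 2, 1]), 0.0)
        carto = node_cartography(W, part)
        assert carto.loc[3, "pc"] == pytest.approx(0.0)       # all edges within module
        assert carto.loc[4, "pc"] == pytest.approx(0.5)       # 1 - 2 * (1/2)^2

    def test_zero_variance_module_mdz(self):
        W = two_k3()
        part = Partition(np.array([1, 1, 1, 2, 2, 2]), 0.5)
        carto = node_cartography(W, part)
        assert np.allclose(carto["mdz"], 0.0)

    def test_isolated_node_flagged_zero(self, caplog):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 1.0
        with caplog.at_level("WARNING"):
            carto = node_cartography(W, Partition(np.array([1, 1, 2]), 0.0))
        assert carto.loc[2, "pc"] == 0.0
        assert "isolated" in caplog.text


class TestNetworkSummarize:
    def test_single_node_network_and_order_invariance(self, rng):
        nodes = tuple(f"n{i}" for i in range(5))
        atlas = NetworkAtlas(nodes, {"n0": "X", "n1": "Y", "n2": "Y",
                                     "n3": "Y", "n4": "Y"})
        W = rng.random((5, 5))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0.0)
        part = Partition(np.array([1, 1, 1, 2, 2]), 0.0)
        carto = node_cartography(W, part)
        summary = network_summarize(carto, atlas)
        assert summary.loc[summary.network == "X", "mean_pc"].iloc[0] == \
            pytest.approx(carto.loc[0, "pc"])
        perm = np.array([4, 2, 0, 3, 1])
        atlas_p = NetworkAtlas(tuple(nodes[i] for i in perm),
                               atlas.network_of_node)
        carto_p = node_cartography(W[np.ix_(perm, perm)],
                                   Partition(part.modules[perm], 0.0))
        summary_p = network_summarize(carto_p, atlas_p)
        merged = summary.merge(summary_p, on="network", suffixes=("", "_p"))
        assert np.allclose(merged["mean_pc"], merged["mean_pc_p"])
        assert np.allclose(merged["mean_mdz"], merged["mean_mdz_p"])
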