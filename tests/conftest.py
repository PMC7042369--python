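"""Shared fixtures: small hand-checkable graphs and planted-structure
generators used across the suite."""

import numpy as np
import pytest

from sedanet import synthdata
from sedanet.graphs import BinaryGraph, ConnectivityMatrix


def symmetric(pairs, n, default=0.0):
    """Build a symmetric zero-diagonal weight matrix from {(i, j): w}."""
    w = np.full((n, n), default, dtype=float)
    np.fill_diagonal(w, 0.0)
    for (i, j), v in pairs.items():
        w[i, j] = w[j, i] = v
    return w


@pytest.fixture
def two_cliques():
    """Two disconnected unit-weight 3-cliques; optimal Q = 0.5."""
    w = np.zeros((6, 6))
    for a, b in [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)]:
        w[a, b] = w[b, a] = 1.0
    return w


@pytest.fixture
def four_node_star_weights():
    """The 4-node ranked-edge example: one clear star backbone."""
    return ConnectivityMatrix(
        symmetric(
            {(0, 1): 0.9, (0, 2): 0.8, (0, 3): 0.7,
             (1, 2): 0.3, (1, 3): 0.2, (2, 3): 0.1},
            4,
        )
    )


@pytest.fixture
def block_model_40():
    """4 x 10-node block covariance with hubs (the standard fixture)."""
    return synthdata.generate_covariance(
        40, (10, 10, 10, 10), 0.5, 0.1, hub_boost=0.2
    )


@pytest.fixture
def block_model_60():
    """4 x 15-node block covariance, stronger contrast for recovery tests."""
    return synthdata.generate_covariance(
        60, (15, 15, 15, 15), 0.6, 0.05, hub_boost=0.0
    )


def planted_core_graph(n_periphery=52, n_core=8, p_periphery=0.08,
                       core_periphery_deg=18, seed=0):
    """Binary graph with a fully interconnected core of high-degree nodes
    over a sparse periphery -- a planted rich-club.

    Each core node gets exactly ``core_periphery_deg`` periphery edges
    (round-robin over a seed-shuffled periphery order), so all core nodes
    share the same degree and sit strictly above every periphery node.
    """
    rng = np.random.default_rng(seed)
    n = n_periphery + n_core
    a = np.zeros((n, n), dtype=int)
    per = rng.random((n_periphery, n_periphery)) < p_periphery
    per = np.triu(per, 1)
    a[:n_periphery, :n_periphery] = per + per.T
    core = slice(n_periphery, n)
    a[core, core] = 1
    order = rng.permutation(n_periphery)
    pos = 0
    for ci in range(n_periphery, n):
        for _ in range(core_periphery_deg):
            pj = order[pos % n_periphery]
            a[ci, pj] = a[pj, ci] = 1
            pos += 1
    np.fill_diagonal(a, 0)
    return BinaryGraph(a), np.arange(n_periphery, n)


def er_graph(n, p, seed):
    rng = np.random.default_rng(seed)
    upper = np.triu(rng.random((n, n)) < p, 1)
    return BinaryGraph(upper + upper.T)
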