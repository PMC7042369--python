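"""Community detection on signed functional connectivity.

Modularity :math:`Q` is maximised with a Louvain-style greedy algorithm on a
signed quality function that treats negative weights asymmetrically:

.. math::

    Q = Q^{+} - \\frac{s^{-}}{s^{+} + s^{-}} Q^{-},
    \\qquad
    Q^{\\pm} = \\frac{1}{s^{\\pm}} \\sum_{ij}
        \\Big[ w^{\\pm}_{ij}
        - \\gamma \\frac{s^{\\pm}_i s^{\\pm}_j}{s^{\\pm}} \\Big]
        \\delta(c_i, c_j)

where :math:`W^{\\pm}` are the positive/negative parts of the weight matrix,
:math:`s^{\\pm}_i` their nodal strengths and :math:`s^{\\pm}` their total
weight (sum over all matrix entries).  Positive within-community weight is
rewarded at full rate while negative within-community weight is penalised at
a rate that shrinks with the share of negative weight in the network.  With
no negative weights this is the standard Newman-Girvan weighted modularity.

The participation coefficient and an agreement-matrix consensus-reclustering
procedure (for deriving a single partition from many subject x density
partitions) live here too.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graphs import ConnectivityMatrix

__all__ = [
    "Partition",
    "AgreementMatrix",
    "signed_modularity",
    "louvain",
    "best_partition",
    "participation",
    "agreement_matrix",
    "consensus",
]

_EPS = 1e-12


def _canonical_labels(assignment: np.ndarray) -> np.ndarray:
    """Relabel communities as contiguous ints ordered by first appearance."""
    out = np.empty_like(assignment)
    mapping: dict[int, int] = {}
    for idx, c in enumerate(assignment):
        if c not in mapping:
            mapping[c] = len(mapping)
        out[idx] = mapping[c]
    return out


@dataclass
class Partition:
    """A hard node-to-community assignment with its modularity score."""

    assignment: np.ndarray
    q_value: float
    gamma: float = 1.0

    def __post_init__(self) -> None:
        a = np.asarray(self.assignment, dtype=int)
        if a.ndim != 1 or a.size == 0:
            raise ValueError("assignment must be a non-empty 1-D array")
        self.assignment = _canonical_labels(a)
        if not -1.0 - 1e-9 <= self.q_value <= 1.0 + 1e-9:
            raise ValueError("q_value outside [-1, 1]")

    @property
    def n_communities(self) -> int:
        return int(self.assignment.max()) + 1

    def __eq__(self, other) -> bool:  # label-invariant equality
        if not isinstance(other, Partition):
            return NotImplemented
        return np.array_equal(self.assignment, other.assignment)


@dataclass
class AgreementMatrix:
    """Co-assignment fractions across a set of partitions."""

    matrix: np.ndarray
    n_partitions: int

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("agreement matrix must be square")
        if not np.allclose(m, m.T):
            raise ValueError("agreement matrix must be symmetric")
        if m.min() < -1e-12 or m.max() > 1 + 1e-12:
            raise ValueError("agreement entries must lie in [0, 1]")
        if not np.allclose(np.diag(m), 1.0):
            raise ValueError("agreement diagonal must be 1")
        self.matrix = m


def _as_weights(w: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    if isinstance(w, ConnectivityMatrix):
        return w.weights
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weights must be square")
    if not np.allclose(w, w.T, atol=1e-12):
        raise ValueError("weights must be symmetric")
    return w


def _modularity_matrix(w: np.ndarray, gamma: float) -> np.ndarray:
    """Signed modularity matrix B such that Q = sum_{ij} B_ij delta(c_i,c_j)."""
    wp = np.where(w > 0, w, 0.0)
    wn = np.where(w < 0, -w, 0.0)
    sp = wp.sum()
    sn = wn.sum()
    b = np.zeros_like(w)
    if sp > 0:
        kp = wp.sum(axis=1)
        b += (wp - gamma * np.outer(kp, kp) / sp) / sp
    if sn > 0:
        kn = wn.sum(axis=1)
        b -= (sn / (sp + sn)) * (wn - gamma * np.outer(kn, kn) / sn) / sn
    return b


def signed_modularity(
    w: ConnectivityMatrix | np.ndarray,
    p: Partition | np.ndarray,
    gamma: float = 1.0,
) -> float:
    """Evaluate the asymmetric signed modularity of a partition."""
    w = _as_weights(w)
    if w.size == 0:
        raise ValueError("empty graph")
    assignment = p.assignment if isinstance(p, Partition) else np.asarray(p, dtype=int)
    if assignment.shape[0] != w.shape[0]:
        raise ValueError("partition does not cover all nodes")
    b = _modularity_matrix(w, gamma)
    same = assignment[:, None] == assignment[None, :]
    return float(b[same].sum())


def _one_level(b: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Greedy local-move phase on a modularity matrix.

    The gain of placing node i into community c is 2 * sum_{j in c, j!=i}
    B_ij; empty community slots have gain 0, so a node with only detrimental
    neighbours isolates itself.
    """
    n = b.shape[0]
    comm = np.arange(n)
    moved = True
    while moved:
        moved = False
        for i in rng.permutation(n):
            row = b[i].copy()
            row[i] = 0.0
            gains = np.bincount(comm, weights=row, minlength=n)
            best = int(np.argmax(gains))
            if best != comm[i] and gains[best] > gains[comm[i]] + _EPS:
                comm[i] = best
                moved = True
    return comm


def louvain(
    w: ConnectivityMatrix | np.ndarray,
    gamma: float = 1.0,
    seed: int = 0,
) -> Partition:
    """Two-phase Louvain maximisation of the signed modularity.

    The node sweep order is shuffled per ``seed``; after each local-move phase
    communities are aggregated and the procedure recurses on the collapsed
    modularity matrix until no further merge occurs.  Deterministic per seed.
    """
    w = _as_weights(w)
    n = w.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    rng = np.random.default_rng(seed)
    b = _modularity_matrix(w, gamma)
    node_comm = np.arange(n)
    bcur = b
    while True:
        level = _one_level(bcur, rng)
        level = _canonical_labels(level)
        n_comms = int(level.max()) + 1
        node_comm = level[node_comm]
        if n_comms == bcur.shape[0]:
            break
        onehot = np.eye(n_comms)[level]
        bcur = onehot.T @ bcur @ onehot
    assignment = _canonical_labels(node_comm)
    same = assignment[:, None] == assignment[None, :]
    q = float(b[same].sum())
    return Partition(assignment, q, gamma=gamma)


def best_partition(
    w: ConnectivityMatrix | np.ndarray,
    gamma: float = 1.0,
    n_restarts: int = 10,
    seed: int = 0,
) -> Partition:
    """Best of ``n_restarts`` Louvain runs (seeds seed, seed+1, ...).

    Returns the partition with the maximum Q; ties go to the lowest restart
    index.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    best: Partition | None = None
    for k in range(n_restarts):
        cand = louvain(w, gamma=gamma, seed=seed + k)
        if best is None or cand.q_value > best.q_value:
            best = cand
    return best


def participation(
    w: ConnectivityMatrix | np.ndarray, p: Partition | np.ndarray
) -> np.ndarray:
    """Participation coefficient on the positive part of the weights.

    P_i = 1 - sum_m (kappa_im / k_i)^2 with kappa_im node i's positive
    strength into community m and k_i its total positive strength; nodes with
    zero positive strength get P_i = 0.
    """
    w = _as_weights(w)
    assignment = p.assignment if isinstance(p, Partition) else np.asarray(p, dtype=int)
    if assignment.shape[0] != w.shape[0]:
        raise ValueError("partition does not cover all nodes")
    wp = np.where(w > 0, w, 0.0)
    n_comms = int(assignment.max()) + 1
    onehot = np.eye(n_comms)[assignment]
    kim = wp @ onehot
    k = kim.sum(axis=1)
    out = np.zeros(w.shape[0])
    nz = k > 0
    out[nz] = 1.0 - ((kim[nz] / k[nz, None]) ** 2).sum(axis=1)
    return out


def agreement_matrix(partitions: list[Partition]) -> AgreementMatrix:
    """Fraction of partitions co-assigning each node pair (diagonal 1)."""
    if not partitions:
        raise ValueError("need at least one partition")
    n = partitions[0].assignment.shape[0]
    acc = np.zeros((n, n))
    for p in partitions:
        a = p.assignment
        if a.shape[0] != n:
            raise ValueError("partitions cover different node sets")
        acc += a[:, None] == a[None, :]
    return AgreementMatrix(acc / len(partitions), n_partitions=len(partitions))


def consensus(
    partitions: list[Partition],
    tau: float = 0.5,
    max_iter: int = 10,
    seed: int = 0,
    n_restarts: int = 10,
) -> tuple[Partition, bool]:
    """Association-reclustering consensus over a set of partitions.

    Builds the agreement matrix, zeroes entries below ``tau``, reclusters it
    with :func:`best_partition`, and repeats on the agreement of the
    reclusterings until all restarts return the identical partition or
    ``max_iter`` is reached.  Returns ``(partition, converged)``.
    """
    if len(partitions) < 2:
        raise ValueError("need at least 2 partitions")
    current = partitions
    final: Partition | None = None
    for it in range(max_iter):
        ag = agreement_matrix(current).matrix.copy()
        ag[ag < tau] = 0.0
        np.fill_diagonal(ag, 0.0)
        runs = [
            louvain(ag, gamma=1.0, seed=seed + it * n_restarts + k)
            for k in range(n_restarts)
        ]
        final = max(runs, key=lambda p: p.q_value)
        if all(r == runs[0] for r in runs[1:]):
            return final, True
        current = runs
    return final, False
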