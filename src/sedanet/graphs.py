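"""Brain-graph construction: correlation matrices, proportional density
thresholding, binarization and the percolation threshold.

A functional brain graph is built from region-of-interest (ROI) signal time
series: edges are pairwise Pearson correlations (signed, in [-1, 1]), the
diagonal is zero, and graphs are compared across subjects/conditions at fixed
*cost densities* -- the top fraction ``d`` of possible edges is retained so
that every graph has the same edge count.  The *percolation threshold* of a
study is the smallest density at which every graph is fully connected.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

logger = logging.getLogger(__name__)

__all__ = [
    "TimeSeriesPanel",
    "ConnectivityMatrix",
    "BinaryGraph",
    "DensityGrid",
    "correlation_matrix",
    "proportional_threshold",
    "binarize",
    "is_connected",
    "percolation_threshold",
    "read_matrix",
    "write_matrix",
]


def _default_labels(n: int) -> list[str]:
    return [f"roi{i:03d}" for i in range(n)]


@dataclass
class TimeSeriesPanel:
    """One subject-condition block of ROI signals (rows = ROIs, cols = time).

    Parameters
    ----------
    subject : str
        Subject identifier.
    condition : str
        Condition label (e.g. ``"B"``, ``"L"``, ``"M"``).
    signals : ndarray of shape (n_nodes, n_timepoints)
        Real-valued signal matrix; every row must have positive variance.
    node_labels : list of str, optional
        ROI labels; generated if omitted.
    t_r : float, optional
        Sampling interval in seconds (metadata only).
    """

    subject: str
    condition: str
    signals: np.ndarray
    node_labels: list[str] | None = None
    t_r: float | None = None

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2:
            raise ValueError("signals must be a 2-D (nodes x time) array")
        n, t = self.signals.shape
        if n < 2:
            raise ValueError("panel needs at least 2 nodes")
        if t < 3:
            raise ValueError("panel needs at least 3 timepoints")
        if not np.all(np.isfinite(self.signals)):
            raise ValueError("signals contain missing/non-finite values")
        if self.node_labels is None:
            self.node_labels = _default_labels(n)
        if len(self.node_labels) != n:
            raise ValueError("node_labels length does not match signals")
        var = self.signals.var(axis=1)
        bad = np.flatnonzero(var <= 0)
        if bad.size:
            raise ValueError(
                f"zero-variance signal for node(s) "
                f"{[self.node_labels[i] for i in bad]}"
            )

    @property
    def n_nodes(self) -> int:
        return self.signals.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.signals.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric signed weighted connectivity matrix with zero diagonal.

    ``density`` is the retained fraction of possible edges (1.0 = full
    all-to-all matrix, i.e. not thresholded).
    """

    weights: np.ndarray
    node_labels: list[str] | None = None
    density: float = 1.0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        w = self.weights
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weights must be symmetric (within 1e-12)")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be exactly 0")
        if self.node_labels is None:
            self.node_labels = _default_labels(w.shape[0])
        if len(self.node_labels) != w.shape[0]:
            raise ValueError("node_labels length does not match weights")
        if not (0 < self.density <= 1):
            raise ValueError("density must be in (0, 1]")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def n_edges(self) -> int:
        iu = np.triu_indices(self.n_nodes, 1)
        return int(np.count_nonzero(self.weights[iu]))


@dataclass
class BinaryGraph:
    """Simple undirected unweighted graph as a 0/1 adjacency matrix."""

    adjacency: np.ndarray
    node_labels: list[str] | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        a = (a != 0).astype(np.int8)
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a)):
            raise ValueError("no self-loops allowed")
        self.adjacency = a
        if self.node_labels is None:
            self.node_labels = _default_labels(a.shape[0])

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def to_networkx(self):
        import networkx as nx

        g = nx.from_numpy_array(self.adjacency)
        return nx.relabel_nodes(
            g, dict(enumerate(self.node_labels)), copy=True
        )


@dataclass
class DensityGrid:
    """Strictly increasing cost densities in (0, 0.5]."""

    densities: list[float] = field(
        default_factory=lambda: list(np.round(np.arange(0.16, 0.501, 0.02), 4))
    )

    def __post_init__(self) -> None:
        d = [float(x) for x in self.densities]
        if not d:
            raise ValueError("empty density grid")
        if any(x <= 0 or x > 0.5 for x in d):
            raise ValueError("densities must lie in (0, 0.5]")
        if any(b <= a for a, b in zip(d, d[1:])):
            raise ValueError("densities must be strictly increasing")
        self.densities = d

    def __iter__(self):
        return iter(self.densities)

    def __len__(self) -> int:
        return len(self.densities)


def correlation_matrix(panel: TimeSeriesPanel) -> ConnectivityMatrix:
    """Pearson correlation between every pair of ROI time series.

    Returns the full (density 1) signed matrix with the diagonal zeroed.
    """
    w = np.corrcoef(panel.signals)
    np.fill_diagonal(w, 0.0)
    w = np.clip((w + w.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix(w, node_labels=list(panel.node_labels), density=1.0)


def _edge_order(w: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Upper-triangle edges ranked by descending signed weight.

    Ties are broken by ascending (i, j) lexicographic order so thresholding is
    deterministic and nested across densities.
    """
    n = w.shape[0]
    iu, ju = np.triu_indices(n, 1)
    vals = w[iu, ju]
    order = np.lexsort((ju, iu, -vals))
    return iu[order], ju[order], vals[order]


def proportional_threshold(c: ConnectivityMatrix, d: float) -> ConnectivityMatrix:
    """Retain the top ``round(d * N(N-1)/2)`` edges by signed weight.

    Retained edges keep their signed weights; everything else is zero.
    ``round`` is half-to-even.  Raises if the requested density keeps no edge.
    """
    if not (0 < d <= 1):
        raise ValueError("density must be in (0, 1]")
    n = c.n_nodes
    n_possible = n * (n - 1) // 2
    m = int(np.round(d * n_possible))
    if m == 0:
        raise ValueError(f"density {d} retains zero edges for N={n}")
    if m >= n_possible and d == 1.0:
        return ConnectivityMatrix(
            c.weights.copy(), node_labels=list(c.node_labels), density=1.0
        )
    ii, jj, vv = _edge_order(c.weights)
    out = np.zeros_like(c.weights)
    out[ii[:m], jj[:m]] = vv[:m]
    out = out + out.T
    return ConnectivityMatrix(out, node_labels=list(c.node_labels), density=float(d))


def binarize(c: ConnectivityMatrix) -> BinaryGraph:
    """Edge presence (1 where w != 0, sign ignored)."""
    return BinaryGraph((c.weights != 0).astype(np.int8), node_labels=list(c.node_labels))


def is_connected(g: BinaryGraph) -> bool:
    """True iff a single connected component spans all nodes."""
    if g.n_nodes == 1:
        return True
    ncomp, _ = connected_components(
        csr_matrix(g.adjacency), directed=False, return_labels=True
    )
    return ncomp == 1


def percolation_threshold(
    matrices: list[ConnectivityMatrix], search_grid: DensityGrid | None = None
) -> float:
    """Smallest grid density at which EVERY matrix is fully connected.

    The default search grid is 1% to 50% in 1% steps.  Raises if no grid
    density connects all matrices, reporting the density with the most
    connected matrices found.
    """
    if not matrices:
        raise ValueError("need at least one matrix")
    n = matrices[0].n_nodes
    if any(m.n_nodes != n for m in matrices):
        raise ValueError("all matrices must have the same node count")
    if search_grid is None:
        search_grid = DensityGrid(list(np.round(np.arange(0.01, 0.501, 0.01), 4)))
    best_d, best_n = None, -1
    for d in search_grid:
        n_conn = 0
        ok = True
        for c in matrices:
            try:
                g = binarize(proportional_threshold(c, d))
            except ValueError:
                ok = False
                break
            if is_connected(g):
                n_conn += 1
            else:
                ok = False
        if ok and n_conn == len(matrices):
            return float(d)
        if n_conn > best_n:
            best_n, best_d = n_conn, d
    raise ValueError(
        f"no grid density connects all {len(matrices)} matrices; best was "
        f"{best_n}/{len(matrices)} connected at density {best_d}"
    )


def write_matrix(c: ConnectivityMatrix, path, sep: str = "\t") -> None:
    """Write a square labelled matrix as delimited text."""
    df = pd.DataFrame(c.weights, index=c.node_labels, columns=c.node_labels)
    df.to_csv(path, sep=sep)


def read_matrix(path, sep: str = "\t") -> ConnectivityMatrix:
    """Read a square labelled matrix from delimited text.

    Validates symmetry within 1e-8; small asymmetries are repaired by
    averaging with a logged warning.  The diagonal is zeroed.
    """
    df = pd.read_csv(path, sep=sep, index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column labels differ")
    w = df.to_numpy(dtype=float)
    if not np.allclose(w, w.T, atol=1e-8):
        raise ValueError(f"{path}: matrix not symmetric within 1e-8")
    if not np.array_equal(w, w.T):
        logger.warning("%s: re-symmetrizing by averaging", path)
        warnings.warn(f"{path}: re-symmetrizing by averaging", stacklevel=2)
        w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix(w, node_labels=[str(x) for x in df.index])
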