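"""Rich-club detection against a degree-preserving null.

The rich-club coefficient phi(k) is the edge density among all nodes of
degree > k.  Because high-degree nodes are more likely to interconnect by
chance alone, phi(k) is normalised by its mean over Maslov-Sneppen rewired
surrogates (random graphs with the identical degree sequence), and k-levels
where the empirical phi exceeds the surrogate distribution (one-sided
permutation test) are declared significant.  The club itself is the node set
of degree > k*, with k* the maximum significant k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graphs import BinaryGraph, ConnectivityMatrix

__all__ = [
    "RichClubCurve",
    "RichClubSet",
    "phi_curve",
    "rewire",
    "normalized_phi",
    "detect_club",
    "club_strength",
]


@dataclass
class RichClubCurve:
    """phi(k), its surrogate-normalised ratio and permutation p per k-level.

    Arrays are indexed by k = 1 .. k_max (``k_levels``); NaN marks k-levels
    where phi is undefined (fewer than 2 nodes of degree > k).
    """

    k_levels: np.ndarray
    phi: np.ndarray
    phi_norm: np.ndarray | None = None
    p_value: np.ndarray | None = None
    n_surrogates: int = 0
    alpha: float | None = None

    @property
    def significant_k(self) -> np.ndarray:
        """k-levels with phi_norm > 1 and p < alpha."""
        if self.phi_norm is None or self.p_value is None or self.alpha is None:
            return np.array([], dtype=int)
        with np.errstate(invalid="ignore"):
            mask = (self.phi_norm > 1) & (self.p_value < self.alpha)
        return self.k_levels[np.nan_to_num(mask, nan=False).astype(bool)]

    @property
    def k_star(self) -> int | None:
        sig = self.significant_k
        return int(sig.max()) if sig.size else None


@dataclass
class RichClubSet:
    """Nodes of degree > k_star; empty (with ``detected`` False) when no
    significant k-level exists."""

    members: list[str]
    k_star: int | None
    detected: bool = True
    source: str = ""
    member_idx: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def phi_curve(g: BinaryGraph) -> RichClubCurve:
    """Unnormalised rich-club coefficient for k = 1 .. max degree - 1."""
    deg = g.degrees()
    kmax = int(deg.max()) if deg.size else 0
    ks = np.arange(1, max(kmax, 2))
    phi = np.full(ks.shape, np.nan)
    a = g.adjacency
    for idx, k in enumerate(ks):
        mask = deg > k
        nk = int(mask.sum())
        if nk >= 2:
            ek = a[np.ix_(mask, mask)].sum() / 2
            phi[idx] = 2.0 * ek / (nk * (nk - 1))
    return RichClubCurve(k_levels=ks, phi=phi)


def rewire(g: BinaryGraph, swaps_per_edge: int = 10, seed: int = 0) -> BinaryGraph:
    """Maslov-Sneppen degree-preserving randomisation.

    Performs ``swaps_per_edge * |E|`` double-edge-swap *attempts*; an attempt
    picks two distinct edges (a,b), (c,d) uniformly, randomly orients the
    second, and rewires to (a,d), (c,b) unless that would create a self-loop
    or multi-edge.  The degree sequence is preserved exactly.
    """
    edges = np.argwhere(np.triu(g.adjacency, 1))
    n_edges = len(edges)
    if n_edges < 2:
        raise ValueError("need at least 2 edges to rewire")
    rng = np.random.default_rng(seed)
    n_attempts = int(swaps_per_edge) * n_edges
    pairs = rng.integers(0, n_edges, size=(n_attempts, 2))
    flips = rng.random(n_attempts) < 0.5
    edge_list = [tuple(e) for e in edges]
    edge_set = {frozenset(e) for e in edge_list}
    for (e1, e2), flip in zip(pairs, flips):
        if e1 == e2:
            continue
        a, b = edge_list[e1]
        c, d = edge_list[e2]
        if flip:
            c, d = d, c
        if len({a, b, c, d}) < 4:
            continue
        new1, new2 = frozenset((a, d)), frozenset((c, b))
        if new1 in edge_set or new2 in edge_set:
            continue
        edge_set.discard(frozenset((a, b)))
        edge_set.discard(frozenset((c, d)))
        edge_set.add(new1)
        edge_set.add(new2)
        edge_list[e1] = (a, d)
        edge_list[e2] = (c, b)
    adj = np.zeros_like(g.adjacency)
    for e in edge_set:
        i, j = tuple(e)
        adj[i, j] = adj[j, i] = 1
    return BinaryGraph(adj, node_labels=list(g.node_labels))


def normalized_phi(
    g: BinaryGraph,
    n_surrogates: int = 100,
    swaps_per_edge: int = 10,
    alpha: float = 0.05,
    seed: int = 0,
) -> RichClubCurve:
    """Surrogate-normalised rich-club curve with one-sided permutation p.

    phi_norm(k) = phi(k) / mean_surrogates phi_surr(k); p(k) uses the add-one
    permutation estimator (1 + #{phi_surr >= phi}) / (n_surrogates + 1), so it
    is never zero.  Because surrogates preserve the degree sequence, the set
    of defined k-levels is identical across surrogates.
    """
    if n_surrogates < 20:
        raise ValueError("need at least 20 surrogates")
    base = phi_curve(g)
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=n_surrogates)
    surr = np.empty((n_surrogates, base.phi.size))
    for i, s in enumerate(child_seeds):
        surr[i] = phi_curve(rewire(g, swaps_per_edge=swaps_per_edge, seed=int(s))).phi
    defined = ~np.isnan(base.phi)
    phi_norm = np.full(base.phi.shape, np.nan)
    p = np.full(base.phi.shape, np.nan)
    if defined.any():
        sub = surr[:, defined]  # degree sequence shared => no NaN here
        with np.errstate(invalid="ignore", divide="ignore"):
            phi_norm[defined] = base.phi[defined] / sub.mean(axis=0)
        ge = (sub >= base.phi[defined][None, :]).sum(axis=0)
        p[defined] = (1.0 + ge) / (n_surrogates + 1.0)
    return RichClubCurve(
        k_levels=base.k_levels,
        phi=base.phi,
        phi_norm=phi_norm,
        p_value=p,
        n_surrogates=n_surrogates,
        alpha=alpha,
    )


def detect_club(g: BinaryGraph, curve: RichClubCurve, source: str = "") -> RichClubSet:
    """Nodes of degree > k* (maximum significant k-level).

    An empty significant set yields an explicit "not detected" result rather
    than an exception.
    """
    k_star = curve.k_star
    if k_star is None:
        return RichClubSet([], None, detected=False, source=source)
    deg = g.degrees()
    idx = np.flatnonzero(deg > k_star)
    return RichClubSet(
        [g.node_labels[i] for i in idx],
        k_star,
        detected=True,
        source=source,
        member_idx=idx,
    )


def club_strength(w: ConnectivityMatrix, club: RichClubSet | list[str]) -> float:
    """Mean signed weight over all unordered pairs of club members.

    Computed on the full signed matrix; requires at least 2 members.
    """
    members = club.members if isinstance(club, RichClubSet) else list(club)
    if len(members) < 2:
        raise ValueError("club needs at least 2 members")
    pos = {lab: i for i, lab in enumerate(w.node_labels)}
    try:
        idx = np.array([pos[m] for m in members])
    except KeyError as exc:
        raise ValueError(f"club member {exc} not in matrix labels") from exc
    sub = w.weights[np.ix_(idx, idx)]
    n = len(idx)
    return float(sub.sum() / (n * (n - 1)))
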