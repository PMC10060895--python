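"""Weighted-network features of a functional brain network.

Five dimensionless graph metrics summarize each PLV network: average
degree (AD, mean node strength), average clustering coefficient (ACC),
characteristic path length (CPL), global efficiency (GE) and modularity
(MD).  Shortest paths use the common PLV-network convention that an edge
of weight w has length 1/w (unreachable = infinite).

Two divisor conventions are exposed for CPL/GE: ``standard`` averages over
the N(N-1) ordered node pairs (so the complete unit-weight graph has
CPL = GE = 1) and ``as_printed`` divides by N(N+1) instead; the two differ
exactly by the factor (N-1)/(N+1).

Weighted clustering is the triangle-intensity (geometric-mean) form with
weights on the natural PLV scale (maximum possible weight 1):

    C_i = 2 / (k_i (k_i - 1)) * sum_{j<h in N(i)} (w_ij w_ih w_jh)^(1/3)

which reduces to the binary 2|e_i| / (k_i (k_i - 1)) on 0/1 weights; a
``binarized`` mode thresholds the weights first and applies the binary
formula.  Modularity is evaluated exactly as

    MD = sum_u [ e_uu - (sum_v e_uv)^2 ]

with e_uv the fraction of total edge weight running between modules u and
v, on a partition found by deterministic greedy (CNM) modularity
maximization.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .errors import ConfigError, DisconnectedNetworkError
from .plv import FBN

FEATURE_ORDER: tuple[str, ...] = ("AD", "ACC", "CPL", "GE", "MD")


@dataclass(frozen=True)
class NetworkFeatures:
    """The five weighted-network features, in fixed (AD, ACC, CPL, GE, MD) order."""

    AD: float
    ACC: float
    CPL: float
    GE: float
    MD: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_ORDER])


def _adjacency(fbn: FBN | np.ndarray) -> np.ndarray:
    """Off-diagonal weight matrix (diagonal zeroed; self-loops never count)."""
    w = np.array(fbn.weights if isinstance(fbn, FBN) else fbn, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ConfigError("adjacency must be square")
    if w.shape[0] == 0:
        raise ConfigError("empty network")
    np.fill_diagonal(w, 0.0)
    return w


def node_strength(fbn: FBN | np.ndarray, i: int) -> float:
    """Weighted degree of node i: the sum of its incident edge weights."""
    w = _adjacency(fbn)
    if not (0 <= i < w.shape[0]):
        raise IndexError(f"node {i} out of range for {w.shape[0]} nodes")
    return float(w[i].sum())


def average_degree(fbn: FBN | np.ndarray) -> float:
    """AD: mean node strength."""
    w = _adjacency(fbn)
    return float(w.sum(axis=1).mean())


def average_clustering(fbn: FBN | np.ndarray, mode: str = "weighted",
                       threshold: float = 0.5) -> float:
    """ACC: mean per-node clustering; nodes with fewer than 2 neighbors
    contribute 0."""
    w = _adjacency(fbn)
    if mode == "binarized":
        w = (w >= threshold).astype(float)
    elif mode != "weighted":
        raise ConfigError(f"unknown clustering mode {mode!r}")
    k = np.count_nonzero(w, axis=1)
    w13 = np.cbrt(w)
    triangles = np.diag(w13 @ w13 @ w13)  # 2 * sum of triangle intensities
    denom = k * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, triangles / denom, 0.0)
    return float(c.mean())


def shortest_path_lengths(fbn: FBN | np.ndarray) -> np.ndarray:
    """All-pairs shortest-path lengths under the 1/weight edge-length rule."""
    w = _adjacency(fbn)
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    return dijkstra(csr_matrix(lengths), directed=False)


def _pair_divisor(n: int, convention: str) -> float:
    if convention == "standard":
        return float(n * (n - 1))
    if convention == "as_printed":
        return float(n * (n + 1))
    raise ConfigError(f"unknown convention {convention!r}")


def characteristic_path_length(fbn: FBN | np.ndarray,
                               convention: str = "standard") -> float:
    """CPL: mean shortest-path length over ordered node pairs.

    Undefined (error) when any pair is unreachable — use GE there.
    """
    lengths = shortest_path_lengths(fbn)
    n = lengths.shape[0]
    off = ~np.eye(n, dtype=bool)
    if np.isinf(lengths[off]).any():
        raise DisconnectedNetworkError(
            "network is disconnected; CPL undefined (use global efficiency)"
        )
    return float(lengths[off].sum() / _pair_divisor(n, convention))


def global_efficiency(fbn: FBN | np.ndarray,
                      convention: str = "standard") -> float:
    """GE: mean inverse shortest-path length (unreachable pairs contribute 0)."""
    lengths = shortest_path_lengths(fbn)
    n = lengths.shape[0]
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isinf(lengths[off]), 0.0, 1.0 / lengths[off])
    return float(inv.sum() / _pair_divisor(n, convention))


def modularity_value(fbn: FBN | np.ndarray,
                     partition: list[set[int]]) -> float:
    """Evaluate MD = sum_u [e_uu - (sum_v e_uv)^2] exactly on a partition.

    e_uv is the fraction of total edge weight between modules u and v
    (each undirected edge counted once; the full inter-module weight
    appears in both rows).
    """
    w = _adjacency(fbn)
    total = w.sum() / 2.0
    if total == 0:
        return 0.0
    module_of = np.empty(w.shape[0], dtype=int)
    for u, members in enumerate(partition):
        for i in members:
            module_of[i] = u
    m = len(partition)
    e = np.zeros((m, m))
    ii, jj = np.triu_indices_from(w, k=1)
    for i, j, wij in zip(ii, jj, w[ii, jj]):
        if wij > 0:
            e[module_of[i], module_of[j]] += wij
            if module_of[i] != module_of[j]:
                e[module_of[j], module_of[i]] += wij
    e /= total
    return float(np.sum(np.diag(e) - e.sum(axis=1) ** 2))


def modularity(fbn: FBN | np.ndarray, seed: int | None = None
               ) -> tuple[float, list[set[int]]]:
    """(MD, partition) with the partition from deterministic greedy (CNM)
    weighted modularity maximization.  ``seed`` is accepted for API
    stability; the greedy agglomeration is deterministic.

    An edgeless network has MD = 0 on the singleton partition.
    """
    w = _adjacency(fbn)
    n = w.shape[0]
    if w.sum() == 0:
        return 0.0, [{i} for i in range(n)]
    g = nx.from_numpy_array(w)
    communities = nx.community.greedy_modularity_communities(g, weight="weight")
    partition = [set(c) for c in communities]
    return modularity_value(w, partition), partition


def network_feature_vector(fbn: FBN | np.ndarray, mode: str = "weighted",
                           convention: str = "standard",
                           seed: int | None = None) -> NetworkFeatures:
    """All five metrics of one network, in (AD, ACC, CPL, GE, MD) order."""
    md, _ = modularity(fbn, seed=seed)
    return NetworkFeatures(
        AD=average_degree(fbn),
        ACC=average_clustering(fbn, mode=mode),
        CPL=characteristic_path_length(fbn, convention=convention),
        GE=global_efficiency(fbn, convention=convention),
        MD=md,
    )
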