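"""Weighted graph-theory metrics on connectomes.

All six global metrics are computed after the same preprocessing chain:

1. **normalize** -- weights divided by the maximum, so W' is in [0, 1];
2. **length** -- edge length L_ij = 1 / W'_ij (stronger connection, shorter
   length); absent edges have infinite length;
3. **distance** -- all-pairs shortest paths on the length graph (Dijkstra).

Metrics:

* characteristic path length: mean of finite off-diagonal distances
  (unreachable pairs are excluded and their count logged);
* strength: mean over nodes of weighted degree (row sums of W');
* transitivity: weighted triangle density
  ``sum_ijk (w_ij w_jk w_ki)^(1/3) / sum_i k_i (k_i - 1)`` with binary
  degrees k;
* modularity: best Q over seeded Louvain restarts at resolution gamma,
  ``Q = sum_c (e_c - gamma * a_c^2)``;
* mean rich-club coefficient: for each degree level k, the weight carried by
  the subgraph of nodes with binary degree > k divided by the sum of the
  equally many largest weights anywhere in the graph; averaged over all
  levels at which the subgraph has at least one edge;
* small worldness: the sigma ratio (C / <C_null>) / (CPL / <CPL_null>) with
  C = transitivity, against an ensemble of degree-preserving rewired nulls
  with shuffled weights (100 by default, seed-controlled).

Undefined metrics are reported as NaN, never silently dropped. All metrics
are invariant to a positive rescaling of W (normalization absorbs it) and to
node relabelling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import shortest_path

from .core_io import Connectome

logger = logging.getLogger("clsmverse")

METRIC_NAMES = (
    "characteristic_path_length",
    "modularity_q",
    "rich_club_mean",
    "strength_mean",
    "small_worldness",
    "transitivity",
)


@dataclass
class GraphMetricSet:
    characteristic_path_length: float
    modularity_q: float
    rich_club_mean: float
    strength_mean: float
    small_worldness: float
    transitivity: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def _as_weights(W: np.ndarray | Connectome) -> np.ndarray:
    if isinstance(W, Connectome):
        W = W.weights
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("weight matrix must be square")
    if np.any(W < 0):
        raise ValueError("negative weights are not supported")
    return W


def normalize(W: np.ndarray | Connectome) -> np.ndarray:
    """Scale weights into [0, 1] by the maximum; zero matrices pass through."""
    W = _as_weights(W)
    m = W.max()
    if m == 0:
        warnings.warn("all-zero weight matrix: normalization is a no-op")
        return W.copy()
    return W / m


def to_length(Wn: np.ndarray) -> np.ndarray:
    """Edge lengths as inverse weights; absent edges become infinite."""
    Wn = np.asarray(Wn, dtype=float)
    L = np.full_like(Wn, np.inf)
    nz = Wn > 0
    L[nz] = 1.0 / Wn[nz]
    np.fill_diagonal(L, 0.0)
    return L


def distances(L: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path lengths (Dijkstra per source)."""
    L = np.asarray(L, dtype=float)
    graph = np.where(np.isfinite(L), L, 0.0)
    np.fill_diagonal(graph, 0.0)
    return shortest_path(graph, method="D", directed=False)


def char_path_length(D: np.ndarray) -> float:
    """Mean finite off-diagonal distance; NaN if no pair is reachable."""
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(D) & off
    n_inf = int(off.sum() - finite.sum())
    if n_inf:
        logger.info("stage=char_path_length unreachable_pairs=%d", n_inf)
    if not finite.any():
        return float("nan")
    return float(D[finite].mean())


def strength(Wn: np.ndarray) -> float:
    """Mean nodal strength (average row sum)."""
    Wn = np.asarray(Wn, dtype=float)
    return float(Wn.sum(axis=1).mean())


def transitivity(Wn: np.ndarray) -> float:
    """Weighted transitivity: geometric-mean triangle intensity over wedges."""
    Wn = np.asarray(Wn, dtype=float)
    k = (Wn > 0).sum(axis=1)
    denom = float((k * (k - 1)).sum())
    if denom == 0:
        return 0.0
    cr = np.cbrt(Wn)
    num = float(np.trace(cr @ cr @ cr))
    return num / denom


def modularity(
    Wn: np.ndarray,
    gamma: float = 1.0,
    seed: int = 0,
    restarts: int = 20,
) -> tuple[float, list[set[int]]]:
    """Best Louvain modularity Q over seeded restarts; returns (Q, partition)."""
    Wn = np.asarray(Wn, dtype=float)
    if not np.any(Wn > 0):
        raise ValueError("modularity is undefined for a graph with no edges")
    G = nx.from_numpy_array(Wn)
    best_q, best_part = -np.inf, None
    for r in range(restarts):
        part = nx.community.louvain_communities(
            G, weight="weight", resolution=gamma, seed=seed + r
        )
        q = nx.community.modularity(G, part, weight="weight", resolution=gamma)
        if q > best_q:
            best_q, best_part = q, part
    return float(best_q), [set(c) for c in best_part]


def rich_club(Wn: np.ndarray) -> float:
    """Mean weighted rich-club coefficient over all defined degree levels."""
    Wn = np.asarray(Wn, dtype=float)
    A = Wn > 0
    if not A.any():
        raise ValueError("rich club is undefined for a graph with no edges")
    k = A.sum(axis=1)
    iu = np.triu_indices(Wn.shape[0], k=1)
    weights_sorted = np.sort(Wn[iu][Wn[iu] > 0])[::-1]
    phis = []
    for level in range(1, int(k.max())):
        nodes = k > level
        if nodes.sum() < 2:
            continue
        sub = Wn[np.ix_(nodes, nodes)]
        su = np.triu_indices(sub.shape[0], k=1)
        vals = sub[su]
        n_edges = int((vals > 0).sum())
        if n_edges == 0:
            continue
        phis.append(float(vals.sum()) / float(weights_sorted[:n_edges].sum()))
    if not phis:
        return float("nan")
    return float(np.mean(phis))


def _null_ensemble(Wn: np.ndarray, n_null: int, rng: np.random.Generator):
    """Degree-preserving rewired nulls with the original weight multiset."""
    G = nx.from_numpy_array(Wn)
    m = G.number_of_edges()
    iu = np.triu_indices(Wn.shape[0], k=1)
    weights = Wn[iu][Wn[iu] > 0]
    for _ in range(n_null):
        H = G.copy()
        if m >= 2:
            try:
                nx.double_edge_swap(
                    H,
                    nswap=5 * m,
                    max_tries=100 * m,
                    seed=int(rng.integers(2**31)),
                )
            except nx.NetworkXException:
                pass  # too dense/small to swap: fall back to weight shuffle only
        perm = rng.permutation(len(weights))
        null = np.zeros_like(Wn)
        for (u, v), w in zip(H.edges(), weights[perm]):
            null[u, v] = null[v, u] = w
        yield null


def small_worldness(
    Wn: np.ndarray,
    n_null: int = 100,
    seed: int = 0,
) -> float:
    """Sigma small-worldness against rewired weight-shuffled nulls."""
    Wn = np.asarray(Wn, dtype=float)
    rng = np.random.default_rng(seed)
    C = transitivity(Wn)
    cpl = char_path_length(distances(to_length(Wn)))
    c_null, l_null = [], []
    for null in _null_ensemble(Wn, n_null, rng):
        c_null.append(transitivity(null))
        l_null.append(char_path_length(distances(to_length(null))))
    c_bar = float(np.mean(c_null))
    l_bar = float(np.nanmean(l_null))
    if c_bar == 0 or not np.isfinite(c_bar):
        raise ValueError("null ensemble has zero mean clustering")
    if not np.isfinite(cpl) or not np.isfinite(l_bar) or l_bar == 0:
        return float("nan")
    return float((C / c_bar) / (cpl / l_bar))


def all_metrics(
    connectome: Connectome | np.ndarray,
    seed: int = 0,
    n_null: int = 100,
    gamma: float = 1.0,
    restarts: int = 20,
) -> GraphMetricSet:
    """Run the normalize -> length -> distance chain and all six metrics.

    Metrics that are undefined on the given graph come back as NaN (for an
    all-zero matrix everything except strength, which is 0).
    """
    W = _as_weights(connectome)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        Wn = normalize(W)
    if not np.any(Wn > 0):
        return GraphMetricSet(
            characteristic_path_length=float("nan"),
            modularity_q=float("nan"),
            rich_club_mean=float("nan"),
            strength_mean=0.0,
            small_worldness=float("nan"),
            transitivity=float("nan"),
        )
    D = distances(to_length(Wn))
    q, _ = modularity(Wn, gamma=gamma, seed=seed, restarts=restarts)
    try:
        rc = rich_club(Wn)
    except ValueError:
        rc = float("nan")
    try:
        sw = small_worldness(Wn, n_null=n_null, seed=seed)
    except ValueError:
        sw = float("nan")
    return GraphMetricSet(
        characteristic_path_length=char_path_length(D),
        modularity_q=q,
        rich_club_mean=rc,
        strength_mean=strength(Wn),
        small_worldness=sw,
        transitivity=transitivity(Wn),
    )
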