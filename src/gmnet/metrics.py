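"""Graph statistics for binarized covariance networks.

Implements the Watts–Strogatz small-world coefficient
``sigma = (C / C_rand) / (L / L_rand)`` where C is the mean local clustering
coefficient, L the characteristic path length, and the *_rand references are
means over degree-preserving randomizations of the same network.  Values of
sigma above 1 indicate more clustered-yet-integrated structure than a
degree-matched random graph.

All operations work on sparse adjacency matrices; path lengths use per-source
breadth-first search so networks with thousands of cube nodes stay tractable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy import sparse
from scipy.sparse import csgraph

from .network import BinaryNetwork

logger = logging.getLogger("gmnet")

__all__ = [
    "NetworkMetrics",
    "clustering_coefficient",
    "path_length",
    "randomize_network",
    "small_world",
]


@dataclass
class NetworkMetrics:
    """Summary statistics of one binary network and its random references."""

    n_nodes: int
    n_edges: int
    mean_degree: float
    clustering: float
    path_length: float
    clustering_rand: float
    path_length_rand: float
    gamma: float          # clustering / clustering_rand
    lambda_: float        # path_length / path_length_rand
    small_world: float    # gamma / lambda_
    n_random: int
    component_fraction: float

    def to_dict(self) -> dict:
        d = asdict(self)
        d["lambda"] = d.pop("lambda_")
        return d


def clustering_coefficient(net: BinaryNetwork) -> tuple[np.ndarray, float]:
    """Watts–Strogatz local clustering per node and its mean.

    C_i = 2 t_i / (k_i (k_i - 1)) with t_i the number of triangles through
    node i; nodes of degree < 2 have C_i = 0.
    """
    a = net.adjacency.astype(np.float64)
    k = np.asarray(a.sum(axis=1)).ravel()
    # t_i = number of closed triangles through i = diag(A^3)/2
    tri = np.asarray((a @ a).multiply(a).sum(axis=1)).ravel() / 2.0
    denom = k * (k - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, tri / denom, 0.0)
    return c, float(c.mean()) if c.size else float("nan")


def _largest_component(net: BinaryNetwork) -> tuple[np.ndarray, float]:
    n_comp, labels = csgraph.connected_components(net.adjacency, directed=False)
    sizes = np.bincount(labels)
    giant = int(np.argmax(sizes))
    nodes = np.flatnonzero(labels == giant)
    return nodes, float(sizes[giant] / net.n_nodes)


def path_length(net: BinaryNetwork) -> float:
    """Characteristic path length: mean shortest-path distance over all
    unordered node pairs within the largest connected component.

    The restriction to the largest component avoids infinite distances in
    disconnected graphs; callers that need auditability of this convention get
    the component fraction from :func:`small_world`.
    """
    if net.n_nodes < 2:
        raise ValueError("path length needs at least 2 nodes")
    if net.n_edges == 0:
        raise ValueError("path length undefined on a network with no edges")
    nodes, _ = _largest_component(net)
    sub = net.adjacency[np.ix_(nodes, nodes)]
    dist = csgraph.shortest_path(sub, method="D", directed=False, unweighted=True)
    iu = np.triu_indices(len(nodes), k=1)
    return float(dist[iu].mean())


def randomize_network(
    net: BinaryNetwork, seed: int | np.random.Generator = 0, swaps_per_edge: int = 10
) -> BinaryNetwork:
    """Degree-preserving randomization by double-edge swaps.

    Attempts ``swaps_per_edge * n_edges`` swaps; each picks two edges (a, b),
    (c, d) and proposes (a, d), (c, b), rejecting self-loops and multi-edges.
    The result is a simple graph with the identical degree sequence.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    coo = sparse.triu(net.adjacency, k=1).tocoo()
    edges = np.stack([coo.row, coo.col], axis=1).astype(np.int64)
    m = edges.shape[0]
    if m < 2:
        warnings.warn("fewer than 2 edges: no swap possible, returning a copy")
        return BinaryNetwork(
            adjacency=net.adjacency.copy(),
            node_origins=net.node_origins,
            threshold=net.threshold,
        )
    edge_set = {(int(u), int(v)) if u < v else (int(v), int(u)) for u, v in edges}
    n_attempts = swaps_per_edge * m
    pick = rng.integers(0, m, size=(n_attempts, 2))
    flip = rng.random(n_attempts) < 0.5
    n_success = 0
    for t in range(n_attempts):
        e1, e2 = pick[t]
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if flip[t]:
            c, d = d, c
        # propose a-d and c-b
        if a == d or c == b:
            continue
        new1 = (a, d) if a < d else (d, a)
        new2 = (c, b) if c < b else (b, c)
        old1 = (a, b) if a < b else (b, a)
        old2 = (min(c, d), max(c, d))
        if new1 in edge_set or new2 in edge_set:
            continue
        edge_set.discard(old1)
        edge_set.discard(old2)
        edge_set.add(new1)
        edge_set.add(new2)
        edges[e1] = new1
        edges[e2] = new2
        n_success += 1
    if n_success == 0:
        warnings.warn("no admissible double-edge swap found; returning input copy")
    arr = np.array(sorted(edge_set), dtype=np.int64)
    n = net.n_nodes
    adj = sparse.coo_matrix(
        (np.ones(len(arr), dtype=np.int8), (arr[:, 0], arr[:, 1])), shape=(n, n)
    )
    adj = adj + adj.T
    return BinaryNetwork(
        adjacency=adj.tocsr(), node_origins=net.node_origins, threshold=net.threshold
    )


def small_world(
    net: BinaryNetwork,
    n_random: int = 5,
    seed: int | np.random.Generator = 0,
    swaps_per_edge: int = 10,
) -> NetworkMetrics:
    """Small-world coefficient against degree-preserving random references.

    gamma = C / mean(C over ``n_random`` randomized graphs), lambda = L /
    mean(L over the same graphs), sigma = gamma / lambda.  Randomized
    references with undefined path length are excluded with a warning; if all
    are excluded an error is raised.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nodes, comp_frac = _largest_component(net)
    if comp_frac <= 0.5:
        warnings.warn(
            f"largest connected component holds only {comp_frac:.1%} of nodes; "
            "small-world statistics may be unstable"
        )
    _, c = clustering_coefficient(net)
    ell = path_length(net)
    c_rand, l_rand = [], []
    for _ in range(n_random):
        r = randomize_network(net, seed=rng, swaps_per_edge=swaps_per_edge)
        try:
            l_r = path_length(r)
        except ValueError:
            warnings.warn("randomized reference with undefined path length excluded")
            continue
        _, c_r = clustering_coefficient(r)
        c_rand.append(c_r)
        l_rand.append(l_r)
    if not c_rand:
        raise ValueError("all randomized references had undefined path length")
    c_rand_mean = float(np.mean(c_rand))
    l_rand_mean = float(np.mean(l_rand))
    if c_rand_mean == 0:
        warnings.warn("random references have zero clustering; gamma undefined")
        gamma = float("nan")
    else:
        gamma = c / c_rand_mean
    lam = ell / l_rand_mean
    degs = net.degrees()
    metrics = NetworkMetrics(
        n_nodes=net.n_nodes,
        n_edges=net.n_edges,
        mean_degree=float(degs.mean()) if degs.size else 0.0,
        clustering=c,
        path_length=ell,
        clustering_rand=c_rand_mean,
        path_length_rand=l_rand_mean,
        gamma=gamma,
        lambda_=lam,
        small_world=gamma / lam,
        n_random=len(c_rand),
        component_fraction=comp_frac,
    )
    logger.info(
        "small_world: n=%d m=%d C=%.4f L=%.4f gamma=%.4f lambda=%.4f sigma=%.4f",
        metrics.n_nodes, metrics.n_edges, c, ell, gamma, lam, metrics.small_world,
    )
    return metrics
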