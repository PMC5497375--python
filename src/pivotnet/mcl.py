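"""Markov cluster algorithm (MCL) for graph partitioning.

MCL simulates flow on a graph by alternating *expansion* (matrix power of a
column-stochastic matrix, i.e. multi-step random walk) and *inflation*
(entry-wise power followed by column renormalization, which sharpens strong
flows and starves weak ones), pruning negligible entries, until the matrix
reaches an idempotent limit.  Clusters are read off the attractor structure
of the limit: rows with positive diagonal mass are attractors; attractors
reachable from one another form an attractor system, and every node joins
the system holding the largest share of its column mass.

Canonical defaults (inflation 2.0, expansion 2, self-loop weight 1.0) are
used; clustering is performed on the unweighted retained-edge graph unless
``weight`` names an edge attribute.
"""

from __future__ import annotations

import warnings

import numpy as np
import networkx as nx

__all__ = ["mcl_cluster"]


def mcl_cluster(
    network: nx.Graph,
    inflation: float = 2.0,
    expansion: int = 2,
    loop_weight: float = 1.0,
    prune_threshold: float = 1e-5,
    max_iterations: int = 100,
    tolerance: float = 1e-6,
    weight: str | None = None,
) -> list[set]:
    """Partition the nodes of an undirected graph with MCL.

    Returns a list of disjoint node sets covering the whole node set,
    ordered by (descending size, lexicographically smallest member).
    Non-convergence within ``max_iterations`` produces a warning, not an
    error.
    """
    if inflation <= 0:
        raise ValueError(f"inflation must be positive: {inflation}")
    if loop_weight <= 0:
        raise ValueError(f"loop_weight must be positive: {loop_weight}")
    if expansion < 1:
        raise ValueError(f"expansion must be >= 1: {expansion}")
    if network.number_of_nodes() == 0:
        raise ValueError("cannot cluster an empty network")

    nodes = sorted(network.nodes())
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    M = np.zeros((n, n))
    for u, v, data in network.edges(data=True):
        w = float(data.get(weight, 1.0)) if weight else 1.0
        M[idx[u], idx[v]] = w
        M[idx[v], idx[u]] = w
    np.fill_diagonal(M, loop_weight)
    M /= M.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(max_iterations):
        new = np.linalg.matrix_power(M, expansion)
        np.power(new, inflation, out=new)
        new[new < prune_threshold] = 0.0
        colsum = new.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        new /= colsum
        delta = np.abs(new - M).max()
        M = new
        if delta < tolerance:
            converged = True
            break
    if not converged:
        warnings.warn(f"MCL did not converge within {max_iterations} iterations "
                      f"(last max-norm change above {tolerance:g})")

    eps = prune_threshold
    attractors = [i for i in range(n) if M[i, i] > eps]
    if not attractors:  # numerical corner: fall back to column argmax rows
        attractors = sorted(set(int(np.argmax(M[:, j])) for j in range(n)))

    # attractor systems: attractors linked by mutual/overlapping flow
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    attractor_set = set(attractors)
    for i in attractors:
        for j in np.nonzero(M[i, :] > eps)[0]:
            if int(j) in attractor_set:
                union(i, int(j))

    systems: dict[int, list[int]] = {}
    for i in attractors:
        systems.setdefault(find(i), []).append(i)
    system_list = list(systems.values())

    # assign every node to the system with the largest share of its column
    # mass; ties broken toward the system with the smallest member id
    clusters: list[set] = [set() for _ in system_list]
    order = sorted(range(len(system_list)),
                   key=lambda s: min(nodes[i] for i in system_list[s]))
    for j in range(n):
        masses = [(sum(M[i, j] for i in system_list[s]), s) for s in order]
        best = max(masses, key=lambda t: t[0])
        if best[0] <= eps and j in attractor_set:
            # attractor of its own (shouldn't happen: it is in a system)
            pass
        clusters[best[1]].add(nodes[j])
    clusters = [c for c in clusters if c]
    clusters.sort(key=lambda c: (-len(c), min(c)))

    assert sum(len(c) for c in clusters) == n, "MCL output must partition nodes"
    return clusters
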