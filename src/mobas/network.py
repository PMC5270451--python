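"""Weighted PPI graph queries and degree-preserving randomization.

Graphs are plain :class:`networkx.Graph` objects with a ``weight`` attribute
per edge in (0, 1] (1.0 for unweighted networks).  The null-network generator
performs double-edge swaps, which preserve every node's degree, the edge
count, and the multiset of edge weights exactly.
"""

from __future__ import annotations

import logging
from typing import Iterable

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["two_hop_locality", "remove_nodes", "rewire_preserving_degrees"]


def two_hop_locality(network: nx.Graph, seed: str) -> set[str]:
    """All nodes within shortest-path distance 2 of ``seed`` (seed included)."""
    if seed not in network:
        raise KeyError(f"seed node {seed!r} not in network")
    adj = network.adj
    one_hop = set(adj[seed])
    result = {seed} | one_hop
    for u in one_hop:
        result.update(adj[u])
    return result


def remove_nodes(network: nx.Graph, nodes: Iterable[str]) -> nx.Graph:
    """Copy of the network without ``nodes`` and their incident edges.

    Nodes absent from the network are ignored (logged); the input graph is
    left unmodified.
    """
    nodes = set(nodes)
    absent = nodes - set(network.nodes)
    if absent:
        logger.debug("remove_nodes: %d nodes not present, ignored", len(absent))
    result = network.copy()
    result.remove_nodes_from(nodes & set(network.nodes))
    return result


def rewire_preserving_degrees(
    network: nx.Graph,
    n_swaps: int | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> nx.Graph:
    """Randomize the network by double-edge swaps, preserving all degrees.

    Each attempt picks two edges (a,b), (c,d) on four distinct nodes and
    replaces them with (a,d), (c,b) — the replacement is rejected if it would
    create a self-loop or a parallel edge.  Weights travel with the swap:
    (a,d) inherits w(a,b) and (c,b) inherits w(c,d), so the multiset of edge
    weights is preserved exactly.  ``n_swaps`` counts *attempted* swaps and
    defaults to 10·|E|, a common mixing heuristic for edge-swap MCMC.
    """
    if n_swaps is not None and n_swaps < 0:
        raise ValueError("n_swaps must be non-negative")
    rng = np.random.default_rng(seed)
    edges = [[u, v, data.get("weight", 1.0)] for u, v, data in network.edges(data=True)]
    m = len(edges)
    result = nx.Graph()
    result.add_nodes_from(network.nodes)
    if m < 2:
        for u, v, w in edges:
            result.add_edge(u, v, weight=w)
        return result

    adjacency: dict[str, set[str]] = {node: set(network.adj[node]) for node in network}
    attempts = 10 * m if n_swaps is None else n_swaps
    accepted = 0
    for _ in range(attempts):
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        a, b, w_ab = edges[i]
        c, d, w_cd = edges[j]
        if rng.random() < 0.5:  # random orientation of the second edge
            c, d = d, c
        if len({a, b, c, d}) < 4:
            continue
        if d in adjacency[a] or b in adjacency[c]:
            continue
        adjacency[a].discard(b)
        adjacency[b].discard(a)
        adjacency[c].discard(d)
        adjacency[d].discard(c)
        adjacency[a].add(d)
        adjacency[d].add(a)
        adjacency[c].add(b)
        adjacency[b].add(c)
        edges[i] = [a, d, w_ab]
        edges[j] = [c, b, w_cd]
        accepted += 1
    logger.debug(
        "rewire_preserving_degrees: accepted %d of %d attempted swaps", accepted, attempts
    )
    for u, v, w in edges:
        result.add_edge(u, v, weight=w)
    return result
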