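"""Shared fixtures: random scoring instances and small synthetic studies."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from mobas.association import BackgroundProfile, GeneScoreProfile
from mobas.scoring import ScoringContext


def make_instance(
    rng: np.random.Generator,
    n_nodes: int = 10,
    p_edge: float = 0.4,
    scheme: str = "mobas",
    lam: float = 0.5,
    n_perm: int = 4,
) -> ScoringContext:
    """A random weighted graph + scores + background for scoring tests."""
    genes = [f"g{i:02d}" for i in range(n_nodes)]
    graph = nx.Graph()
    graph.add_nodes_from(genes)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                graph.add_edge(genes[i], genes[j], weight=float(rng.uniform(0.05, 1.0)))
    scores = GeneScoreProfile({g: float(rng.uniform(0.0, 5.0)) for g in genes})
    background = BackgroundProfile(
        genes=genes, matrix=rng.uniform(0.0, 2.0, size=(n_perm, n_nodes))
    )
    return ScoringContext(
        scores=scores, network=graph, background=background, scheme=scheme, lam=lam
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def path_graph() -> nx.Graph:
    g = nx.path_graph(["A", "B", "C", "D"])
    nx.set_edge_attributes(g, 1.0, "weight")
    return g
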