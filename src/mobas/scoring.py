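"""The three subnetwork scoring schemes.

* ``node`` — aggregate node score σ_N(Q) = (Σ_{u∈Q} r_u) / √|Q|, the
  jActiveModules-style baseline that ignores the degree of connectivity.
* ``linear`` — λ-weighted combination of normalized edge-weight density and
  the node aggregate, σ_L(Q) = λ·Σw/√C(|Q|,2) + (1−λ)·Σr/√|Q|.
* ``mobas`` — the modularity-based score σ_M(Q) = Σ over unordered pairs
  {u,v} ⊆ Q of (s_uv − r̂_uv), where s_uv = w(u,v)·r_u·r_v for edges (0 for
  non-edges) and r̂_uv is the empirical background pair association.  A pair
  of proteins that do not interact contributes a pure penalty of −r̂_uv, so
  dense, strongly associated subgraphs are favored without a tunable
  size/connectivity trade-off parameter.

Pair sums run over unordered distinct pairs (no self-pairs), matching the
C(|Q|,2) normalizer of the linear scheme.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping

import networkx as nx

from .association import BackgroundProfile, GeneScoreProfile

SCHEMES = ("node", "linear", "mobas")

__all__ = [
    "SCHEMES",
    "ScoringContext",
    "Subnetwork",
    "pair_association",
    "score_node_based",
    "score_linear",
    "score_mobas",
    "score",
    "score_delta",
]


@dataclass
class ScoringContext:
    """Everything a scheme needs: gene scores, network weights, background, λ."""

    scores: GeneScoreProfile | Mapping[str, float]
    network: nx.Graph
    background: BackgroundProfile | None = None
    scheme: str = "mobas"
    lam: float = 0.5

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}, got {self.scheme!r}")
        if not (0.0 <= self.lam <= 1.0):
            raise ValueError("lambda must lie in [0, 1]")
        if self.scheme == "mobas" and self.background is None:
            raise ValueError("the modularity-based scheme requires a background profile")

    def r(self, gene: str) -> float:
        return self.scores[gene]

    def w(self, u: str, v: str) -> float:
        data = self.network.get_edge_data(u, v)
        if data is None:
            return 0.0
        return data.get("weight", 1.0)

    def rhat(self, u: str, v: str) -> float:
        if self.background is None:
            raise ValueError("no background profile attached to this context")
        return self.background.pair_score(u, v)


@dataclass
class Subnetwork:
    """A discovered module: node set, scheme-tagged score, seed and rank."""

    nodes: tuple[str, ...]
    score: float
    scheme: str
    seed: str | None = None
    rank: int | None = None

    def __post_init__(self) -> None:
        if not self.nodes:
            raise ValueError("a subnetwork must contain at least one node")

    @property
    def size(self) -> int:
        return len(self.nodes)

    @property
    def node_set(self) -> frozenset[str]:
        return frozenset(self.nodes)


def pair_association(u: str, v: str, ctx: ScoringContext) -> float:
    """s_uv = w(u,v)·r_u·r_v for interacting pairs, 0 otherwise."""
    if u == v:
        raise ValueError("pair association is defined for distinct proteins")
    r_u, r_v = ctx.r(u), ctx.r(v)  # KeyError for unknown genes
    w = ctx.w(u, v)
    return w * r_u * r_v if w else 0.0


def _node_term(Q: Iterable[str], ctx: ScoringContext) -> float:
    members = sorted(Q)
    if not members:
        raise ValueError("subnetwork must be non-empty")
    total = 0.0
    for g in members:
        total += ctx.r(g)
    return total / math.sqrt(len(members))


def _edge_sum(Q: Iterable[str], ctx: ScoringContext) -> float:
    # sorted-pair iteration keeps the summation order deterministic
    members = sorted(set(Q))
    total = 0.0
    for u, v in combinations(members, 2):
        total += ctx.w(u, v)
    return total


def score_node_based(Q: Iterable[str], ctx: ScoringContext) -> float:
    """σ_N(Q) = (Σ_{u∈Q} r_u) / √|Q|."""
    return _node_term(Q, ctx)


def score_linear(Q: Iterable[str], ctx: ScoringContext) -> float:
    """σ_L(Q) = λ·Σw/√C(|Q|,2) + (1−λ)·σ_N(Q); the edge term is 0 for |Q| < 2."""
    members = set(Q)
    if not members:
        raise ValueError("subnetwork must be non-empty")
    k = len(members)
    if k >= 2:
        edge_term = _edge_sum(members, ctx) / math.sqrt(math.comb(k, 2))
    else:
        edge_term = 0.0
    return ctx.lam * edge_term + (1.0 - ctx.lam) * _node_term(members, ctx)


def score_mobas(Q: Iterable[str], ctx: ScoringContext) -> float:
    """σ_M(Q) = Σ over unordered pairs {u,v} ⊆ Q of (s_uv − r̂_uv); singletons score 0."""
    members = sorted(set(Q))
    if not members:
        raise ValueError("subnetwork must be non-empty")
    total = 0.0
    for u, v in combinations(members, 2):
        total += pair_association(u, v, ctx) - ctx.rhat(u, v)
    return total


_SCORERS = {"node": score_node_based, "linear": score_linear, "mobas": score_mobas}


def score(Q: Iterable[str], ctx: ScoringContext) -> float:
    """Score ``Q`` under the context's scheme."""
    return _SCORERS[ctx.scheme](Q, ctx)


def score_delta(
    current: Subnetwork | Iterable[str], candidate: str, ctx: ScoringContext
) -> float:
    """Score gain from adding ``candidate`` to the current subnetwork.

    Uses the closed-form increment for each scheme; equal (to numerical
    precision) to re-scoring the enlarged set from scratch.
    """
    members = set(current.nodes) if isinstance(current, Subnetwork) else set(current)
    if candidate in members:
        raise ValueError(f"candidate {candidate!r} is already in the subnetwork")
    k = len(members)
    r_c = ctx.r(candidate)
    node_sum = sum(ctx.r(g) for g in sorted(members))
    node_delta = (node_sum + r_c) / math.sqrt(k + 1) - node_sum / math.sqrt(k)

    if ctx.scheme == "node":
        return node_delta
    if ctx.scheme == "linear":
        w_sum = _edge_sum(members, ctx)
        w_new = sum(
            data.get("weight", 1.0)
            for u, data in ctx.network.adj[candidate].items()
            if u in members
        ) if candidate in ctx.network else 0.0
        old_edge = w_sum / math.sqrt(math.comb(k, 2)) if k >= 2 else 0.0
        new_edge = (w_sum + w_new) / math.sqrt(math.comb(k + 1, 2))
        return ctx.lam * (new_edge - old_edge) + (1.0 - ctx.lam) * node_delta
    # mobas: only pairs involving the candidate change
    gain = 0.0
    for u in sorted(members):
        gain += pair_association(u, candidate, ctx) - ctx.rhat(u, candidate)
    return gain
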