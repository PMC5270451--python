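"""Greedy seed-and-extend discovery of high-scoring subnetworks.

The search seeds at the remaining protein with the highest disease-association
score, repeatedly adds the neighboring protein with the best strictly positive
score improvement, and restricts the candidate scan to the two-hop locality of
the seed (computed once, on the network as it stands when the seed is picked).
When no candidate improves the score, the module is recorded, its proteins are
removed, and the search restarts from the next-best remaining seed until the
network is exhausted.  Identified modules are ranked by score (ties broken by
the lexicographically smaller seed).
"""

from __future__ import annotations

import logging
import math
from typing import Iterable

import networkx as nx
import numpy as np

from .scoring import ScoringContext, Subnetwork, score as _full_score

logger = logging.getLogger(__name__)

__all__ = ["grow_module", "find_all_modules"]

# Above this many genes the all-pairs background matrix is not materialized
# and the search falls back to per-pair background dot products.
_GRAM_LIMIT = 4000


class _SearchEngine:
    """Indexed view of a scoring context for fast repeated module growth."""

    def __init__(self, network: nx.Graph, ctx: ScoringContext):
        self.ctx = ctx
        self.scheme = ctx.scheme
        self.lam = ctx.lam
        self.adj: dict[str, dict[str, float]] = {
            u: {v: data.get("weight", 1.0) for v, data in nbrs.items()}
            for u, nbrs in network.adj.items()
        }
        self.r = {g: float(ctx.r(g)) for g in network.nodes}
        self.bg = ctx.background
        self._use_gram = False
        if self.scheme == "mobas":
            if self.bg is None:
                raise ValueError("mobas scoring requires a background profile")
            if len(self.bg.genes) <= _GRAM_LIMIT:
                self.gram = self.bg.gram
                self._use_gram = True

    def _two_hop(self, seed: str, alive: set[str]) -> set[str]:
        one = {v for v in self.adj[seed] if v in alive}
        out = {seed} | one
        for u in one:
            out.update(v for v in self.adj[u] if v in alive)
        return out

    def _bg_row(self, gene: str):
        if self._use_gram:
            return self.gram[self.bg.index_of(gene)]
        return self.bg.column(gene)

    def grow(self, seed: str, alive: set[str] | None = None) -> Subnetwork:
        if seed not in self.adj:
            raise KeyError(f"seed node {seed!r} not in network")
        if alive is None:
            alive = set(self.adj)
        locality = self._two_hop(seed, alive)

        members: list[str] = [seed]
        member_set: set[str] = {seed}
        node_sum = self.r[seed]
        edge_sum = 0.0
        bg_acc = None
        if self.scheme == "mobas":
            bg_acc = np.array(self._bg_row(seed), dtype=np.float64)

        candidates = {v for v in self.adj[seed] if v in locality and v in alive}
        while candidates:
            best: str | None = None
            best_gain = 0.0
            k = len(member_set)
            sqrt_k = math.sqrt(k)
            sqrt_k1 = math.sqrt(k + 1)
            for c in sorted(candidates):
                r_c = self.r[c]
                if self.scheme == "node":
                    gain = (node_sum + r_c) / sqrt_k1 - node_sum / sqrt_k
                elif self.scheme == "linear":
                    w_new = sum(
                        w for u, w in self.adj[c].items() if u in member_set
                    )
                    old_edge = (
                        edge_sum / math.sqrt(math.comb(k, 2)) if k >= 2 else 0.0
                    )
                    new_edge = (edge_sum + w_new) / math.sqrt(math.comb(k + 1, 2))
                    node_delta = (node_sum + r_c) / sqrt_k1 - node_sum / sqrt_k
                    gain = self.lam * (new_edge - old_edge) + (1.0 - self.lam) * node_delta
                else:  # mobas
                    s_part = 0.0
                    for u, w in self.adj[c].items():
                        if u in member_set:
                            s_part += w * self.r[u] * r_c
                    if self._use_gram:
                        bg_part = bg_acc[self.bg.index_of(c)]
                    else:
                        bg_part = float(bg_acc @ self.bg.column(c)) / self.bg.n_permutations
                    gain = s_part - bg_part
                if gain > best_gain:  # strict improvement; sorted scan keeps
                    best = c            # the lexicographically smaller id on ties
                    best_gain = gain
            if best is None:
                break
            members.append(best)
            member_set.add(best)
            node_sum += self.r[best]
            edge_sum += sum(w for u, w in self.adj[best].items() if u in member_set if u != best)
            if bg_acc is not None:
                bg_acc = bg_acc + self._bg_row(best)
            candidates.discard(best)
            candidates |= {
                v
                for v in self.adj[best]
                if v in locality and v in alive and v not in member_set
            }
            candidates &= alive
        final = _full_score(member_set, self.ctx)
        return Subnetwork(
            nodes=tuple(members), score=final, scheme=self.scheme, seed=seed
        )


def grow_module(network: nx.Graph, ctx: ScoringContext, seed: str) -> Subnetwork:
    """Grow a single module from ``seed`` on the given network.

    Candidates must be adjacent to the current subnetwork and inside the
    seed's two-hop locality; additions require a strictly positive score gain;
    ties go to the lexicographically smaller gene id.
    """
    return _SearchEngine(network, ctx).grow(seed)


def find_all_modules(
    network: nx.Graph, ctx: ScoringContext, min_size: int = 1
) -> list[Subnetwork]:
    """Exhaust the network into ranked, disjoint high-scoring modules.

    Seeds are taken in decreasing order of gene score (ties by id); each
    discovered module's proteins are removed before the next seed is chosen,
    so the returned node sets partition V.  Output is sorted by score
    descending with ranks 1..K (ties by smaller seed id); ``min_size`` filters
    the returned list after ranking.
    """
    engine = _SearchEngine(network, ctx)
    alive = set(network.nodes)
    order = sorted(alive, key=lambda g: (-engine.r[g], g))
    modules: list[Subnetwork] = []
    for seed in order:
        if seed not in alive:
            continue
        module = engine.grow(seed, alive)
        modules.append(module)
        alive -= module.node_set
    modules.sort(key=lambda m: (-m.score, m.seed or ""))
    ranked: list[Subnetwork] = []
    for rank, module in enumerate(modules, start=1):
        module.rank = rank
        ranked.append(module)
    if min_size > 1:
        return [m for m in ranked if m.size >= min_size]
    return ranked
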