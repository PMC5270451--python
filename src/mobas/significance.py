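"""Empirical significance of discovered modules and evaluation utilities.

Because the number of hypotheses equals the number of potential connected
subnetworks, significance is assessed with rank-pooled empirical q-values:
for the rank-i observed module, pool the top-i module scores from each of M
randomized datasets and report the fraction at least as high as the observed
score.  Two null models are used — permuted phenotypes (breaking the
genotype–phenotype relationship) and degree-preserving network rewiring
(breaking functional association) — and a module is called significant only
when the maximum of its two q-values falls below the threshold (default 0.05).

Also here: the hypergeometric overlap and 2x2 chi-square evaluators used for
cross-cohort reproducibility, and the sample-subsampling / rank-overlap
utilities used for robustness analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .association import (
    BackgroundProfile,
    GeneScoreProfile,
    GeneScorer,
    GenotypeDataset,
)
from .io import SnpGeneMap
from .network import rewire_preserving_degrees
from .scoring import ScoringContext, Subnetwork
from .search import find_all_modules

logger = logging.getLogger(__name__)

__all__ = [
    "SignificanceResult",
    "run_null",
    "empirical_qvalues",
    "combine_significance",
    "hypergeometric_overlap",
    "chi_square_2x2",
    "subsample_dataset",
    "rank_overlap",
    "RankOverlap",
]


@dataclass
class SignificanceResult:
    """Per-module q-values under both null models and the combined call."""

    q_pheno: float
    q_net: float
    q_combined: float
    significant: bool
    rank: int | None = None
    score: float | None = None


def run_null(
    model: str,
    *,
    network: nx.Graph,
    m: int = 100,
    seed: int | np.random.SeedSequence = 0,
    scores: GeneScoreProfile | Mapping[str, float] | None = None,
    background: BackgroundProfile | None = None,
    scheme: str = "mobas",
    lam: float = 0.5,
    dataset: GenotypeDataset | None = None,
    snp_gene_map: SnpGeneMap | None = None,
    log_base: str = "e",
    permuted_profiles: Sequence[GeneScoreProfile] | None = None,
    swaps_per_edge: int = 10,
) -> list[list[float]]:
    """Ranked module scores from ``m`` randomized datasets.

    ``model='pheno'`` recomputes gene scores under permuted phenotypes (from
    ``dataset`` + ``snp_gene_map``, or from pre-computed ``permuted_profiles``)
    and searches the original network; ``model='net'`` keeps the observed
    scores and searches freshly rewired networks.  For the modularity scheme
    the background profile computed from the original dataset is reused across
    null runs.  Reproducible given the seed.
    """
    if m < 1:
        raise ValueError("m must be at least 1")
    if model not in ("pheno", "net"):
        raise ValueError("model must be 'pheno' or 'net'")
    seed_seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = seed_seq.spawn(m)

    results: list[list[float]] = []
    if model == "pheno":
        if permuted_profiles is not None:
            if len(permuted_profiles) < m:
                raise ValueError(
                    f"need at least {m} permuted profiles, got {len(permuted_profiles)}"
                )
            profiles = list(permuted_profiles[:m])
        else:
            if dataset is None or snp_gene_map is None:
                raise ValueError(
                    "phenotype null needs a dataset and SNP-gene map "
                    "(or pre-computed permuted profiles)"
                )
            scorer = GeneScorer(dataset, snp_gene_map, list(network.nodes), log_base)
            profiles = []
            for child in children:
                rng = np.random.default_rng(child)
                profiles.append(scorer.profile(rng.permutation(dataset.phenotype)))
        for i, profile in enumerate(profiles):
            ctx = ScoringContext(
                scores=profile,
                network=network,
                background=background,
                scheme=scheme,
                lam=lam,
            )
            modules = find_all_modules(network, ctx)
            results.append([mod.score for mod in modules])
            logger.debug("pheno null run %d/%d: %d modules", i + 1, m, len(modules))
    else:
        if scores is None:
            raise ValueError("network null needs the observed gene scores")
        n_swaps = swaps_per_edge * network.number_of_edges()
        for i, child in enumerate(children):
            random_net = rewire_preserving_degrees(network, n_swaps=n_swaps, seed=child)
            ctx = ScoringContext(
                scores=scores,
                network=random_net,
                background=background,
                scheme=scheme,
                lam=lam,
            )
            modules = find_all_modules(random_net, ctx)
            results.append([mod.score for mod in modules])
            logger.debug("net null run %d/%d: %d modules", i + 1, m, len(modules))
    return results


def empirical_qvalues(
    observed: Sequence[float], nulls: Sequence[Sequence[float]]
) -> list[float]:
    """Rank-pooled empirical q-value for each observed module score.

    For the rank-i observed score, pool the top min(i, length) scores from
    each null run and return the fraction that are at least as high.  When a
    null run yields fewer than i modules its whole list is pooled and the
    denominator counts the values actually pooled.
    """
    if len(observed) == 0:
        raise ValueError("observed score list must be non-empty")
    if len(nulls) == 0:
        raise ValueError("at least one null score list is required")
    sorted_nulls = [np.sort(np.asarray(lst, dtype=np.float64))[::-1] for lst in nulls]
    lengths = np.array([len(a) for a in sorted_nulls])
    qvalues: list[float] = []
    for i, s in enumerate(observed, start=1):
        numerator = 0
        denominator = 0
        for arr, length in zip(sorted_nulls, lengths):
            pooled = min(i, length)
            # arr is descending: elements >= s form a prefix
            n_ge = int(np.searchsorted(-arr, -s, side="right"))
            numerator += min(n_ge, pooled)
            denominator += pooled
        qvalues.append(numerator / denominator if denominator else 0.0)
    return qvalues


def combine_significance(
    q_pheno: float, q_net: float, threshold: float = 0.05
) -> SignificanceResult:
    """Combined call: q = max of the two null-model q-values, significant iff q < threshold."""
    for name, q in (("q_pheno", q_pheno), ("q_net", q_net)):
        if not (0.0 <= q <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1], got {q}")
    q_combined = max(q_pheno, q_net)
    return SignificanceResult(
        q_pheno=q_pheno,
        q_net=q_net,
        q_combined=q_combined,
        significant=q_combined < threshold,
    )


def hypergeometric_overlap(
    set_a: Iterable[str],
    set_b: Iterable[str],
    universe: Iterable[str],
    n_tests: int = 1,
) -> float:
    """Bonferroni-corrected upper-tail hypergeometric overlap probability.

    P(overlap >= observed) for |A∩B| when drawing |B| genes from the universe,
    multiplied by ``n_tests`` and capped at 1.
    """
    a, b, u = set(set_a), set(set_b), set(universe)
    if not (a <= u and b <= u):
        raise ValueError("both gene sets must be contained in the universe")
    if n_tests < 1:
        raise ValueError("n_tests must be at least 1")
    overlap = len(a & b)
    p = float(stats.hypergeom.sf(overlap - 1, len(u), len(a), len(b)))
    return min(1.0, n_tests * p)


def chi_square_2x2(table: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) for a 2x2 table.

    Computed by the closed form n·(ad−bc)² / ((a+b)(c+d)(a+c)(b+d)).
    """
    t = np.asarray(table, dtype=np.float64)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    a, b = t[0]
    c, d = t[1]
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise ValueError("all table margins must be positive")
    n = t.sum()
    statistic = n * (a * d - b * c) ** 2 / math.prod(margins)
    p_value = float(stats.chi2.sf(statistic, df=1))
    return float(statistic), p_value


def subsample_dataset(
    dataset: GenotypeDataset,
    keep_fraction: float,
    seed: int | np.random.SeedSequence = 0,
) -> GenotypeDataset:
    """Subsample cases and controls independently, preserving their proportion.

    Keeps round(keep_fraction · group size) samples per phenotype group,
    without replacement; raises if a group would be emptied.
    """
    if not (0.0 < keep_fraction <= 1.0):
        raise ValueError("keep_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    kept: list[np.ndarray] = []
    for label in (1, 0):
        group = np.flatnonzero(dataset.phenotype == label)
        n_keep = int(round(keep_fraction * len(group)))
        if n_keep == 0:
            raise ValueError(
                f"keep_fraction {keep_fraction} empties the "
                f"{'case' if label else 'control'} group"
            )
        kept.append(np.sort(rng.choice(group, size=n_keep, replace=False)))
    indices = np.sort(np.concatenate(kept))
    return dataset.subset_samples(indices)


@dataclass
class RankOverlap:
    """Best-matching test module for one reference module."""

    best_rank: int
    overlap: int
    jaccard: float


def rank_overlap(
    reference_modules: Sequence[Subnetwork],
    test_modules: Sequence[Subnetwork],
) -> dict[int, RankOverlap]:
    """For each reference module, the test-module rank with maximal overlap.

    Ties are broken by larger Jaccard index, then by smaller rank.  A
    reference module disjoint from every test module maps to the
    smallest-rank test module with overlap 0 (flagged by ``overlap == 0``).
    """
    if not reference_modules or not test_modules:
        raise ValueError("both module lists must be non-empty")
    mapping: dict[int, RankOverlap] = {}
    for ref in reference_modules:
        ref_rank = ref.rank if ref.rank is not None else len(mapping) + 1
        ref_set = ref.node_set
        best: RankOverlap | None = None
        for pos, test in enumerate(test_modules, start=1):
            test_rank = test.rank if test.rank is not None else pos
            inter = len(ref_set & test.node_set)
            union = len(ref_set | test.node_set)
            jac = inter / union if union else 0.0
            candidate = RankOverlap(best_rank=test_rank, overlap=inter, jaccard=jac)
            if (
                best is None
                or candidate.overlap > best.overlap
                or (candidate.overlap == best.overlap and candidate.jaccard > best.jaccard)
                or (
                    candidate.overlap == best.overlap
                    and candidate.jaccard == best.jaccard
                    and candidate.best_rank < best.best_rank
                )
            ):
                best = candidate
        mapping[ref_rank] = best  # type: ignore[assignment]
    return mapping
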