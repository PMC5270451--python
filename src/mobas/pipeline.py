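"""End-to-end orchestration: gene scoring → background → search → significance.

Two entry points cover the two input modes:

* :func:`analyze_dataset` starts from raw genotypes (or a synthetic dataset)
  and generates its own phenotype permutations for the background and the
  phenotype null model.
* :func:`analyze_files` starts from p-value files (observed ``.assoc``, the
  SNP→gene map, the PPI edge list, and a set of permuted-phenotype ``.assoc``
  files).  With p-value-only inputs the supplied permuted set is the only
  source of phenotype randomization, so its first N files feed the background
  and its first M files feed the phenotype null model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

from .association import (
    BackgroundProfile,
    GeneScoreProfile,
    GeneScorer,
    GenotypeDataset,
    gene_scores,
)
from .io import ModuleReport, SnpGeneMap, read_assoc
from .scoring import ScoringContext, Subnetwork
from .search import find_all_modules
from .significance import (
    SignificanceResult,
    combine_significance,
    empirical_qvalues,
    run_null,
)

logger = logging.getLogger(__name__)

__all__ = ["AnalysisResult", "analyze_dataset", "analyze_files", "reports_from_modules"]


@dataclass
class AnalysisResult:
    """Ranked modules with their significance calls and provenance."""

    modules: list[Subnetwork]
    significance: list[SignificanceResult] | None
    profile: GeneScoreProfile
    background: BackgroundProfile | None
    scheme: str
    m_null: int | None = None

    @property
    def reports(self) -> list[ModuleReport]:
        return reports_from_modules(self.modules, self.significance, self.scheme)

    def significant_modules(self) -> list[Subnetwork]:
        if self.significance is None:
            return []
        return [
            mod
            for mod, sig in zip(self.modules, self.significance)
            if sig.significant
        ]


def reports_from_modules(
    modules: Sequence[Subnetwork],
    significance: Sequence[SignificanceResult] | None = None,
    scheme: str | None = None,
) -> list[ModuleReport]:
    reports = []
    for i, mod in enumerate(modules):
        sig = significance[i] if significance is not None else None
        reports.append(
            ModuleReport(
                rank=mod.rank if mod.rank is not None else i + 1,
                size=mod.size,
                score=mod.score,
                genes=list(mod.nodes),
                scheme=scheme or mod.scheme,
                q_pheno=sig.q_pheno if sig else None,
                q_net=sig.q_net if sig else None,
                q_combined=sig.q_combined if sig else None,
            )
        )
    return reports


def _significance_from_nulls(
    modules: Sequence[Subnetwork],
    nulls_pheno: list[list[float]],
    nulls_net: list[list[float]],
    q_threshold: float,
) -> list[SignificanceResult]:
    observed = [mod.score for mod in modules]
    q_pheno = empirical_qvalues(observed, nulls_pheno)
    q_net = empirical_qvalues(observed, nulls_net)
    results = []
    for mod, qp, qn in zip(modules, q_pheno, q_net):
        sig = combine_significance(qp, qn, threshold=q_threshold)
        sig.rank = mod.rank
        sig.score = mod.score
        results.append(sig)
    return results


def analyze_dataset(
    dataset: GenotypeDataset,
    snp_gene_map: SnpGeneMap,
    network: nx.Graph,
    *,
    scheme: str = "mobas",
    lam: float = 0.5,
    n_background: int = 100,
    m_null: int = 100,
    seed: int = 0,
    q_threshold: float = 0.05,
    swaps_per_edge: int = 10,
    log_base: str = "e",
    min_size: int = 1,
    significance: bool = True,
) -> AnalysisResult:
    """Full pipeline from genotypes: score genes, search, assess significance.

    All randomness (background permutations, phenotype-null permutations,
    network rewiring) derives from ``seed``.
    """
    root = np.random.SeedSequence(seed)
    bg_seed, pheno_seed, net_seed = root.spawn(3)
    genes = list(network.nodes)
    scorer = GeneScorer(dataset, snp_gene_map, genes, log_base)
    profile = scorer.profile()
    background = None
    if scheme == "mobas":
        background = scorer.background(n_background, seed=bg_seed)
    ctx = ScoringContext(
        scores=profile, network=network, background=background, scheme=scheme, lam=lam
    )
    modules = find_all_modules(network, ctx, min_size=1)

    sig_results = None
    if significance:
        nulls_pheno = run_null(
            "pheno",
            network=network,
            m=m_null,
            seed=pheno_seed,
            background=background,
            scheme=scheme,
            lam=lam,
            dataset=dataset,
            snp_gene_map=snp_gene_map,
            log_base=log_base,
        )
        nulls_net = run_null(
            "net",
            network=network,
            m=m_null,
            seed=net_seed,
            scores=profile,
            background=background,
            scheme=scheme,
            lam=lam,
            swaps_per_edge=swaps_per_edge,
        )
        sig_results = _significance_from_nulls(modules, nulls_pheno, nulls_net, q_threshold)

    if min_size > 1:
        keep = [i for i, mod in enumerate(modules) if mod.size >= min_size]
        modules = [modules[i] for i in keep]
        if sig_results is not None:
            sig_results = [sig_results[i] for i in keep]
    return AnalysisResult(
        modules=modules,
        significance=sig_results,
        profile=profile,
        background=background,
        scheme=scheme,
        m_null=m_null if significance else None,
    )


def _profile_from_assoc(
    assoc_path: str | Path,
    snp_gene_map: SnpGeneMap,
    genes: Sequence[str],
    log_base: str,
) -> GeneScoreProfile:
    records = read_assoc(assoc_path)
    pvalues = {rec.snp_id: rec.p_value for rec in records}
    restricted = snp_gene_map.restrict_to_snps(pvalues)
    return gene_scores(pvalues, restricted, genes, log_base)


def analyze_files(
    assoc_path: str | Path,
    snp_gene_map: SnpGeneMap,
    network: nx.Graph,
    permuted_assoc_paths: Sequence[str | Path] | None = None,
    *,
    scheme: str = "mobas",
    lam: float = 0.5,
    n_background: int = 100,
    m_null: int = 100,
    seed: int = 0,
    q_threshold: float = 0.05,
    swaps_per_edge: int = 10,
    log_base: str = "e",
    min_size: int = 1,
    significance: bool = True,
) -> AnalysisResult:
    """Full pipeline from p-value files.

    The permuted ``.assoc`` set supplies both the background (first
    ``n_background`` files) and the phenotype null (first ``m_null`` files);
    it is required for the modularity scheme and, when significance is
    requested, for the phenotype null model.
    """
    genes = list(network.nodes)
    profile = _profile_from_assoc(assoc_path, snp_gene_map, genes, log_base)

    permuted_profiles: list[GeneScoreProfile] = []
    if permuted_assoc_paths:
        for path in permuted_assoc_paths:
            permuted_profiles.append(
                _profile_from_assoc(path, snp_gene_map, genes, log_base)
            )

    background = None
    if scheme == "mobas":
        if len(permuted_profiles) < 1:
            raise ValueError(
                "the modularity scheme requires permuted .assoc files "
                "to build the background distribution"
            )
        n_bg = min(n_background, len(permuted_profiles))
        if n_bg < n_background:
            logger.warning(
                "only %d permuted files available for a background of %d",
                len(permuted_profiles),
                n_background,
            )
        matrix = np.vstack(
            [prof.as_array(genes) for prof in permuted_profiles[:n_bg]]
        )
        background = BackgroundProfile(genes=genes, matrix=matrix, log_base=log_base)

    ctx = ScoringContext(
        scores=profile, network=network, background=background, scheme=scheme, lam=lam
    )
    modules = find_all_modules(network, ctx, min_size=1)

    sig_results = None
    if significance:
        if not permuted_profiles:
            raise ValueError(
                "significance assessment needs permuted .assoc files "
                "for the phenotype null model"
            )
        m_eff = min(m_null, len(permuted_profiles))
        if m_eff < m_null:
            logger.warning(
                "only %d permuted files available for %d phenotype-null runs",
                len(permuted_profiles),
                m_null,
            )
        nulls_pheno = run_null(
            "pheno",
            network=network,
            m=m_eff,
            seed=seed,
            background=background,
            scheme=scheme,
            lam=lam,
            permuted_profiles=permuted_profiles,
        )
        nulls_net = run_null(
            "net",
            network=network,
            m=m_null,
            seed=seed,
            scores=profile,
            background=background,
            scheme=scheme,
            lam=lam,
            swaps_per_edge=swaps_per_edge,
        )
        sig_results = _significance_from_nulls(modules, nulls_pheno, nulls_net, q_threshold)

    if min_size > 1:
        keep = [i for i, mod in enumerate(modules) if mod.size >= min_size]
        modules = [modules[i] for i in keep]
        if sig_results is not None:
            sig_results = [sig_results[i] for i in keep]
    return AnalysisResult(
        modules=modules,
        significance=sig_results,
        profile=profile,
        background=background,
        scheme=scheme,
        m_null=m_null if significance else None,
    )
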