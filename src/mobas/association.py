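"""Case/control association analysis and gene-level disease scores.

SNP-level association uses the Cochran–Armitage trend test with additive
weights (0, 1, 2) on minor-allele dosages, complete-case per SNP.  Gene scores
are the maximum of ``-log(p)`` over the SNPs mapped to a gene's region of
interest (the coding region extended by a window, default 20 kb up- and
downstream); a gene with no mapped SNP scores 0 and stays in the network as a
neutral connector.

The permutation background for the modularity score is built by permuting the
phenotype labels N times, recomputing the gene-score profile on each permuted
dataset, and averaging per-pair products of permuted scores.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from functools import cached_property
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import SnpGeneMap, SnpRecord

logger = logging.getLogger(__name__)

MISSING = -1
"""Sentinel dosage for a missing genotype call."""

_P_FLOOR = 1e-300  # keeps -log(p) finite when chi2.sf underflows


@dataclass
class GenotypeDataset:
    """Case/control samples with per-SNP minor-allele dosages.

    ``genotypes`` has shape (n_snps, n_samples) with values in
    {0, 1, 2, MISSING}; ``phenotype`` is 0 (control) / 1 (case).
    Permuted and subsampled variants share the genotype matrix where possible.
    """

    samples: list[str]
    phenotype: np.ndarray
    genotypes: np.ndarray
    snps: list[SnpRecord]

    def __post_init__(self) -> None:
        self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.phenotype.shape != (len(self.samples),):
            raise ValueError("phenotype length must equal the sample count")
        if self.genotypes.shape != (len(self.snps), len(self.samples)):
            raise ValueError("genotype matrix must be (n_snps, n_samples)")
        if not np.isin(self.phenotype, (0, 1)).all():
            raise ValueError("phenotype values must be 0 (control) or 1 (case)")
        if self.n_cases == 0 or self.n_controls == 0:
            raise ValueError("dataset needs at least one case and one control")
        valid = np.isin(self.genotypes, (0, 1, 2, MISSING))
        if not valid.all():
            raise ValueError("dosages must be 0, 1, 2 or MISSING")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_cases(self) -> int:
        return int((self.phenotype == 1).sum())

    @property
    def n_controls(self) -> int:
        return int((self.phenotype == 0).sum())

    @property
    def snp_ids(self) -> list[str]:
        return [rec.snp_id for rec in self.snps]

    def missing_rates(self) -> np.ndarray:
        return (self.genotypes == MISSING).mean(axis=1)

    def mafs(self) -> np.ndarray:
        """Minor-allele frequency per SNP among non-missing calls."""
        observed = self.genotypes != MISSING
        n_alleles = 2.0 * observed.sum(axis=1)
        dosage_sum = np.where(observed, self.genotypes, 0).sum(axis=1)
        with np.errstate(invalid="ignore"):
            freq = np.where(n_alleles > 0, dosage_sum / n_alleles, 0.0)
        return np.minimum(freq, 1.0 - freq)

    @cached_property
    def _dosage_indicators(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        # float32 indicator matrices so genotype counts reduce to matmuls,
        # reused across phenotype permutations.
        return tuple(
            (self.genotypes == dosage).astype(np.float32) for dosage in (0, 1, 2)
        )

    def genotype_counts(
        self, phenotype: np.ndarray | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Per-SNP (n_snps, 3) genotype counts for cases and controls."""
        ph = self.phenotype if phenotype is None else np.asarray(phenotype)
        case_vec = (ph == 1).astype(np.float32)
        control_vec = (ph == 0).astype(np.float32)
        indicators = self._dosage_indicators
        case_counts = np.stack([ind @ case_vec for ind in indicators], axis=1)
        control_counts = np.stack([ind @ control_vec for ind in indicators], axis=1)
        return case_counts, control_counts

    def trend_pvalues(self, phenotype: np.ndarray | None = None) -> np.ndarray:
        """Cochran–Armitage trend p-value for every SNP (vectorized)."""
        case_counts, control_counts = self.genotype_counts(phenotype)
        return trend_test_from_counts(case_counts, control_counts)

    def with_phenotype(self, phenotype: np.ndarray) -> "GenotypeDataset":
        """A view of the dataset with a replacement phenotype vector."""
        new = GenotypeDataset.__new__(GenotypeDataset)
        new.samples = self.samples
        new.genotypes = self.genotypes
        new.snps = self.snps
        new.phenotype = np.asarray(phenotype, dtype=np.int8)
        if new.phenotype.shape != (len(self.samples),):
            raise ValueError("phenotype length must equal the sample count")
        # share the indicator cache: the genotype matrix is unchanged
        if "_dosage_indicators" in self.__dict__:
            new.__dict__["_dosage_indicators"] = self._dosage_indicators
        return new

    def subset_samples(self, indices: np.ndarray) -> "GenotypeDataset":
        indices = np.asarray(indices, dtype=int)
        return GenotypeDataset(
            samples=[self.samples[i] for i in indices],
            phenotype=self.phenotype[indices],
            genotypes=self.genotypes[:, indices],
            snps=list(self.snps),
        )

    def subset_snps(self, mask: np.ndarray) -> "GenotypeDataset":
        mask = np.asarray(mask)
        kept = [rec for rec, keep in zip(self.snps, mask) if keep]
        return GenotypeDataset(
            samples=list(self.samples),
            phenotype=self.phenotype.copy(),
            genotypes=self.genotypes[mask],
            snps=kept,
        )


def filter_snps(
    dataset: GenotypeDataset,
    max_missing: float = 0.10,
    min_maf: float = 0.05,
) -> GenotypeDataset:
    """QC filter: drop SNPs with missing rate > ``max_missing`` or MAF < ``min_maf``.

    Both comparisons are strict, so a SNP sitting exactly on a threshold is
    kept.  The sample set is unchanged; an empty result is permitted.
    """
    if not (0.0 <= max_missing <= 1.0 and 0.0 <= min_maf <= 1.0):
        raise ValueError("thresholds must lie in [0, 1]")
    missing = dataset.missing_rates()
    maf = dataset.mafs()
    keep = (missing <= max_missing) & (maf >= min_maf)
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info(
            "filter_snps: removed %d of %d SNPs (max_missing=%.3g, min_maf=%.3g)",
            n_removed,
            dataset.n_snps,
            max_missing,
            min_maf,
        )
    if not keep.any():
        logger.warning("filter_snps: no SNPs pass the filters")
    filtered = dataset.subset_snps(keep)
    filtered.snps = [
        replace(rec, missing_rate=float(mr), maf=float(mf))
        for rec, mr, mf in zip(filtered.snps, missing[keep], maf[keep])
    ]
    return filtered


def trend_test_from_counts(
    case_counts: np.ndarray, control_counts: np.ndarray
) -> np.ndarray:
    """Vectorized Cochran–Armitage trend test with additive weights (0, 1, 2).

    ``case_counts`` and ``control_counts`` are (..., 3) genotype-count arrays.
    SNPs with zero variance (all observed samples share one genotype, or one
    phenotype group is empty) get p = 1.
    """
    A = np.asarray(case_counts, dtype=np.float64)
    B = np.asarray(control_counts, dtype=np.float64)
    if A.shape[-1] != 3 or B.shape != A.shape:
        raise ValueError("expected matching (..., 3) genotype count arrays")
    if (A < 0).any() or (B < 0).any():
        raise ValueError("genotype counts must be non-negative")
    weights = np.array([0.0, 1.0, 2.0])
    totals = A + B
    n = totals.sum(axis=-1)
    n_cases = A.sum(axis=-1)
    n_controls = B.sum(axis=-1)
    t_stat = ((weights * (n_controls[..., None] * A - n_cases[..., None] * B))).sum(
        axis=-1
    )
    variance = (
        n_cases
        * n_controls
        / np.where(n > 0, n, 1.0)
        * (n * (weights**2 * totals).sum(axis=-1) - ((weights * totals).sum(axis=-1)) ** 2)
    )
    degenerate = variance <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(degenerate, 0.0, t_stat**2 / np.where(degenerate, 1.0, variance))
    p = stats.chi2.sf(chi2, df=1)
    p = np.where(degenerate, 1.0, p)
    return np.clip(p, _P_FLOOR, 1.0)


def trend_test(
    case_genotype_counts: Sequence[float], control_genotype_counts: Sequence[float]
) -> float:
    """Cochran–Armitage trend p-value for one SNP's 2x3 genotype table.

    Returns p = 1 (with a logged warning) when the statistic's variance is
    zero, e.g. when every observed sample carries the same genotype.
    """
    A = np.asarray(case_genotype_counts, dtype=np.float64)
    B = np.asarray(control_genotype_counts, dtype=np.float64)
    if A.sum() <= 0 or B.sum() <= 0:
        raise ValueError("both phenotype groups need a positive total count")
    p = trend_test_from_counts(A[None, :], B[None, :])[0]
    if p == 1.0:
        weights = np.array([0.0, 1.0, 2.0])
        totals = A + B
        n = totals.sum()
        var = n * (weights**2 * totals).sum() - ((weights * totals).sum()) ** 2
        if var <= 0:
            logger.warning("trend_test: zero genotype variance, returning p = 1")
    return float(p)


def map_snps_to_genes(
    snps: Sequence[SnpRecord],
    gene_coords: pd.DataFrame,
    window_bp: int = 20_000,
) -> SnpGeneMap:
    """Map SNPs to genes whose region of interest contains them.

    The region of interest is ``[start - window_bp, end + window_bp]`` on the
    gene's chromosome (1-based, boundary inclusive).  ``gene_coords`` needs
    columns ``gene``, ``chrom``, ``start``, ``end``.  A SNP may map to several
    overlapping genes; a SNP without coordinates raises.
    """
    required = {"gene", "chrom", "start", "end"}
    if not required.issubset(gene_coords.columns):
        raise ValueError(f"gene_coords must have columns {sorted(required)}")
    by_chrom = {str(c): g for c, g in gene_coords.groupby("chrom", sort=False)}

    pairs: list[tuple[str, str]] = []
    for rec in snps:
        if rec.chromosome is None or rec.position is None:
            raise ValueError(f"SNP {rec.snp_id} lacks coordinates required for mapping")
        group = by_chrom.get(str(rec.chromosome))
        if group is None:
            continue
        hit = (group["start"].to_numpy() - window_bp <= rec.position) & (
            rec.position <= group["end"].to_numpy() + window_bp
        )
        for gene in group.loc[hit, "gene"]:
            pairs.append((rec.snp_id, str(gene)))
    return SnpGeneMap(pairs)


@dataclass
class GeneScoreProfile:
    """Per-gene disease-association scores r_v = max over ROI SNPs of -log p."""

    scores: dict[str, float]
    log_base: str = "e"

    def __post_init__(self) -> None:
        if self.log_base not in ("e", "10"):
            raise ValueError("log_base must be 'e' or '10'")
        negative = [g for g, s in self.scores.items() if s < 0]
        if negative:
            raise ValueError(f"gene scores must be non-negative: {negative[:3]}")

    def __getitem__(self, gene: str) -> float:
        return self.scores[gene]

    def get(self, gene: str, default: float = 0.0) -> float:
        return self.scores.get(gene, default)

    def __contains__(self, gene: str) -> bool:
        return gene in self.scores

    @property
    def genes(self) -> list[str]:
        return list(self.scores)

    def as_array(self, order: Sequence[str]) -> np.ndarray:
        return np.array([self.scores[g] for g in order], dtype=np.float64)


def _neglog(p: np.ndarray | float, log_base: str) -> np.ndarray | float:
    logp = np.log(p) if log_base == "e" else np.log10(p)
    return -logp


def gene_scores(
    snp_pvalues: Mapping[str, float],
    snp_gene_map: SnpGeneMap,
    genes: Iterable[str],
    log_base: str = "e",
) -> GeneScoreProfile:
    """Gene score r_v = max over mapped SNPs of -log(p); unmapped genes score 0.

    Every SNP mapped to a requested gene must have a p-value; restrict the map
    first (``SnpGeneMap.restrict_to_snps``) if some SNPs were filtered out.
    """
    scores: dict[str, float] = {}
    for gene in genes:
        best = 0.0
        for snp in snp_gene_map.snps_of(gene):
            p = snp_pvalues[snp]
            best = max(best, float(_neglog(max(p, _P_FLOOR), log_base)))
        scores[gene] = best
    return GeneScoreProfile(scores=scores, log_base=log_base)


def permute_phenotypes(
    dataset: GenotypeDataset, n: int, seed: int | np.random.SeedSequence = 0
) -> list[GenotypeDataset]:
    """``n`` copies of the dataset with uniformly permuted phenotype labels.

    The genotype matrix is shared, case/control counts are preserved, and the
    sequence of permutations is reproducible given the seed.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    return [dataset.with_phenotype(rng.permutation(dataset.phenotype)) for _ in range(n)]


@dataclass
class BackgroundProfile:
    """Gene-score vectors from N phenotype permutations (Eq. background).

    ``matrix`` has shape (N, n_genes); column order follows ``genes``.  The
    background pair score r̂_uv is the mean over permutations of the product of
    the two genes' permuted scores.
    """

    genes: list[str]
    matrix: np.ndarray
    log_base: str = "e"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.genes):
            raise ValueError("matrix must be (N, n_genes)")
        if self.matrix.shape[0] < 1:
            raise ValueError("at least one permutation is required")
        self._index = {g: i for i, g in enumerate(self.genes)}

    @property
    def n_permutations(self) -> int:
        return int(self.matrix.shape[0])

    def column(self, gene: str) -> np.ndarray:
        return self.matrix[:, self._index[gene]]

    def pair_score(self, u: str, v: str) -> float:
        """r̂_uv = (Σ_i r_u^(i) r_v^(i)) / N; symmetric and non-negative."""
        i, j = self._index[u], self._index[v]
        return float(self.matrix[:, i] @ self.matrix[:, j] / self.n_permutations)

    @cached_property
    def gram(self) -> np.ndarray:
        """All-pairs background matrix (n_genes x n_genes); cached.

        Convenient for modest gene universes; for genome-scale networks use
        :meth:`pair_score`, which stays O(N) per pair with no quadratic memory.
        """
        return self.matrix.T @ self.matrix / self.n_permutations

    def index_of(self, gene: str) -> int:
        return self._index[gene]


def background_pair_score(u: str, v: str, background: BackgroundProfile) -> float:
    """Background disease association of the (u, v) interaction."""
    return background.pair_score(u, v)


class GeneScorer:
    """Precomputed SNP→gene index for fast repeated gene-score evaluation.

    Used wherever the same dataset is scored under many phenotype vectors
    (the Eq.-6 background and the phenotype-permutation null model).
    SNPs in the map but absent from the dataset are ignored.
    """

    def __init__(
        self,
        dataset: GenotypeDataset,
        snp_gene_map: SnpGeneMap,
        genes: Sequence[str],
        log_base: str = "e",
    ):
        self.dataset = dataset
        self.genes = list(genes)
        self.log_base = log_base
        snp_index = {s: i for i, s in enumerate(dataset.snp_ids)}
        gene_pos: list[int] = []
        snp_pos: list[int] = []
        for gi, gene in enumerate(self.genes):
            for snp in snp_gene_map.snps_of(gene):
                si = snp_index.get(snp)
                if si is not None:
                    gene_pos.append(gi)
                    snp_pos.append(si)
        self._gene_pos = np.asarray(gene_pos, dtype=np.intp)
        self._snp_pos = np.asarray(snp_pos, dtype=np.intp)

    def _score_vector(self, phenotype: np.ndarray | None) -> np.ndarray:
        p = self.dataset.trend_pvalues(phenotype)
        logp = np.asarray(_neglog(p, self.log_base))
        row = np.zeros(len(self.genes), dtype=np.float64)
        np.maximum.at(row, self._gene_pos, logp[self._snp_pos])
        return row

    def profile(self, phenotype: np.ndarray | None = None) -> GeneScoreProfile:
        row = self._score_vector(phenotype)
        return GeneScoreProfile(
            scores=dict(zip(self.genes, row.tolist())), log_base=self.log_base
        )

    def background(
        self, n: int, seed: int | np.random.SeedSequence = 0
    ) -> BackgroundProfile:
        """Background profile from ``n`` phenotype permutations."""
        if n < 1:
            raise ValueError("n must be at least 1")
        rng = np.random.default_rng(seed)
        rows = np.empty((n, len(self.genes)), dtype=np.float64)
        for i in range(n):
            rows[i] = self._score_vector(rng.permutation(self.dataset.phenotype))
        return BackgroundProfile(genes=list(self.genes), matrix=rows, log_base=self.log_base)
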