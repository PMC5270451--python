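"""Synthetic GWAS + PPI instances with a planted disease module.

The generator emulates the inputs of a case/control GWAS integrated with a
weighted interaction network, with known ground truth, so every stage of the
pipeline can be exercised without restricted cohort data:

* a configuration-model background network with a heavy-tailed ("powerlaw-ish")
  degree sequence and simple-graph repair by rejected stubs, mimicking the
  degree heterogeneity of real PPI networks;
* a planted module of ``n_planted`` genes wired to a requested internal edge
  density;
* Hardy–Weinberg genotypes at every SNP, with one causal SNP per planted gene
  whose case minor-allele frequency is shifted by a controllable effect size
  (an odds-ratio convenience converter is provided);
* gene coordinates and a SNP→gene map consistent with the 20 kb-window
  region-of-interest mapping.

What it deliberately does not model: linkage disequilibrium between SNPs,
population stratification, and quantitative phenotypes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .association import GenotypeDataset, map_snps_to_genes
from .io import SnpGeneMap, SnpRecord

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticSpec",
    "generate_network",
    "generate_genotypes",
    "make_fixture",
    "odds_ratio_to_maf_shift",
]

_GENE_SPACING = 200_000  # bp between gene starts; keeps 20 kb ROIs disjoint
_GENE_LENGTH = 50_000
_FIRST_GENE_START = 100_000


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic study.

    Defaults describe the standard evaluation condition: 500 genes with 5 SNPs
    each, a planted module of 10 genes at internal density 0.8, causal SNPs
    with case MAF 0.2 versus control MAF 0.1, and 500 cases / 500 controls.
    """

    n_genes: int = 500
    n_snps_per_gene: int = 5
    n_planted: int = 10
    planted_density: float = 0.8
    effect_size: float = 0.1  # case-minus-control MAF shift at causal SNPs
    causal_base_maf: float = 0.1  # control MAF at causal SNPs
    n_cases: int = 500
    n_controls: int = 500
    maf_range: tuple[float, float] = (0.05, 0.5)
    min_degree: int = 3
    degree_tail: float = 1.5  # Pareto shape; smaller = heavier tail
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted > self.n_genes:
            raise ValueError("planted module cannot exceed the gene count")
        if not (0.0 <= self.planted_density <= 1.0):
            raise ValueError("planted_density must lie in [0, 1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        case_maf = self.causal_base_maf + self.effect_size
        if not (0.0 < self.causal_base_maf < 1.0 and 0.0 < case_maf < 1.0):
            raise ValueError(
                "effect size pushes the causal allele frequency outside (0, 1)"
            )
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("need at least one case and one control")
        if self.n_snps_per_gene < 1:
            raise ValueError("each gene needs at least one SNP")

    @property
    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i + 1:0{width}d}" for i in range(self.n_genes)]

    @property
    def planted_gene_ids(self) -> list[str]:
        return self.gene_ids[: self.n_planted]

    def gene_coordinates(self) -> pd.DataFrame:
        starts = _FIRST_GENE_START + _GENE_SPACING * np.arange(self.n_genes)
        return pd.DataFrame(
            {
                "gene": self.gene_ids,
                "chrom": "1",
                "start": starts,
                "end": starts + _GENE_LENGTH,
            }
        )


def odds_ratio_to_maf_shift(odds_ratio: float, control_maf: float) -> float:
    """Case-minus-control MAF shift equivalent to a per-allele odds ratio."""
    if odds_ratio <= 0:
        raise ValueError("odds ratio must be positive")
    odds = control_maf / (1.0 - control_maf) * odds_ratio
    return odds / (1.0 + odds) - control_maf


def _seed_streams(spec: SyntheticSpec) -> dict[str, np.random.SeedSequence]:
    root = np.random.SeedSequence(spec.seed)
    names = ("network", "genotypes")
    return dict(zip(names, root.spawn(len(names))))


def generate_network(spec: SyntheticSpec) -> nx.Graph:
    """Configuration-model network with the planted genes wired densely.

    Degrees are ``min_degree`` plus a Pareto-tailed integer excess; stubs are
    matched randomly, with pairs that would create self-loops or parallel
    edges rejected back into the pool for a bounded number of repair rounds.
    Edge weights are drawn uniformly from [0.25, 1].  The planted module gets
    additional internal edges until it reaches the requested density.
    """
    rng = np.random.default_rng(_seed_streams(spec)["network"])
    genes = spec.gene_ids
    n = spec.n_genes
    cap = max(spec.min_degree + 1, n // 5)
    degrees = spec.min_degree + np.minimum(
        cap - spec.min_degree, rng.pareto(spec.degree_tail, size=n).astype(np.int64)
    )
    if degrees.sum() % 2:
        degrees[int(rng.integers(0, n))] += 1

    graph = nx.Graph()
    graph.add_nodes_from(genes)
    stubs = np.repeat(np.arange(n), degrees)
    for _ in range(20):  # repair rounds for rejected stubs
        if len(stubs) < 2:
            break
        rng.shuffle(stubs)
        leftovers: list[int] = []
        for a, b in zip(stubs[0::2], stubs[1::2]):
            u, v = genes[int(a)], genes[int(b)]
            if u == v or graph.has_edge(u, v):
                leftovers.extend((int(a), int(b)))
            else:
                graph.add_edge(u, v)
        if len(stubs) % 2:
            leftovers.append(int(stubs[-1]))
        stubs = np.asarray(leftovers)
    if len(stubs):
        logger.debug("generate_network: dropped %d unmatched stubs", len(stubs))

    planted = spec.planted_gene_ids
    possible = list(combinations(planted, 2))
    target = round(spec.planted_density * len(possible))
    present = sum(1 for u, v in possible if graph.has_edge(u, v))
    if present < target:
        missing = [(u, v) for u, v in possible if not graph.has_edge(u, v)]
        order = rng.permutation(len(missing))
        for idx in order[: target - present]:
            graph.add_edge(*missing[int(idx)])

    weights = rng.uniform(0.25, 1.0, size=graph.number_of_edges())
    for (u, v), w in zip(graph.edges, weights):
        graph[u][v]["weight"] = float(w)
    return graph


def generate_genotypes(
    spec: SyntheticSpec, seed: int | None = None
) -> tuple[GenotypeDataset, SnpGeneMap, pd.DataFrame]:
    """Synthetic genotypes, SNP→gene map, and gene coordinates.

    Non-causal SNPs draw Hardy–Weinberg dosages with a shared MAF in both
    phenotype groups; the first SNP of each planted gene is causal, with case
    MAF ``causal_base_maf + effect_size`` versus control ``causal_base_maf``.
    Passing ``seed`` overrides the spec's genotype stream, which is how
    independent cohorts are drawn from one study design.
    """
    stream = (
        _seed_streams(spec)["genotypes"]
        if seed is None
        else np.random.SeedSequence(seed)
    )
    rng = np.random.default_rng(stream)
    coords = spec.gene_coordinates()
    planted = set(spec.planted_gene_ids)

    n_samples = spec.n_cases + spec.n_controls
    phenotype = np.concatenate(
        [np.ones(spec.n_cases, dtype=np.int8), np.zeros(spec.n_controls, dtype=np.int8)]
    )
    case_mask = phenotype == 1

    snps: list[SnpRecord] = []
    rows: list[np.ndarray] = []
    lo, hi = spec.maf_range
    for gene, start in zip(spec.gene_ids, coords["start"]):
        for j in range(spec.n_snps_per_gene):
            snp_id = f"rs_{gene}_{j}"
            position = int(start) + 1_000 * j + 500
            causal = gene in planted and j == 0
            if causal:
                maf_case = spec.causal_base_maf + spec.effect_size
                maf_control = spec.causal_base_maf
                dosages = np.empty(n_samples, dtype=np.int8)
                dosages[case_mask] = rng.binomial(2, maf_case, size=spec.n_cases)
                dosages[~case_mask] = rng.binomial(2, maf_control, size=spec.n_controls)
            else:
                maf = rng.uniform(lo, hi)
                dosages = rng.binomial(2, maf, size=n_samples).astype(np.int8)
            snps.append(SnpRecord(snp_id=snp_id, chromosome="1", position=position))
            rows.append(dosages)

    dataset = GenotypeDataset(
        samples=[f"S{i + 1:05d}" for i in range(n_samples)],
        phenotype=phenotype,
        genotypes=np.vstack(rows),
        snps=snps,
    )
    snp_gene_map = map_snps_to_genes(snps, coords, window_bp=20_000)
    return dataset, snp_gene_map, coords


def make_fixture(
    spec: SyntheticSpec, out_dir: str | Path, n_permuted: int = 100
) -> dict[str, object]:
    """Write the four pipeline input files plus ground truth to ``out_dir``.

    Emits the observed ``.assoc`` (trend-test p-values computed from the
    synthetic genotypes), ``n_permuted`` permuted-phenotype ``.assoc`` files,
    the SNP→gene map, the weighted PPI edge list, and the planted-gene truth
    list.  Returns a manifest of the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    network = generate_network(spec)
    dataset, snp_gene_map, coords = generate_genotypes(spec)

    def _write_assoc(path: Path, pvalues: np.ndarray) -> None:
        with open(path, "w") as fh:
            fh.write("SNP\tCHR\tBP\tP\n")
            for rec, p in zip(dataset.snps, pvalues):
                fh.write(f"{rec.snp_id}\t{rec.chromosome}\t{rec.position}\t{p:.6g}\n")

    observed_path = out_dir / "observed.assoc"
    _write_assoc(observed_path, dataset.trend_pvalues())

    perm_rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(3)[2])
    permuted_paths: list[Path] = []
    for i in range(n_permuted):
        path = out_dir / f"permuted_{i + 1:03d}.assoc"
        _write_assoc(path, dataset.trend_pvalues(perm_rng.permutation(dataset.phenotype)))
        permuted_paths.append(path)

    map_path = out_dir / "snp_gene_map.tsv"
    with open(map_path, "w") as fh:
        for snp, gene in snp_gene_map.pairs:
            fh.write(f"{snp}\t{gene}\n")

    ppi_path = out_dir / "network.ppi.tsv"
    with open(ppi_path, "w") as fh:
        for u, v, data in network.edges(data=True):
            fh.write(f"{u}\t{v}\t{data['weight']:.6g}\n")

    truth_path = out_dir / "planted_genes.tsv"
    with open(truth_path, "w") as fh:
        for gene in spec.planted_gene_ids:
            fh.write(gene + "\n")

    coords_path = out_dir / "gene_coords.tsv"
    coords.to_csv(coords_path, sep="\t", index=False)

    return {
        "observed_assoc": observed_path,
        "permuted_assoc": permuted_paths,
        "snp_gene_map": map_path,
        "ppi": ppi_path,
        "truth": truth_path,
        "gene_coords": coords_path,
        "network": network,
        "dataset": dataset,
    }
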