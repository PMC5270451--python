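# Methods

## Problem and model

The package identifies disease-associated functional modules: connected
subnetworks of a weighted human PPI graph G = (V, E, w), w: E → (0, 1], whose
member genes carry strong case/control association signal and interact
densely. Inputs are either per-SNP association p-values (PLINK-style
`.assoc`) or a raw minor-allele dosage matrix with a dichotomous phenotype,
plus a SNP→gene map and the PPI edge list.

### SNP and gene scoring

With raw genotypes, per-SNP p-values come from the Cochran–Armitage trend
test with additive weights (0, 1, 2). Missing dosages are handled per SNP by
complete-case analysis; a SNP whose observed samples carry a single genotype
has zero trend variance and is assigned p = 1 with a warning. Reported
p-values are floored at 1e-300 so that log-transformed scores stay finite.
QC filters drop SNPs with missing rate strictly above 10% or MAF strictly
below 5% (both thresholds configurable; values sitting exactly on a threshold
are kept).

Gene scores aggregate the region of interest (coding region ± 20 kb, boundary
inclusive, multi-gene mapping allowed): r_v is the maximum of −log p over
mapped SNPs, natural log by default with base 10 selectable. All three
subnetwork schemes are monotone in r_v, so the base only rescales scores. A
gene with no mapped SNP scores 0 and remains in the network: under the
modularity score its pairs contribute s − r̂ = 0 − 0, so it acts as a neutral
connector, and removing it would distort connectivity for everything else.

### Subnetwork scores

* σ_N(Q) = Σ r_u / √|Q| — the node-aggregate baseline.
* σ_L(Q) = λ·Σ_{pairs} w(u,v)/√C(|Q|,2) + (1−λ)·σ_N(Q), λ ∈ [0, 1]
  (default 0.5). For |Q| = 1 the edge term is defined as 0. With λ = 0 the
  scheme reduces exactly (bit-for-bit) to σ_N.
* σ_M(Q) = Σ over unordered distinct pairs {u,v} ⊆ Q of (s_uv − r̂_uv),
  where s_uv = w(u,v)·r_u·r_v for edges and 0 otherwise, and r̂_uv is the
  background pair association. Singletons score 0. Pair sums run over
  unordered distinct pairs — no self-pairs — matching the C(|Q|,2)
  normalizer in σ_L. σ_M is deliberately not normalized by the standard
  deviation of the pair scores; the dependencies between pair terms would
  complicate the definition considerably for little practical gain.

The background is empirical: the phenotype vector is permuted N times
(default 100; the scaled-down synthetic evaluations use N = 20), gene scores
are recomputed on each permuted dataset, and
r̂_uv = (1/N) Σ_i r_u^(i)·r_v^(i). The public interface computes r̂ on
demand from the stored per-gene permuted score vectors (O(N) per pair, no
quadratic memory); for gene universes up to 4000 the search additionally
caches the full Gram matrix of permuted scores, which makes each candidate
evaluation O(1) and is what keeps the permutation-heavy evaluations fast.

### Search

Greedy seed-and-extend: seed at the highest-r_v remaining gene (ties to the
lexicographically smaller id), grow by repeatedly scanning genes that are
adjacent to the current module *and* inside the seed's two-hop locality,
adding the candidate with the largest strictly positive score gain (ties to
the smaller id), and stopping when no candidate improves the score. The
locality is computed once when the seed is chosen, on the network as it
stands then, and not recomputed as the module grows. Completed modules are
removed and the process repeats until the network is exhausted, so the
returned modules partition V. Gains are computed by closed-form increments
and the final score of each module is re-evaluated from scratch; the
increments are tested to agree with full re-scoring to 1e-9. Singleton
modules are recorded (they rank low and never reach significance); a minimum
reported size is available as a filter.

No backtracking or node removal happens during growth, and no stochastic
search (simulated annealing, genetic algorithms) is attempted: the searcher
is intentionally simple and shared across all three schemes so that score
comparisons carry no algorithmic bias.

### Significance

Because the number of hypotheses equals the number of potential connected
subnetworks, q-values are rank-pooled: for the rank-i observed module, the
top min(i, available) scores of each of M randomized datasets are pooled and
q_i is the fraction at least as high as the observed score. When a null run
yields fewer than i modules, its whole list is pooled and the denominator
counts the values actually pooled. q = 0 (observed beats every pooled score)
is rendered in reports as "< 1/(M·i)", its resolution bound.

Two null models (default M = 100 each; the synthetic evaluations use
M = 20): permuted phenotypes with re-scored genes on the original network,
and degree-preserving rewiring of the network with the observed scores. A
module is significant only if max(q_pheno, q_net) < threshold (default
0.05, strict). Under the modularity scheme the background r̂ computed from
the original dataset is reused inside the phenotype-permutation null runs:
recomputing N permutations inside each of M runs would be quadratic and
changes nothing in expectation.

Rewiring uses double-edge swaps: two edges (a,b), (c,d) on four distinct
nodes become (a,d), (c,b) unless that creates a self-loop or parallel edge;
weights travel with the swap, so the degree sequence, edge count and weight
multiset are preserved exactly. The default budget is 10·|E| attempted
swaps, a common mixing heuristic for edge-swap MCMC; accepted and attempted
counts are logged. Connectivity and per-node weighted degree (strength) are
not preserved.

### File-mode nulls

When the pipeline starts from p-value files rather than genotypes, the
supplied permuted-phenotype `.assoc` files are the only available source of
phenotype randomization, so the first N of them build the background and the
first M feed the phenotype null model. With raw genotypes (or synthetic
data) the background and the null runs use independent permutation streams.

## Synthetic studies

The generator emulates a case/control GWAS over a gene-level interaction
network with known ground truth.

* **Network**: configuration model on n_genes = 500 nodes with degrees
  min_degree (3) plus a Pareto(1.5) integer excess capped at n/5 — a
  heavy-tailed degree sequence resembling PPI degree heterogeneity. Stubs
  are matched randomly; pairs creating self-loops or parallel edges are
  rejected back into the pool for up to 20 repair rounds, then dropped.
  Edge weights are Uniform(0.25, 1), mimicking reliability scores that
  concentrate away from zero. The planted module (10 genes) receives extra
  internal edges until it reaches internal density 0.8.
* **Genotypes**: 5 SNPs per gene, 500 cases / 500 controls. Non-causal SNPs
  are Hardy–Weinberg with MAF ~ Uniform(0.05, 0.5), identical in both
  groups. One causal SNP per planted gene has control MAF 0.1 and case MAF
  0.2 (an additive allele-frequency shift of 0.1, roughly an odds ratio of
  2.25; a converter between the two parameterizations is provided). Genes
  sit 200 kb apart on one chromosome with SNPs inside the gene body, so the
  20 kb-window mapping assigns each SNP to exactly its own gene.
* **Not modeled**: linkage disequilibrium, population stratification,
  quantitative traits, genotyping missingness in the generated matrices.

Consequently, passing the synthetic evaluations shows that the scoring,
search and significance machinery recovers a dense associated subgraph under
clean polygenic-null background — it does not demonstrate robustness to LD
structure, confounding, or the weight biases of real interaction databases.

## Evaluation sizes and outcomes computed

The scaled-down evaluation conditions are N = 20 background permutations and
M = 20 null runs per null model, ten generator seeds per property: planted-
module recovery (top module carries ≥ 8/10 planted genes at combined
q < 0.05 in ≥ 8/10 seeds), null calibration (≤ 10% significant calls on
effect-free data), two-cohort reproducibility (Bonferroni-corrected
hypergeometric overlap p < 0.01, correcting for all module pairs), and
half-sample robustness (best-overlap rank 1 for the planted module in
≥ 7/10 seeds). `scripts/acceptance.py` recomputes single-seed instances of
each of these end to end; the test suite runs the ten-seed versions.

## Numerical and design choices

* Duplicate PPI rows keep the maximum weight; self-loops are dropped —
  conservative and deterministic resolution of conflicting interaction
  records.
* Sorted iteration orders everywhere scores are accumulated, so identical
  inputs give byte-identical outputs.
* Strict inequalities at all decision points (score gains, q-value
  threshold, QC thresholds) — documented per operation above.
* Subsampling for robustness analysis keeps round(f·group) cases and
  controls independently, preserving the case/control ratio.
* The Bonferroni factor for module-overlap tests defaults to
  (#modules_a × #modules_b), the number of pairwise comparisons available.
* Output floats are rendered with 6 significant digits; reports round-trip
  through the reader to that precision.

## Known limitations

* The greedy searcher is order-dependent and has no optimality guarantee;
  it is step-optimal only (each addition is the best available at that
  step), which the tests verify.
* The trend test assumes an additive genetic model; dominant/recessive
  codings and covariate adjustment are out of scope.
* Empirical q-values have resolution 1/(M·i); with M = 20 a rank-1 module
  can at best be reported as q < 0.05.
* The rewiring null preserves degrees but not connectivity; on very sparse
  or nearly tree-like networks the rewired graphs can fragment differently
  from the original.
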