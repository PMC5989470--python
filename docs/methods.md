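# Methods

`scfidelity` quantifies how faithfully an in vitro cell population (for
example an organoid-derived secretory cell) represents an in vivo reference
cell type, using single-cell RNA-seq UMI count matrices as the common
currency. This note records the models, the constants, the numerical
choices, and what the synthetic validation does and does not establish.

## Pipeline model

The analysis is the classic graph-based scRNA-seq workflow, with one
study-specific statistic at its center.

**QC filtering.** Cells are retained when `n_umi >= min_umi` (default
1000), `n_genes >= min_genes` (default 400) and `n_umi < max_umi` (default
8000, strict); genes are then retained when detected (count > 0) in at
least `min_cells_per_gene` (default 5) of the retained cells. "At least"
maps to `>=` and "less than" to `<` throughout, so a 1000-UMI cell is kept
and an 8000-UMI cell dropped. Filtering is applied once — cells first, then
genes, with no re-iteration — which makes it idempotent: removing
low-prevalence genes could in principle push a cell below the gene
threshold, but we deliberately do not re-filter, matching the two-step
merge/object setup the thresholds come from.

**Normalization.** `v[c,g] = ln(count[c,g] / n_umi[c] * scale_factor + 1)`
with `scale_factor = 10,000`. Natural log and the 10k factor are the
de-facto standards of the toolchain generation this pipeline mirrors; both
are config-exposed. The transform is exactly invariant to per-cell depth
rescaling.

**Variable genes.** Per-gene mean and dispersion (variance/mean, n−1
variance) are computed on the log-normalized matrix; genes pass with mean >
0.14 and dispersion > 0.4 (defaults). An alternative — dispersion on
de-logged values — was considered and rejected as the default because the
cutoffs are quoted against "normalized and scaled expression"; the literal
reading is the one implemented.

**PCA.** Genes are z-scored across cells (n−1 sd; zero-variance genes map
to 0), clipped to ±10, then decomposed by exact (full SVD) PCA, default 12
components. Component signs are fixed by making the largest-magnitude gene
loading of each component positive, so runs are reproducible bit-for-bit.

**SNN graph and clustering.** Each cell's k = 20 nearest neighbors
(Euclidean, in PC space, self included in the neighbor list — this choice
changes the Jaccard weights and is therefore pinned) define a
shared-nearest-neighbor graph with edge weight `|N(i) ∩ N(j)| / |N(i) ∪
N(j)|`; edges with weight ≤ 1/15 are pruned. Communities are found by
Louvain modularity optimization with a resolution parameter (default 1.35)
scaling the null-model term; Leiden is available behind
`cluster_method: leiden`. The optimizer's RNG is seeded, labels are
relabeled contiguous-from-0 by decreasing cluster size, and isolated cells
become singletons. tSNE (default 1000 iterations) is provided for
visualization only; no analysis quantity depends on it.

**Markers.** Per gene, the ROC-AUC separating a cluster from all other
cells is computed exactly via the rank (Mann–Whitney) identity with 0.5
credit per tied pair — no trapezoid approximation — making it
oracle-checkable by brute-force pair counting and invariant under monotone
transforms of expression. Genes with AUC > 0.60 describe a cluster; the
stricter AUC > 0.65 set (strict inequality, sorted by decreasing AUC, ties
broken by symbol) is the scoring signature.

**Bimodal likelihood-ratio test.** Expression in a group is modeled as a
mixture of a point mass at exactly 0 (in normalized units) and a normal
over the nonzero values: `L = n_zero·ln(1−π) + n_pos·ln(π) + Σ ln
N(x; μ, σ)` at the MLE (π = detection fraction; μ, σ the ML normal fit,
ddof = 0). The test statistic is `2·(L_in + L_out − L_pooled)` against a
chi-square with 3 degrees of freedom (π, μ, σ free per group versus
pooled), upper tail. σ is floored at 1 when a group has fewer than two
positive values or zero spread, keeping likelihoods finite in degenerate
cells; the floor is the only non-MLE ingredient. Bonferroni correction uses
the number of genes tested in the comparison (not the genome), capped at 1.
Null simulations (both groups drawn from one zero-inflated normal, n =
50/50) put the type-I error at ≈ 0.05–0.06 at nominal 0.05 — the chi-square
reference is asymptotic and mildly anticonservative at these sizes.

**Transcriptome-fraction score.** The fidelity statistic: `score(c) =
Σ_{g∈sig} v[c,g] / Σ_{g∈all} v[c,g]`. Under this denominator the score of
the full gene universe is exactly 1 and disjoint signatures add — the
properties that let per-cluster scores be read as "fraction of the
transcriptome". The statistic's verbal definition could also be read with a literal
"total scaled UMI" denominator (a per-cell constant equal to the scale
factor); that convention is available via `score_denominator: scaled_umi`
and recorded in the score's convention tag, but self-consistency of
fraction-of-transcriptome percentages makes the normalized-sum denominator
the default, and the convention is recorded on every score vector. The log
base follows the normalization module (natural log).

**Comparison.** Cohen's d with the pooled sd,
`d = (mean₁ − mean₂)/sd_pooled`, `sd_pooled = sqrt(((n₁−1)s₁² +
(n₂−1)s₂²)/(n₁+n₂−2))`, plus a two-sided t test — Welch by default
(cluster sizes here differ by orders of magnitude; the pooled-variance
variant sits behind `equal_var_ttest`). Zero pooled sd yields d = 0 for
equal means and signed infinity (with a warning) otherwise.

**Benchmark orchestration.** Reference and query matrices are harmonized by
gene-symbol intersection (dropped-gene count reported — conservative and
auditable, since nothing in the data states how the original matrices were
aligned). The reference is clustered, the reference cluster located either
explicitly or as the cluster maximizing mean expression of a supplied
marker list, and its AUC > 0.65 signature derived. Queries are merged with
condition tags, clustered with their own config, and every cell scored
against the signature; per-cluster reports carry the mean score, Cohen's
d/p versus the remaining query cells, and versus the reference population.
Reference and query clustering accept separate config blocks since the two
datasets generally need different settings.

## Synthetic data generator

The generator emulates the statistical structure of nanowell (Seq-Well
class) UMI data so the whole pipeline can be validated against known ground
truth:

* **Counts:** per cell, a program label from the mixture proportions, a
  library size L from a log-normal law (clipped to ≥ 1), and gene counts
  multinomial over the program's propensity vector given L. Defaults pin
  the library law at median ≈ 2200 UMI with log-sd 0.4 (the ~1000–8000
  band) and route 10.4% / 5.4% of expected counts to dedicated `mt-` /
  `Rps|Rpl` gene blocks — the observed averages of the data being emulated.
* **Structure:** programs share a log-normal baseline propensity vector
  with program-specific wobble; each plants a disjoint block of marker
  genes up-weighted by `marker_fold` (benchmark default 10). Rare
  populations are supported down to a few percent via the proportions.
* **Fidelity dial:** a program may be interpolated toward a designated
  reference program, `w = (1−δ)·base + δ·reference` on normalized weights,
  δ ∈ [0,1] — the planted analogue of an in vitro state approaching its
  in vivo counterpart. Mean marker scores are strictly increasing in δ.

The multinomial-conditional-on-L law was chosen over per-gene negative
binomial deliberately: it is the simplest mechanism that exercises every
downstream statistic, with overdispersion entering through library-size
spread and between-program structure. The generator does **not** model
doublets, ambient RNA, batch effects, per-gene biological overdispersion
beyond program mixing, or trajectory structure — so passing tests
demonstrate algorithmic correctness and parameter recovery under clean
planted structure, not robustness to those real-data artifacts.

## Validation problem sizes

The planted benchmark uses 3 programs × 300 genes × 600 cells with marker
fold 10 (clustering ARI, marker AUC/recovery), 300–400-cell datasets for
the benchmark-level checks, five seeds × five δ values for the fidelity
dial, and 1000-replicate null simulations for calibration. QC and selection
cutoffs are scaled to this gene-axis size (minimum 500 UMI, 100 genes,
prevalence 3, variable-gene cutoffs 0.1/0.1, 10 PCs, resolution 1.0); the
package defaults remain the full-scale values listed above.

## Numerical choices and degenerate inputs

* Zero-count cells: QC metrics report 0 fractions and a flag; normalization
  refuses them with a pointer to filter first.
* AUC with an empty in- or out-group, empty gene lists, empty signatures:
  explicit errors or typed warnings (`EmptySignatureWarning`), never silent
  empty results.
* Seeds: one global `rng_seed` fans out to per-stage seeds by CRC32 hashing
  of the stage name, so stages can be re-run independently yet
  deterministically; all derived seeds are < 2³¹.
* Top-cell selection breaks score ties by lexicographic cell id.
* Heatmap z-scores clip at ±2.5; zero-variance genes become all-zero rows
  and are flagged; gene order by average-linkage Euclidean hierarchical
  clustering.

## Known limitations

* The self-benchmark gap statistic (best query cluster versus reference
  population, in pooled standard errors) is sensitive to modularity
  optimization splitting a program into sub-clusters: the best-scoring
  fragment is selected, which biases the gap upward on some seeds even
  though per-cell scores are identical. The fixed-condition property test
  holds; the seed-to-seed spread is expected behavior of argmax selection,
  not score error.
* The bimodal LRT's chi-square(3) reference is asymptotic; at n ≈ 50 per
  group it runs slightly hot (≈ 0.06 at nominal 0.05).
* Louvain determinism is guaranteed for a fixed seed and input order;
  permuting cells can change ambiguous partitions (not the crisp planted
  ones used in validation).
* Gene identity is the case-sensitive symbol string; no cross-genome or
  alias mapping.
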