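# scfidelity

**Benchmarking in vitro cell populations against an in vivo reference with
single-cell RNA-seq.**

Organoids and other stem-cell-derived cultures are routinely used as stand-ins
for rare in vivo cell types — intestinal Paneth cells being a canonical
example — yet "how close is the dish to the tissue?" is usually answered with
a handful of marker genes. `scfidelity` implements a quantitative answer for
anyone with UMI count matrices from both sides of that comparison: it derives
an unbiased reference signature from the in vivo data, scores every in vitro
cell by how much of its transcriptome is devoted to that signature, and ranks
culture conditions and subpopulations by effect size.

## The statistics at the core

Given log-normalized expression `v[c,g] = ln(count[c,g] / n_c · 10⁴ + 1)`,
the **transcriptome-fraction score** of cell *c* for gene set *S* is

    score(c) = Σ_{g∈S} v[c,g] / Σ_{g} v[c,g]   ∈ [0, 1]

so a score of 0.53 reads as "53% of this cell's (log-scaled) transcriptome is
devoted to the signature". The signature *S* itself is derived from the
reference data by a **ROC-AUC marker test**: per gene, the exact
Mann–Whitney AUC (0.5 credit per tied pair) separating the reference cell
type's cluster from all other cells, keeping genes with AUC > 0.65.
Populations are compared with **Cohen's d** = (m₁ − m₂)/sd_pooled and a
Welch t test; individual genes with a **bimodal likelihood-ratio test**
(point mass at zero + normal over detected values, χ²₃), Bonferroni
corrected.

Upstream of these sit standard QC (≥1000 UMI, ≥400 genes, <8000 UMI, gene in
≥5 cells), mean/dispersion variable-gene selection (>0.14 / >0.4), clipped
z-score PCA (12 PCs), and Louvain clustering of a Jaccard-weighted
shared-nearest-neighbor graph (k=20, prune 1/15, resolution 1.35) — every
constant lives in `AnalysisConfig` and a YAML config file.

A **synthetic generator** (`scfidelity.synthetic`) produces UMI matrices with
planted cell programs, marker blocks, rare populations, log-normal library
sizes and mitochondrial/ribosomal count routing, plus a **fidelity dial** δ
that interpolates a program toward a designated reference program — so the
entire pipeline is testable against known ground truth with no downloads.

## Worked example

Score a synthetic "organoid" condition, dialed 60% of the way toward a
synthetic "in vivo" reference, against that reference:

```python
import scfidelity as sf

cfg = sf.AnalysisConfig(
    min_umi=500, min_genes=100, max_umi=20_000, min_cells_per_gene=3,
    var_mean_cutoff=0.1, var_dispersion_cutoff=0.1, n_pcs=10,
    resolution=1.0, rng_seed=0,
)

ref_spec = sf.make_benchmark_spec(
    n_programs=3, n_genes=300, n_cells=400, proportions=[0.5, 0.3, 0.2],
    marker_fold=10.0, rng_seed=100, sample_label="invivo",
)
ref_cm, ref_truth = sf.generate_counts(ref_spec)
markers = sf.GeneList("reference_markers", ref_truth.marker_genes["prog0"])

query_spec = sf.make_benchmark_spec(
    n_programs=3, n_genes=300, n_cells=400, proportions=[0.0, 0.6, 0.4],
    marker_fold=10.0, fidelity={"prog1": 0.6}, reference_program="prog0",
    rng_seed=200, sample_label="organoid",
)
query_cm, _ = sf.generate_counts(query_spec)

report = sf.run_benchmark(ref_cm, {"organoid": query_cm}, cfg,
                          reference_markers=markers)
print(f"signature: {len(report.signature)} genes at AUC > "
      f"{report.signature.auc_threshold}")
print(f"reference mean score: {report.reference_scores.scores.mean():.3f}")
print(report.per_cluster[["n_cells", "mean_score", "d_vs_rest",
                          "d_reference_vs_cluster"]].round(3))
```

prints

```
signature: 66 genes at AUC > 0.65
reference mean score: 0.297
         n_cells  mean_score  d_vs_rest  d_reference_vs_cluster
cluster
0            126       0.258      1.698                   4.622
1            106       0.254      1.025                   5.702
2             86       0.217     -1.746                   9.206
3             82       0.217     -1.720                  10.081
```

Read: the reference cell type devotes on average 29.7% of its transcriptome
to its own 66-gene signature; the best-matching query clusters (0 and 1, the
δ-dialed program) reach ~25–26%, clearly above the unrelated program
(clusters 2–3, ~22%) but still measurably short of the in vivo reference
(d ≈ 4.6 versus d ≈ 9–10 for the unrelated clusters). Raising δ closes the
gap monotonically.

The same pipeline is scriptable from the shell:

```bash
scfidelity simulate --spec spec.yaml --out-prefix sim
scfidelity qc --in sim_dge.tsv --config cfg.yaml --out filtered.tsv
scfidelity cluster --in filtered.tsv --config cfg.yaml --out-labels labels.tsv
scfidelity score --in filtered.tsv --signature markers.txt --out scores.tsv
scfidelity benchmark --reference ref_dge.tsv --query organoid=q_dge.tsv \
    --reference-markers markers.txt --config cfg.yaml --out-dir out/
```

Every artifact-producing run writes a JSON manifest (config snapshot, seed,
input digests) sufficient to reproduce it bit-identically.

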