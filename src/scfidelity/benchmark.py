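"""End-to-end fidelity benchmark of in vitro populations against an in vivo reference.

The orchestration mirrors the experimental design: an in vivo reference dataset is
QC-filtered, normalized and clustered, a reference cell-type signature is
derived from its marker AUCs; the in vitro query conditions are merged,
clustered the same way, and every query cell is scored by the fraction of
its transcriptome dedicated to the reference signature.  Query clusters are
then ranked and compared — against the remaining query cells and against the
reference population itself — by Cohen's d and a two-sided t test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy

from .config import AnalysisConfig, stage_seed
from .markers import EmptySignatureWarning, GeneSignature, derive_signature
from .matrix_io import CountMatrix, GeneList
from .preprocess import (
    NormalizedMatrix,
    filter_cells_genes,
    normalize_log_scaled,
    select_variable_genes,
)
from .reduce_cluster import ClusterAssignment, build_snn_graph, cluster_graph, run_pca
from .scoring import ComparisonReport, ScoreVector, compare_scores, score_cells

__all__ = [
    "BenchmarkReport",
    "HeatmapMatrix",
    "run_benchmark",
    "condition_cluster_fractions",
    "heatmap_zscore_matrix",
    "tf_filter",
]


@dataclass
class BenchmarkReport:
    """All benchmark outputs plus the provenance needed to re-run them."""

    signature: GeneSignature
    per_cluster: pd.DataFrame  # one row per query cluster
    cluster_fractions: pd.DataFrame  # conditions x clusters, rows sum to 1
    reference_scores: ScoreVector
    query_scores: ScoreVector
    query_labels: ClusterAssignment
    conditions: pd.Series  # per query cell condition tag
    config: dict[str, Any] = field(default_factory=dict)
    rng_seed: int = 0
    n_genes_shared: int = 0
    n_genes_dropped: int = 0

    @property
    def best_cluster(self) -> int:
        return int(self.per_cluster["mean_score"].idxmax())

    @property
    def best_cluster_mean_score(self) -> float:
        return float(self.per_cluster["mean_score"].max())


def _cluster_pipeline(
    m: CountMatrix, cfg: AnalysisConfig, seed: int
) -> tuple[NormalizedMatrix, ClusterAssignment]:
    filtered = filter_cells_genes(m, cfg)
    nm = normalize_log_scaled(filtered, cfg.scale_factor)
    var_genes = select_variable_genes(nm, cfg)
    if len(var_genes) < cfg.n_pcs:
        raise ValueError(
            f"only {len(var_genes)} variable genes at the configured cutoffs; "
            f"need >= n_pcs={cfg.n_pcs}"
        )
    pca = run_pca(nm, var_genes, n_pcs=cfg.n_pcs, clip=cfg.zscore_clip)
    k = min(cfg.snn_k, nm.values.shape[0] - 1)
    snn = build_snn_graph(pca, k=k, prune=cfg.snn_prune)
    labels = cluster_graph(snn, resolution=cfg.resolution, seed=seed, method=cfg.cluster_method)
    return nm, labels


def _pick_reference_cluster(
    nm: NormalizedMatrix, labels: ClusterAssignment, markers: GeneList
) -> int:
    present = [g for g in markers.genes if g in nm.values.columns]
    if not present:
        raise ValueError("none of the reference marker genes are in the matrix")
    mean_by_cluster = (
        nm.values.loc[:, present].mean(axis=1).groupby(labels.labels).mean()
    )
    return int(mean_by_cluster.idxmax())


def run_benchmark(
    reference: CountMatrix,
    query_conditions: Mapping[str, CountMatrix],
    cfg: AnalysisConfig,
    reference_cluster: int | None = None,
    reference_markers: GeneList | None = None,
    reference_cfg: AnalysisConfig | None = None,
) -> BenchmarkReport:
    """Run the full fidelity benchmark.

    Parameters
    ----------
    reference : CountMatrix
        The in vivo reference dataset from which the cell-type signature is
        derived.
    query_conditions : mapping of condition name -> CountMatrix
        In vitro datasets to be merged, clustered and scored.
    cfg : AnalysisConfig
        Pipeline constants for the query analysis (and, unless
        ``reference_cfg`` is given, for the reference analysis too).
    reference_cluster : int, optional
        The reference cluster whose markers define the signature.  If None,
        the cluster is picked as the one with the highest mean expression of
        ``reference_markers``.
    reference_markers : GeneList, optional
        Known markers of the reference cell type, used only to locate the
        reference cluster when ``reference_cluster`` is None.
    reference_cfg : AnalysisConfig, optional
        Separate constants for the reference run (the reference and query
        datasets may need different clustering settings).
    """
    if not query_conditions:
        raise ValueError("at least one query condition is required")
    ref_cfg = reference_cfg or cfg

    shared = [g for g in reference.gene_ids if all(
        g in q.counts.columns for q in query_conditions.values()
    )]
    universe = set(reference.gene_ids)
    for q in query_conditions.values():
        universe |= set(q.gene_ids)
    n_dropped = len(universe) - len(shared)
    if not shared:
        raise ValueError("reference and query matrices share no genes")

    ref = CountMatrix(reference.counts.loc[:, shared], sample_label=reference.sample_label)
    ref_nm, ref_labels = _cluster_pipeline(
        ref, ref_cfg, seed=stage_seed(cfg.rng_seed, "reference_cluster")
    )
    if reference_cluster is None:
        if reference_markers is None:
            raise ValueError("provide reference_cluster or reference_markers")
        reference_cluster = _pick_reference_cluster(ref_nm, ref_labels, reference_markers)
    signature = derive_signature(
        ref_nm, ref_labels, reference_cluster, auc_threshold=cfg.marker_auc_score,
        name=f"{reference.sample_label or 'reference'}_cluster{reference_cluster}",
    )
    if len(signature) == 0:
        raise RuntimeError(
            f"reference signature is empty at AUC > {cfg.marker_auc_score}; "
            f"cluster {reference_cluster} has {len(ref_labels.cells_in(reference_cluster))} cells"
        )

    merged_parts, condition_tags = [], []
    for cond, q in query_conditions.items():
        part = q.counts.loc[:, shared].copy()
        part.index = [f"{cond}:{c}" for c in part.index]
        merged_parts.append(part)
        condition_tags.extend([cond] * part.shape[0])
    merged = CountMatrix(pd.concat(merged_parts, axis=0), sample_label="merged_query")
    conditions = pd.Series(condition_tags, index=merged.counts.index, name="condition")

    query_nm, query_labels = _cluster_pipeline(
        merged, cfg, seed=stage_seed(cfg.rng_seed, "query_cluster")
    )
    conditions = conditions.loc[query_nm.values.index]

    ref_scores = score_cells(ref_nm, signature.as_gene_list(), cfg.score_denominator)
    ref_in_cluster = ref_scores.subset(ref_labels.cells_in(reference_cluster))
    query_scores = score_cells(query_nm, signature.as_gene_list(), cfg.score_denominator)

    rows = []
    for cl in sorted(query_labels.labels.unique()):
        cells = query_labels.cells_in(cl)
        rest = [c for c in query_scores.scores.index if c not in set(cells)]
        row: dict[str, Any] = {"cluster": cl, "n_cells": len(cells)}
        row["mean_score"] = float(query_scores.scores.loc[cells].mean())
        if len(cells) >= 2 and len(rest) >= 2:
            vs_rest = compare_scores(
                query_scores.subset(cells), query_scores.subset(rest),
                labels=(f"cluster{cl}", "rest"), equal_var=cfg.equal_var_ttest,
            )
            row.update(d_vs_rest=vs_rest.cohens_d, p_vs_rest=vs_rest.p_value)
        else:
            row.update(d_vs_rest=np.nan, p_vs_rest=np.nan)
        if len(cells) >= 2 and len(ref_in_cluster) >= 2:
            vs_ref = compare_scores(
                ref_in_cluster, query_scores.subset(cells),
                labels=("reference", f"cluster{cl}"), equal_var=cfg.equal_var_ttest,
            )
            row.update(d_reference_vs_cluster=vs_ref.cohens_d, p_reference_vs_cluster=vs_ref.p_value)
        else:
            row.update(d_reference_vs_cluster=np.nan, p_reference_vs_cluster=np.nan)
        rows.append(row)
    per_cluster = pd.DataFrame(rows).set_index("cluster")

    fractions = condition_cluster_fractions(query_labels, conditions)

    return BenchmarkReport(
        signature=signature,
        per_cluster=per_cluster,
        cluster_fractions=fractions,
        reference_scores=ref_in_cluster,
        query_scores=query_scores,
        query_labels=query_labels,
        conditions=conditions,
        config=cfg.to_dict(),
        rng_seed=cfg.rng_seed,
        n_genes_shared=len(shared),
        n_genes_dropped=n_dropped,
    )


def condition_cluster_fractions(
    labels: ClusterAssignment | pd.Series, condition_of_cell: pd.Series
) -> pd.DataFrame:
    """Cluster frequencies within each condition; rows sum to 1."""
    lab = labels.labels if isinstance(labels, ClusterAssignment) else labels
    lab = lab.loc[condition_of_cell.index]
    if lab.isna().any():
        raise ValueError("every cell needs both a cluster label and a condition tag")
    table = pd.crosstab(condition_of_cell, lab, normalize="index")
    table.index.name = "condition"
    table.columns.name = "cluster"
    return table


@dataclass
class HeatmapMatrix:
    """Genes x cells z-score matrix clipped to a symmetric range."""

    values: pd.DataFrame  # genes x cells
    clip: float
    zero_variance_genes: list[str] = field(default_factory=list)


def heatmap_zscore_matrix(
    nm: NormalizedMatrix,
    cells: list[str],
    genes: list[str],
    clip: float = 2.5,
    cell_groups: pd.Series | None = None,
    cell_scores: pd.Series | None = None,
) -> HeatmapMatrix:
    """Row (gene) z-score matrix for display, clipped to ``+-clip``.

    Genes are ordered by hierarchical clustering of their z-score profiles
    (average linkage, Euclidean); cells by group then decreasing score when
    provided.  Zero-variance genes get all-zero rows and are flagged.
    """
    missing_c = [c for c in cells if c not in nm.values.index]
    missing_g = [g for g in genes if g not in nm.values.columns]
    if missing_c or missing_g:
        raise ValueError(f"missing cells {missing_c[:5]} / genes {missing_g[:5]}")
    sub = nm.values.loc[cells, genes]
    mu = sub.mean(axis=0)
    sd = sub.std(axis=0, ddof=1)
    flat = sd[sd == 0].index.tolist()
    if flat:
        warnings.warn(f"{len(flat)} genes have zero variance across the selection")
    z = (sub - mu) / sd.replace(0, 1.0)
    z.loc[:, flat] = 0.0
    z = z.clip(-clip, clip).T  # genes x cells

    if z.shape[0] > 2:
        link = scipy.cluster.hierarchy.linkage(z.to_numpy(), method="average", metric="euclidean")
        gene_order = scipy.cluster.hierarchy.leaves_list(link)
        z = z.iloc[gene_order]
    if cell_groups is not None or cell_scores is not None:
        groups = cell_groups.loc[cells] if cell_groups is not None else pd.Series("", index=cells)
        scores = cell_scores.loc[cells] if cell_scores is not None else pd.Series(0.0, index=cells)
        order = sorted(cells, key=lambda c: (str(groups[c]), -scores[c], c))
        z = z.loc[:, order]
    return HeatmapMatrix(values=z, clip=clip, zero_variance_genes=flat)


def tf_filter(sig: GeneSignature, tf_catalog: GeneList) -> GeneSignature:
    """Restrict a signature to transcription factors, preserving order and AUCs."""
    if len(tf_catalog.genes) == 0:
        raise ValueError("empty TF catalog")
    catalog = set(tf_catalog.genes)
    kept = [g for g in sig.genes if g in catalog]
    if not kept:
        warnings.warn(
            f"no transcription factor in signature {sig.name!r}", EmptySignatureWarning
        )
    return GeneSignature(
        name=f"{sig.name}_tf",
        genes=kept,
        aucs={g: sig.aucs[g] for g in kept},
        auc_threshold=sig.auc_threshold,
        source_cluster=sig.source_cluster,
    )
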