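"""QC filtering, depth normalization, and variable-gene selection.

The stages are exposed both as scikit-learn style estimators operating on
cells x genes pandas DataFrames (:class:`QCFilter`, :class:`LogNormalizer`,
:class:`VariableGeneSelector`) and as thin functions over the package's
:class:`~scfidelity.matrix_io.CountMatrix` container.

Boundary semantics are literal: "at least" is >=, "less than" is a strict
upper bound.  A cell is kept when
n_umi >= min_umi, n_genes >= min_genes and n_umi < max_umi; a gene is then
kept when detected (count > 0) in >= min_cells_per_gene of the retained
cells.  Filtering is applied once, cells first then genes, with no
re-iteration, which makes the operation idempotent.

Normalization is log(count / cell_total * scale_factor + 1) with the natural
logarithm and a default scale factor of 10,000 — invariant to per-cell
sequencing depth by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .config import AnalysisConfig
from .matrix_io import CountMatrix

__all__ = [
    "QCFilter",
    "LogNormalizer",
    "VariableGeneSelector",
    "NormalizedMatrix",
    "VariableGeneSet",
    "compute_qc_metrics",
    "filter_cells_genes",
    "normalize_log_scaled",
    "select_variable_genes",
]

MITO_PREFIXES = ("mt-",)
RIBO_PREFIXES = ("Rps", "Rpl")


@dataclass
class NormalizedMatrix:
    """Per-cell depth-scaled, log-transformed expression.

    ``values[c, g] = log(counts[c, g] / n_umi[c] * scale_factor + 1)``.
    ``provenance`` records the source sample and filter parameters.
    """

    values: pd.DataFrame
    scale_factor: float
    provenance: dict[str, Any] = field(default_factory=dict)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class VariableGeneSet:
    """Genes passing both the mean and dispersion cutoffs, with the stats used."""

    genes: list[str]
    stats: pd.DataFrame  # per-gene columns: mean, dispersion

    def __len__(self) -> int:
        return len(self.genes)


def _prefix_mask(genes: Sequence[str], prefixes: Sequence[str]) -> np.ndarray:
    return np.array([g.startswith(tuple(prefixes)) for g in genes], dtype=bool)


def compute_qc_metrics(
    m: CountMatrix | pd.DataFrame,
    mito_prefixes: Sequence[str] = MITO_PREFIXES,
    ribo_prefixes: Sequence[str] = RIBO_PREFIXES,
) -> pd.DataFrame:
    """Per-cell QC metrics: n_umi, n_genes, pct_mito, pct_ribo, zero_count flag.

    Fractions are of total counts; zero-count cells get 0 by convention and
    are flagged in the ``zero_count`` column.
    """
    counts = m.counts if isinstance(m, CountMatrix) else m
    if counts.shape[0] == 0 or counts.shape[1] == 0:
        raise ValueError("empty count matrix")
    values = counts.to_numpy()
    n_umi = values.sum(axis=1)
    n_genes = (values > 0).sum(axis=1)
    mito = _prefix_mask(counts.columns, mito_prefixes)
    ribo = _prefix_mask(counts.columns, ribo_prefixes)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct_mito = np.where(n_umi > 0, values[:, mito].sum(axis=1) / np.maximum(n_umi, 1), 0.0)
        pct_ribo = np.where(n_umi > 0, values[:, ribo].sum(axis=1) / np.maximum(n_umi, 1), 0.0)
    return pd.DataFrame(
        {
            "n_umi": n_umi,
            "n_genes": n_genes,
            "pct_mito": pct_mito,
            "pct_ribo": pct_ribo,
            "zero_count": n_umi == 0,
        },
        index=counts.index,
    )


class QCFilter(BaseEstimator):
    """Cell- and gene-level QC filter.

    Cells are filtered on total UMI and detected-gene thresholds, then genes
    on a detection-prevalence threshold computed over the *retained* cells,
    in one pass.

    Parameters
    ----------
    min_umi, min_genes : int
        Inclusive lower bounds on per-cell total counts / detected genes.
    max_umi : float
        Exclusive upper bound on per-cell total counts.
    min_cells_per_gene : int
        Inclusive lower bound on the number of retained cells detecting a gene.
    """

    def __init__(
        self,
        min_umi: int = 1000,
        min_genes: int = 400,
        max_umi: float = 8000,
        min_cells_per_gene: int = 5,
    ):
        self.min_umi = min_umi
        self.min_genes = min_genes
        self.max_umi = max_umi
        self.min_cells_per_gene = min_cells_per_gene

    def fit(self, X: pd.DataFrame, y=None) -> "QCFilter":
        values = X.to_numpy()
        n_umi = values.sum(axis=1)
        n_genes = (values > 0).sum(axis=1)
        cell_mask = (n_umi >= self.min_umi) & (n_genes >= self.min_genes) & (n_umi < self.max_umi)
        if not cell_mask.any():
            raise ValueError("no cells survive QC")
        prevalence = (values[cell_mask] > 0).sum(axis=0)
        gene_mask = prevalence >= self.min_cells_per_gene
        self.cell_mask_ = pd.Series(cell_mask, index=X.index)
        self.gene_mask_ = pd.Series(gene_mask, index=X.columns)
        self.n_cells_kept_ = int(cell_mask.sum())
        self.n_genes_kept_ = int(gene_mask.sum())
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        cells = self.cell_mask_.reindex(X.index, fill_value=False)
        genes = self.gene_mask_.reindex(X.columns, fill_value=False)
        return X.loc[cells.to_numpy(), genes.to_numpy()]

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X).transform(X)


class LogNormalizer(TransformerMixin, BaseEstimator):
    """Stateless depth normalization: log(count / total * scale_factor + 1)."""

    def __init__(self, scale_factor: float = 10_000.0):
        self.scale_factor = scale_factor

    def fit(self, X: pd.DataFrame, y=None) -> "LogNormalizer":
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        totals = X.to_numpy().sum(axis=1, keepdims=True)
        if (totals == 0).any():
            bad = X.index[totals.ravel() == 0].tolist()
            raise ValueError(f"zero-count cells present (filter first): {bad[:5]}")
        scaled = X.to_numpy() / totals * self.scale_factor
        return pd.DataFrame(np.log1p(scaled), index=X.index, columns=X.columns)


class VariableGeneSelector(TransformerMixin, BaseEstimator):
    """Select highly variable genes by mean / dispersion cutoffs.

    Per-gene mean and dispersion (variance / mean, n-1 variance) are computed
    on the normalized matrix; a gene is kept when mean > mean_cutoff AND
    dispersion > dispersion_cutoff.  Genes with zero mean are excluded.
    """

    def __init__(self, mean_cutoff: float = 0.14, dispersion_cutoff: float = 0.4):
        self.mean_cutoff = mean_cutoff
        self.dispersion_cutoff = dispersion_cutoff

    def fit(self, X: pd.DataFrame, y=None) -> "VariableGeneSelector":
        if X.shape[0] < 2:
            raise ValueError("need at least 2 cells to estimate dispersion")
        values = X.to_numpy()
        means = values.mean(axis=0)
        variances = values.var(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            dispersions = np.where(means > 0, variances / np.where(means > 0, means, 1.0), 0.0)
        self.means_ = pd.Series(means, index=X.columns)
        self.dispersions_ = pd.Series(dispersions, index=X.columns)
        self.support_ = (
            (means > 0) & (means > self.mean_cutoff) & (dispersions > self.dispersion_cutoff)
        )
        return self

    def get_support(self) -> np.ndarray:
        return self.support_

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X.loc[:, self.support_]


def filter_cells_genes(m: CountMatrix, cfg: AnalysisConfig) -> CountMatrix:
    """Apply the QC filter to a CountMatrix per the config thresholds."""
    qc = QCFilter(
        min_umi=cfg.min_umi,
        min_genes=cfg.min_genes,
        max_umi=cfg.max_umi,
        min_cells_per_gene=cfg.min_cells_per_gene,
    )
    return CountMatrix(qc.fit_transform(m.counts), sample_label=m.sample_label)


def normalize_log_scaled(m: CountMatrix, scale_factor: float = 10_000.0) -> NormalizedMatrix:
    """Depth-normalize and log-transform a count matrix."""
    values = LogNormalizer(scale_factor=scale_factor).fit_transform(m.counts)
    return NormalizedMatrix(
        values=values,
        scale_factor=scale_factor,
        provenance={"sample_label": m.sample_label, "n_cells": m.n_cells, "n_genes": m.n_genes},
    )


def select_variable_genes(nm: NormalizedMatrix, cfg: AnalysisConfig) -> VariableGeneSet:
    """Variable genes of a normalized matrix at the config cutoffs."""
    sel = VariableGeneSelector(
        mean_cutoff=cfg.var_mean_cutoff, dispersion_cutoff=cfg.var_dispersion_cutoff
    ).fit(nm.values)
    stats = pd.DataFrame({"mean": sel.means_, "dispersion": sel.dispersions_})
    genes = [g for g, keep in zip(nm.gene_ids, sel.support_) if keep]
    return VariableGeneSet(genes=genes, stats=stats)
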