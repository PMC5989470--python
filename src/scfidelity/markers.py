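"""Marker derivation and differential expression statistics.

Two statistics drive cluster characterization:

* **ROC-AUC marker test** — per gene, the area under the ROC curve for
  separating in-cluster from out-of-cluster cells by expression, computed
  exactly through the rank (Mann-Whitney) identity with half credit for
  ties: AUC = (concordant + 0.5 * tied) / (n_in * n_out).  Genes above a
  reporting threshold (default 0.60) describe a cluster; a stricter
  threshold (default 0.65) defines scoring signatures.

* **Bimodal likelihood-ratio test** — each group's expression is modeled as
  a mixture of a point mass at zero and a normal over the positive values;
  the statistic is 2*(L(in) + L(out) - L(pooled)) referred to a chi-square
  with 3 degrees of freedom (pi, mu, sigma free per group).  The normal
  sigma is the ML estimate, floored at 1 when a group has fewer than two
  positive values or zero spread so likelihoods stay finite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .matrix_io import GeneList
from .preprocess import NormalizedMatrix
from .reduce_cluster import ClusterAssignment

__all__ = [
    "GeneSignature",
    "EmptySignatureWarning",
    "roc_auc_markers",
    "bimod_lrt",
    "de_table",
    "bonferroni_adjust",
    "derive_signature",
]


class EmptySignatureWarning(UserWarning):
    """Raised (as a warning) when a derived signature contains no genes."""


@dataclass
class GeneSignature:
    """Ranked marker gene list with per-gene AUC and the threshold used."""

    name: str
    genes: list[str]
    aucs: dict[str, float] = field(default_factory=dict)
    auc_threshold: float = 0.65
    source_cluster: int | None = None

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def as_gene_list(self) -> GeneList:
        return GeneList(name=self.name, genes=list(self.genes))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.genes, "auc": [self.aucs[g] for g in self.genes]})


def _group_masks(
    nm: NormalizedMatrix, labels: ClusterAssignment, cluster_id: int
) -> tuple[np.ndarray, np.ndarray]:
    lab = labels.labels.reindex(nm.values.index)
    if lab.isna().any():
        raise ValueError("cluster labels missing for some cells in the matrix")
    in_mask = (lab == cluster_id).to_numpy()
    if not in_mask.any():
        raise ValueError(f"cluster {cluster_id} has no cells")
    if in_mask.all():
        raise ValueError(f"cluster {cluster_id} contains every cell; no out-group")
    return in_mask, ~in_mask


def _rank_auc(values: np.ndarray, in_mask: np.ndarray) -> np.ndarray:
    """Column-wise tie-aware AUC of in-group vs out-group via mid-ranks."""
    n_in = int(in_mask.sum())
    n_out = values.shape[0] - n_in
    ranks = stats.rankdata(values, axis=0, method="average")
    r_in = ranks[in_mask].sum(axis=0)
    u = r_in - n_in * (n_in + 1) / 2.0
    return u / (n_in * n_out)


def roc_auc_markers(
    nm: NormalizedMatrix, labels: ClusterAssignment, cluster_id: int
) -> pd.DataFrame:
    """Per-gene marker records for one cluster versus all other cells.

    Returns a DataFrame indexed by gene with columns ``cluster``, ``auc``,
    ``mean_in``, ``mean_out``, ``pct_in``, ``pct_out`` for *all* genes;
    callers filter by their AUC threshold of choice.
    """
    in_mask, out_mask = _group_masks(nm, labels, cluster_id)
    values = nm.values.to_numpy()
    auc = _rank_auc(values, in_mask)
    return pd.DataFrame(
        {
            "cluster": cluster_id,
            "auc": auc,
            "mean_in": values[in_mask].mean(axis=0),
            "mean_out": values[out_mask].mean(axis=0),
            "pct_in": (values[in_mask] > 0).mean(axis=0),
            "pct_out": (values[out_mask] > 0).mean(axis=0),
        },
        index=nm.values.columns,
    )


def _bimod_loglik(x: np.ndarray) -> float:
    """Log-likelihood of the zero-inflated normal mixture at its MLE.

    pi = fraction of positive values; (mu, sigma) = ML normal fit to the
    positives, sigma floored at 1 for <2 positives or zero spread.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    pos = x[x != 0]
    n_pos = pos.size
    n_zero = n - n_pos
    pi = n_pos / n
    ll = 0.0
    if n_zero:
        ll += n_zero * np.log(1 - pi)
    if n_pos:
        ll += n_pos * np.log(pi)
        mu = pos.mean()
        sigma = pos.std(ddof=0)
        if n_pos < 2 or sigma == 0:
            sigma = 1.0
        ll += stats.norm.logpdf(pos, loc=mu, scale=sigma).sum()
    return float(ll)


def bimod_lrt(x_in: np.ndarray, x_out: np.ndarray) -> tuple[float, float]:
    """Bimodal likelihood-ratio test between two expression vectors.

    Returns ``(statistic, p_value)``; the statistic is clipped at 0 against
    numerical round-off and the p-value is the chi-square(3) upper tail.
    """
    x_in = np.asarray(x_in, dtype=float)
    x_out = np.asarray(x_out, dtype=float)
    if x_in.size < 1 or x_out.size < 1:
        raise ValueError("both groups must be non-empty")
    stat = 2.0 * (_bimod_loglik(x_in) + _bimod_loglik(x_out) - _bimod_loglik(np.concatenate([x_in, x_out])))
    stat = max(stat, 0.0)
    return stat, float(stats.chi2.sf(stat, df=3))


def de_table(
    nm: NormalizedMatrix,
    cells_a: list[str],
    cells_b: list[str],
    n_tests: int | None = None,
) -> pd.DataFrame:
    """Bimodal-LRT differential expression of group A versus group B.

    One row per gene: ``lrt_statistic``, ``p_value``, Bonferroni
    ``p_adjusted`` (over the genes tested unless ``n_tests`` overrides),
    and ``log_fold_change`` = mean(A) - mean(B) of log-normalized values.
    Sorted by increasing adjusted p then decreasing |log fold change|.
    """
    a = nm.values.loc[cells_a].to_numpy()
    b = nm.values.loc[cells_b].to_numpy()
    if a.shape[0] < 1 or b.shape[0] < 1:
        raise ValueError("both groups must be non-empty")
    stats_p = [bimod_lrt(a[:, j], b[:, j]) for j in range(a.shape[1])]
    lrt = np.array([s for s, _ in stats_p])
    p = np.array([pv for _, pv in stats_p])
    out = pd.DataFrame(
        {
            "lrt_statistic": lrt,
            "p_value": p,
            "p_adjusted": bonferroni_adjust(p, n_tests),
            "log_fold_change": a.mean(axis=0) - b.mean(axis=0),
        },
        index=nm.values.columns,
    )
    return out.sort_values(
        ["p_adjusted", "log_fold_change"], ascending=[True, False], key=abs
    )


def bonferroni_adjust(p_values: np.ndarray, n_tests: int | None = None) -> np.ndarray:
    """Bonferroni correction: p_adj = min(1, p * n_tests)."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p values must lie in [0, 1]")
    n = len(p) if n_tests is None else int(n_tests)
    if n < len(p):
        raise ValueError("n_tests must be >= number of p values")
    return np.minimum(p * n, 1.0)


def derive_signature(
    nm: NormalizedMatrix,
    labels: ClusterAssignment,
    cluster_id: int,
    auc_threshold: float = 0.65,
    name: str | None = None,
) -> GeneSignature:
    """Marker signature of a cluster: genes with AUC strictly above threshold.

    Genes are sorted by decreasing AUC (ties broken by gene symbol for
    determinism).  An empty result is returned with an
    :class:`EmptySignatureWarning` rather than silently.
    """
    records = roc_auc_markers(nm, labels, cluster_id)
    hits = records[records["auc"] > auc_threshold]
    hits = hits.sort_values(["auc"], ascending=False, kind="stable")
    hits = hits.iloc[np.lexsort((hits.index, -hits["auc"].to_numpy()))]
    sig_name = name or f"cluster{cluster_id}_auc{auc_threshold:g}"
    if hits.empty:
        warnings.warn(
            f"signature {sig_name!r} is empty at AUC > {auc_threshold}", EmptySignatureWarning
        )
    return GeneSignature(
        name=sig_name,
        genes=list(hits.index),
        aucs=hits["auc"].to_dict(),
        auc_threshold=auc_threshold,
        source_cluster=cluster_id,
    )
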