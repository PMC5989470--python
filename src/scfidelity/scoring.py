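"""Transcriptome-fraction signature scoring and effect-size comparison.

The central statistic assigns each cell the fraction of its (log-normalized)
transcriptome dedicated to a gene list:

    score(c) = sum_{g in signature} v[c, g] / sum_{g in all genes} v[c, g]

where v is log(scaled UMI + 1).  Under this default convention the score of
the full gene universe is exactly 1 and scores of disjoint signatures add.
A literal "scaled UMI" denominator (the per-cell scale factor, since scaled
counts sum to it) is available via ``denominator='scaled_umi'``.

Populations are compared by Cohen's d with the pooled standard deviation,
d = (mean_1 - mean_2) / sd_pooled, alongside a two-sided t test (Welch by
default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .matrix_io import GeneList
from .preprocess import NormalizedMatrix
from .reduce_cluster import ClusterAssignment

__all__ = [
    "ScoreVector",
    "ComparisonReport",
    "SignatureScorer",
    "score_cells",
    "cohens_d",
    "compare_scores",
    "select_top_cells",
]


@dataclass
class ScoreVector:
    """Per-cell transcriptome-fraction scores in [0, 1] for one signature."""

    scores: pd.Series
    signature_name: str
    denominator: str = "lognorm"
    missing_genes: tuple[str, ...] = ()

    def subset(self, cells: list[str]) -> "ScoreVector":
        return ScoreVector(
            self.scores.loc[cells], self.signature_name, self.denominator, self.missing_genes
        )

    def __len__(self) -> int:
        return len(self.scores)


@dataclass
class ComparisonReport:
    """Two-group score comparison: effect size and t test."""

    label_1: str
    label_2: str
    n_1: int
    n_2: int
    mean_1: float
    mean_2: float
    pooled_sd: float
    cohens_d: float
    t_statistic: float
    p_value: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


class SignatureScorer(BaseEstimator):
    """Estimator computing transcriptome-fraction scores for a gene list.

    ``fit`` resolves the signature against the matrix's gene universe (and
    records misses); ``transform`` returns the per-cell score vector.
    """

    def __init__(self, genes: list[str] | None = None, denominator: str = "lognorm",
                 scale_factor: float = 10_000.0):
        self.genes = genes
        self.denominator = denominator
        self.scale_factor = scale_factor

    def fit(self, X: pd.DataFrame, y=None) -> "SignatureScorer":
        if not self.genes:
            raise ValueError("signature is empty")
        if self.denominator not in ("lognorm", "scaled_umi"):
            raise ValueError("denominator must be 'lognorm' or 'scaled_umi'")
        universe = set(X.columns)
        self.present_ = [g for g in self.genes if g in universe]
        self.missing_ = [g for g in self.genes if g not in universe]
        if not self.present_:
            raise ValueError(f"no signature gene present in matrix; missing: {self.missing_}")
        if self.missing_:
            warnings.warn(
                f"{len(self.missing_)} signature genes absent from matrix "
                f"(contribute 0): {self.missing_[:10]}"
            )
        return self

    def transform(self, X: pd.DataFrame) -> pd.Series:
        numer = X.loc[:, self.present_].to_numpy().sum(axis=1)
        if self.denominator == "lognorm":
            denom = X.to_numpy().sum(axis=1)
            if (denom == 0).any():
                bad = X.index[denom == 0].tolist()
                raise ValueError(f"cells with zero total normalized expression: {bad[:5]}")
        else:
            denom = np.full(X.shape[0], float(self.scale_factor))
        return pd.Series(numer / denom, index=X.index, name="score")


def score_cells(
    nm: NormalizedMatrix,
    sig: GeneList | list[str],
    denominator: str = "lognorm",
) -> ScoreVector:
    """Score every cell of a normalized matrix against a gene list."""
    genes = list(sig.genes) if isinstance(sig, GeneList) else list(sig)
    name = sig.name if isinstance(sig, GeneList) else "signature"
    scorer = SignatureScorer(
        genes=genes, denominator=denominator, scale_factor=nm.scale_factor
    ).fit(nm.values)
    return ScoreVector(
        scores=scorer.transform(nm.values),
        signature_name=name,
        denominator=denominator,
        missing_genes=tuple(scorer.missing_),
    )


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Cohen's d with the pooled standard deviation.

    sd_pooled = sqrt(((n1-1)s1^2 + (n2-1)s2^2) / (n1+n2-2));
    d = (mean(x) - mean(y)) / sd_pooled.  A zero pooled sd yields 0 for
    equal means and signed infinity (with a warning) otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 values")
    diff = x.mean() - y.mean()
    pooled = np.sqrt(((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2))
    if pooled == 0:
        if diff == 0:
            return 0.0
        warnings.warn("zero pooled sd with unequal means; effect size is infinite")
        return float(np.sign(diff) * np.inf)
    return float(diff / pooled)


def compare_scores(
    x: ScoreVector | pd.Series | np.ndarray,
    y: ScoreVector | pd.Series | np.ndarray,
    labels: tuple[str, str] = ("group_1", "group_2"),
    equal_var: bool = False,
) -> ComparisonReport:
    """Two-sided t test (Welch by default) plus Cohen's d between two groups."""
    xv = np.asarray(x.scores if isinstance(x, ScoreVector) else x, dtype=float)
    yv = np.asarray(y.scores if isinstance(y, ScoreVector) else y, dtype=float)
    if xv.size < 2 or yv.size < 2:
        raise ValueError("each group needs at least 2 values")
    d = cohens_d(xv, yv)
    if np.array_equal(xv, yv):
        t_stat, p = 0.0, 1.0
    else:
        t_stat, p = stats.ttest_ind(xv, yv, equal_var=equal_var)
    n1, n2 = xv.size, yv.size
    pooled = np.sqrt(
        ((n1 - 1) * xv.var(ddof=1) + (n2 - 1) * yv.var(ddof=1)) / (n1 + n2 - 2)
    )
    return ComparisonReport(
        label_1=labels[0],
        label_2=labels[1],
        n_1=n1,
        n_2=n2,
        mean_1=float(xv.mean()),
        mean_2=float(yv.mean()),
        pooled_sd=float(pooled),
        cohens_d=d,
        t_statistic=float(t_stat),
        p_value=float(p),
    )


def select_top_cells(
    scores: ScoreVector,
    labels: ClusterAssignment | None,
    cluster_id: int | None,
    n: int,
) -> list[str]:
    """The n highest-scoring cells of a cluster (or of all cells).

    Ties are broken by lexicographic cell id so the selection is
    deterministic.  If the cluster holds fewer than n cells, all are
    returned with a warning.
    """
    if labels is not None and cluster_id is not None:
        pool = labels.cells_in(cluster_id)
    else:
        pool = list(scores.scores.index)
    s = scores.scores.loc[pool]
    if len(s) < n:
        warnings.warn(f"requested top {n} cells but only {len(s)} available; returning all")
        n = len(s)
    order = sorted(s.index, key=lambda c: (-s[c], c))
    return order[:n]
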