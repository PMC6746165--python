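"""Per-condition protein co-expression networks.

For each rearing condition the 7x7 matrix of pairwise Pearson correlations
is computed over the condition's samples (pooled across the three V1
regions), with two-sided p-values from the t transform of R on n-2 degrees
of freedom and Bonferroni correction over the 21 unique protein pairs.
Proteins are ordered by hierarchical clustering on 1 - R so proteins with
similar correlation patterns sit on nearby dendrogram leaves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr

from .preprocess import ExpressionMatrix

__all__ = [
    "CorrelationResult",
    "condition_correlations",
    "seriate_proteins",
    "pairwise_pearson",
    "canonical_leaf_order",
]

#: Unique off-diagonal pairs among 7 proteins; the Bonferroni denominator.
N_PROTEIN_PAIRS = 21


@dataclass
class CorrelationResult:
    """Pairwise Pearson correlations with Bonferroni-corrected significance."""

    r: pd.DataFrame
    p_raw: pd.DataFrame
    alpha_adjusted: float
    leaf_order: list[str]
    significant_mask: pd.DataFrame
    n_samples: int
    condition: str | None = None


def pairwise_pearson(values: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """7x7 Pearson R and two-sided p-value matrices over the given samples.

    A constant column leaves its pairs undefined (NaN in both matrices).
    """
    cols = list(values.columns)
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            x, y = values.iloc[:, i], values.iloc[:, j]
            if x.std(ddof=0) == 0 or y.std(ddof=0) == 0:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            res = pearsonr(x, y)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    return (
        pd.DataFrame(r, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
    )


def condition_correlations(
    matrix: ExpressionMatrix,
    condition: str,
    alpha: float = 0.05,
) -> CorrelationResult:
    """Correlation network for one condition, regions pooled.

    Requires at least 3 samples (the p-value needs n - 2 >= 1).  The
    adjusted threshold is ``alpha / 21``.
    """
    values = matrix.rows_for_condition(condition)
    if len(values) < 3:
        raise ValueError(
            f"condition {condition!r} has {len(values)} samples; need >= 3 for Pearson p-values"
        )
    r, p = pairwise_pearson(values)
    alpha_adj = alpha / N_PROTEIN_PAIRS
    mask = (p < alpha_adj).fillna(False)
    np.fill_diagonal(mask.values, False)
    leaf_order, _ = seriate_proteins(r)
    return CorrelationResult(
        r=r,
        p_raw=p,
        alpha_adjusted=alpha_adj,
        leaf_order=leaf_order,
        significant_mask=mask,
        n_samples=len(values),
        condition=condition,
    )


def canonical_leaf_order(link: np.ndarray, n: int) -> list[int]:
    """Leaf order with children of every merge sorted by smallest member index.

    Any left-right orientation of a dendrogram's children is a valid leaf
    ordering; anchoring on the minimum original index makes the order a pure
    function of the tree, so equal-distance inputs keep their input order.
    """

    def rec(node: int) -> tuple[list[int], int]:
        if node < n:
            return [node], node
        a, b = int(link[node - n, 0]), int(link[node - n, 1])
        la, ma = rec(a)
        lb, mb = rec(b)
        return (la + lb, ma) if ma < mb else (lb + la, mb)

    return rec(n + len(link) - 1)[0]


def seriate_proteins(r: pd.DataFrame) -> tuple[list[str], np.ndarray]:
    """Order proteins by average-linkage clustering on distance 1 - R.

    Undefined correlations (constant columns) are treated as distance 1
    (uncorrelated) for ordering purposes only.  Deterministic, with ties
    broken by input index via the canonical leaf order.
    """
    labels = list(r.columns)
    d = 1.0 - r.to_numpy(dtype=float)
    d = np.where(np.isnan(d), 1.0, d)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    link = linkage(squareform(d, checks=False), method="average")
    order = canonical_leaf_order(link, len(labels))
    return [labels[i] for i in order], link
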