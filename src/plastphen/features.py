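"""Centered-SVD PCA and the nine plasticity features.

The expression matrix (samples x 7 proteins) is column-centered and
decomposed by SVD.  Basis vectors, variance fractions and per-protein cos^2
quality diagnostics guide the construction of nine candidate plasticity
features: three mean-scaled protein sums and six contrast indices of the
form (a - b) / (a + b), each bounded in [-1, 1] for nonnegative inputs.
Features are screened by correlating them against the first three principal
dimensions with Bonferroni correction; the excitatory:inhibitory (E:I)
index is kept for phenotype display even when it fails screening, because
of its importance for experience-dependent plasticity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .preprocess import ExpressionMatrix

__all__ = [
    "SUM_FEATURES",
    "INDEX_FEATURES",
    "FEATURE_NAMES",
    "PCAResult",
    "run_pca",
    "cos2_by_protein",
    "compute_features",
    "feature_table",
    "ScreeningResult",
    "screen_features",
]

SUM_FEATURES = ("all_protein_sum", "glutr_sum", "gabar_sum")
INDEX_FEATURES = (
    "ei_index",
    "gaba1_glun2a",
    "glun2b_glun2a",
    "gaba1_gaba3",
    "glun2b_glua2",
    "glun2a_glua2",
)
FEATURE_NAMES = SUM_FEATURES + INDEX_FEATURES

#: Screening tests: 9 features x first 3 dimensions.
N_SCREEN_TESTS = 27
_SCREEN_DIMS = ("Dim1", "Dim2", "Dim3")


@dataclass
class PCAResult:
    """Column-centered SVD decomposition of the expression matrix.

    ``loadings`` holds the orthonormal basis vectors as columns (Dim1..Dim7,
    indexed by protein); ``scores`` the sample coordinates.  The sign of each
    basis vector is fixed by making its largest-magnitude entry positive.
    """

    center: pd.Series
    loadings: pd.DataFrame
    scores: pd.DataFrame
    variance_fraction: np.ndarray
    singular_values: np.ndarray

    @property
    def dims(self) -> list[str]:
        return list(self.scores.columns)

    def reconstruct(self) -> pd.DataFrame:
        """Scores x loadings' + center; equals the input within 1e-8."""
        rec = self.scores.to_numpy() @ self.loadings.to_numpy().T + self.center.to_numpy()
        return pd.DataFrame(rec, index=self.scores.index, columns=self.loadings.index)


def run_pca(matrix: ExpressionMatrix) -> PCAResult:
    """Centered SVD of the samples x proteins matrix.

    Variance fractions come from the squared singular values.  Rank-deficient
    input simply yields trailing zero variance fractions.
    """
    if matrix.n_samples < 8:
        raise ValueError(f"PCA needs >= 8 complete rows, got {matrix.n_samples}")
    x = matrix.values.to_numpy(dtype=float)
    center = x.mean(axis=0)
    xc = x - center
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    # SVD sign indeterminacy: force the largest-|loading| entry positive
    for j in range(vt.shape[0]):
        i = int(np.argmax(np.abs(vt[j])))
        if vt[j, i] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    dims = [f"Dim{k + 1}" for k in range(len(s))]
    total = float((s**2).sum())
    var_frac = s**2 / total if total > 0 else np.zeros_like(s)
    return PCAResult(
        center=pd.Series(center, index=matrix.proteins),
        loadings=pd.DataFrame(vt.T, index=matrix.proteins, columns=dims),
        scores=pd.DataFrame(u * s, index=matrix.values.index, columns=dims),
        variance_fraction=var_frac,
        singular_values=s,
    )


def cos2_by_protein(pca: PCAResult, matrix: ExpressionMatrix) -> pd.DataFrame:
    """Quality of representation of each protein on each dimension.

    The squared Pearson correlation between the protein's column and the
    score column; rows sum to 1 over all 7 dimensions (degenerate score
    columns contribute 0).  A zero-variance protein column is undefined and
    reported as a NaN row.
    """
    x = matrix.values
    out = pd.DataFrame(0.0, index=pca.loadings.index, columns=pca.dims)
    for protein in out.index:
        col = x[protein].to_numpy(dtype=float)
        if col.std() == 0:
            out.loc[protein] = np.nan
            continue
        for dim in pca.dims:
            sc = pca.scores[dim].to_numpy()
            if sc.std() == 0:
                out.loc[protein, dim] = 0.0
            else:
                out.loc[protein, dim] = float(np.corrcoef(col, sc)[0, 1] ** 2)
    return out


# ---------------------------------------------------------------------------
# plasticity features


def _index(a: float, b: float) -> float:
    """Contrast index (a - b) / (a + b); NaN when the denominator is zero."""
    denom = a + b
    return np.nan if denom == 0 else (a - b) / denom


def compute_features(od: Mapping[str, float]) -> dict[str, float]:
    """The nine plasticity features of one sample.

    Three mean-scaled sums (all proteins / 7, glutamatergic receptors / 4,
    GABA_A receptors / 2) and six contrast indices.  Every index is oriented
    so the first-named mature subunit is positive: e.g. the GluN2B:GluN2A
    band computes (GluN2A - GluN2B) / (GluN2A + GluN2B), positive when
    GluN2A dominates.  Undefined indices (zero denominator) come back NaN.
    """
    missing = [p for p in ("GluA2", "GluN1", "GluN2A", "GluN2B", "GABAAa1", "GABAAa3", "Synapsin") if p not in od]
    if missing:
        raise ValueError(f"missing proteins {missing}")
    if any(od[p] < 0 for p in od):
        raise ValueError("optical densities must be nonnegative")
    glua2, glun1, glun2a, glun2b = od["GluA2"], od["GluN1"], od["GluN2A"], od["GluN2B"]
    a1, a3, syn = od["GABAAa1"], od["GABAAa3"], od["Synapsin"]
    glutr = (glua2 + glun1 + glun2a + glun2b) / 4.0
    gabar = (a1 + a3) / 2.0
    return {
        "all_protein_sum": (glua2 + glun1 + glun2a + glun2b + a1 + a3 + syn) / 7.0,
        "glutr_sum": glutr,
        "gabar_sum": gabar,
        "ei_index": _index(glutr, gabar),
        "gaba1_glun2a": _index(glun2a, a1),
        "glun2b_glun2a": _index(glun2a, glun2b),
        "gaba1_gaba3": _index(a1, a3),
        "glun2b_glua2": _index(glun2b, glua2),
        "glun2a_glua2": _index(glun2a, glua2),
    }


def feature_table(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-sample table of the nine features, row-aligned with the matrix."""
    rows = [compute_features(dict(r)) for _, r in matrix.values.iterrows()]
    return pd.DataFrame(rows, index=matrix.values.index, columns=list(FEATURE_NAMES))


@dataclass
class ScreeningResult:
    """Feature-vs-dimension screening outcome."""

    correlations: pd.DataFrame  # 9 features x Dim1-3, Pearson R
    p_values: pd.DataFrame
    alpha_adjusted: float
    retained: list[str]  # features significant on >= 1 dimension
    clustering_features: list[str]  # input to tSNE/k-means
    phenotype_features: list[str]  # always includes the E:I index


def screen_features(
    features: pd.DataFrame,
    pca: PCAResult,
    alpha: float = 0.05,
) -> ScreeningResult:
    """Correlate each feature with Dim1-3 and keep the significant ones.

    Bonferroni over the 27 tests.  A feature enters clustering if at least
    one adjusted-significant correlation exists; the E:I index is carried
    into the phenotype display regardless, but stays out of the clustering
    input when it fails screening.
    """
    if len(features) != len(pca.scores):
        raise ValueError("features and PCA scores are not row-aligned")
    alpha_adj = alpha / N_SCREEN_TESTS
    r = pd.DataFrame(index=list(FEATURE_NAMES), columns=list(_SCREEN_DIMS), dtype=float)
    p = r.copy()
    for feat in FEATURE_NAMES:
        fv = features[feat].to_numpy(dtype=float)
        for dim in _SCREEN_DIMS:
            sc = pca.scores[dim].to_numpy()
            if fv.std() == 0 or sc.std() == 0:
                r.loc[feat, dim] = np.nan
                p.loc[feat, dim] = np.nan
            else:
                res = pearsonr(fv, sc)
                r.loc[feat, dim] = res.statistic
                p.loc[feat, dim] = res.pvalue
    sig = (p < alpha_adj).fillna(False)
    retained = [f for f in FEATURE_NAMES if sig.loc[f].any()]
    clustering = list(retained)
    phenotype = list(retained if "ei_index" in retained else retained + ["ei_index"])
    return ScreeningResult(
        correlations=r,
        p_values=p,
        alpha_adjusted=alpha_adj,
        retained=retained,
        clustering_features=clustering,
        phenotype_features=phenotype,
    )
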