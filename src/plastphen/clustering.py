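"""tSNE embedding, k-means with the exponential-tau elbow, and subclusters.

The screened plasticity features are z-scored (sums near 1 and indices in
[-1, 1] live on incompatible scales), embedded to 2D with tSNE, and sorted
into clusters with k-means.  The number of clusters comes from the elbow
rule: fit WSS(k) = A * exp(-k / tau) + C to the within-cluster
sum-of-squares curve and take k* = round(4 * tau), clamped to the scanned
range.  Samples of one rearing condition inside one cluster form a
"subcluster" when they number at least 2 and exceed 20% of the cluster;
subcluster similarity is the Pearson correlation between mean feature
vectors, Bonferroni-corrected over all pairs and ordered by average-linkage
clustering on 1 - R.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.optimize import curve_fit
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE

from .networks import canonical_leaf_order

__all__ = [
    "ClusterResult",
    "SubclusterProfile",
    "zscore_features",
    "embed_tsne",
    "fit_elbow",
    "choose_k",
    "kmeans_assign",
    "cluster_samples",
    "annotate_subclusters",
    "subcluster_similarity",
]

DEFAULT_PERPLEXITY = 15.0
DEFAULT_TSNE_ITER = 1000
DEFAULT_RESTARTS = 50


def zscore_features(features: pd.DataFrame) -> pd.DataFrame:
    """Per-feature standardization to mean 0, SD 1 (constant columns -> 0)."""
    sd = features.std(ddof=0).replace(0.0, 1.0)
    return (features - features.mean()) / sd


def embed_tsne(
    feature_matrix: pd.DataFrame,
    perplexity: float = DEFAULT_PERPLEXITY,
    seed: int = 20190903,
    n_iter: int = DEFAULT_TSNE_ITER,
) -> pd.DataFrame:
    """2D tSNE of the (already standardized) feature matrix.

    Deterministic for a fixed seed.  Coordinates are re-centered on the
    origin.  Perplexity must satisfy n > 3 * perplexity.
    """
    n = len(feature_matrix)
    if n <= 3 * perplexity:
        raise ValueError(
            f"perplexity {perplexity} too large for n={n}; need n > 3*perplexity "
            f"(max usable perplexity {max((n - 1) / 3.0, 0):.1f})"
        )
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        max_iter=n_iter,
        init="pca",
        random_state=seed,
        method="barnes_hut",
    )
    coords = tsne.fit_transform(feature_matrix.to_numpy(dtype=float))
    coords = coords - coords.mean(axis=0)
    return pd.DataFrame(coords, index=feature_matrix.index, columns=["tsne1", "tsne2"])


def _wss_curve(
    x: np.ndarray, k_values: range, seed: int, restarts: int
) -> dict[int, float]:
    wss = {}
    for k in k_values:
        km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
        km.fit(x)
        wss[k] = float(km.inertia_)
    return wss


def _exp_elbow(k, a, tau, c):
    return a * np.exp(-k / tau) + c


@dataclass
class ElbowResult:
    k: int
    tau: float
    wss_by_k: dict[int, float]
    fit_params: dict[str, float] | None
    used_fallback: bool = False


def fit_elbow(wss_by_k: dict[int, float], k_range: range | None = None) -> ElbowResult:
    """Fit WSS(k) = A*exp(-k/tau) + C and take k* = round(4*tau), clamped.

    Rounding is half-up.  If the exponential fit fails (e.g. the WSS curve
    is not decreasing), falls back to the largest-second-difference elbow
    with a warning flag on the result.
    """
    ks = np.array(sorted(wss_by_k))
    ys = np.array([wss_by_k[k] for k in ks])
    lo, hi = (k_range.start, k_range.stop - 1) if k_range else (int(ks[0]), int(ks[-1]))
    try:
        span = float(ys.max() - ys.min())
        p0 = (span if span > 0 else 1.0, 2.0, float(ys.min()))
        popt, _ = curve_fit(
            _exp_elbow, ks.astype(float), ys, p0=p0,
            bounds=((0.0, 1e-6, -np.inf), np.inf), maxfev=20000,
        )
        tau = float(popt[1])
        k_star = int(np.clip(int(np.floor(4.0 * tau + 0.5)), lo, hi))
        return ElbowResult(
            k=k_star,
            tau=tau,
            wss_by_k=dict(wss_by_k),
            fit_params={"amplitude": float(popt[0]), "tau": tau, "offset": float(popt[2])},
        )
    except RuntimeError:
        # largest drop in slope (max second difference)
        second = np.diff(ys, 2)
        k_star = int(ks[int(np.argmax(second)) + 1]) if len(second) else int(ks[0])
        return ElbowResult(
            k=k_star, tau=float("nan"), wss_by_k=dict(wss_by_k),
            fit_params=None, used_fallback=True,
        )


def choose_k(
    feature_matrix: pd.DataFrame,
    k_range: range = range(2, 10),
    seed: int = 0,
    restarts: int = DEFAULT_RESTARTS,
) -> ElbowResult:
    """Scan k over ``k_range`` with best-of-restarts k-means, then fit the elbow."""
    n = len(feature_matrix)
    if k_range.stop - 1 >= n:
        raise ValueError(f"k_range upper bound must stay below n={n}")
    wss = _wss_curve(feature_matrix.to_numpy(dtype=float), k_range, seed, restarts)
    return fit_elbow(wss, k_range=k_range)


def kmeans_assign(
    coordinates: pd.DataFrame,
    k: int,
    seed: int = 0,
    restarts: int = DEFAULT_RESTARTS,
) -> pd.Series:
    """Best-of-restarts k-means labels, canonicalized by descending cluster size.

    Labels run 1..k; cluster 1 is the largest.  Ties in size break by the
    original k-means label for determinism.
    """
    if k > len(coordinates):
        raise ValueError(f"k={k} exceeds n={len(coordinates)}")
    x = coordinates.to_numpy(dtype=float)
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    raw = km.fit_predict(x)
    sizes = pd.Series(raw).value_counts()
    order = sorted(sizes.index, key=lambda lbl: (-sizes[lbl], lbl))
    remap = {old: new + 1 for new, old in enumerate(order)}
    return pd.Series([remap[v] for v in raw], index=coordinates.index, name="cluster")


@dataclass
class ClusterResult:
    """Embedding, chosen k, assignments and the elbow diagnostics."""

    embedding: pd.DataFrame
    k: int
    assignments: pd.Series
    wss_by_k: dict[int, float]
    tau: float
    seed: int
    perplexity: float
    used_fallback: bool = False


def cluster_samples(
    feature_matrix: pd.DataFrame,
    perplexity: float = DEFAULT_PERPLEXITY,
    seed: int = 20190903,
    k: int | None = None,
    k_range: range = range(2, 10),
    restarts: int = DEFAULT_RESTARTS,
    standardize: bool = True,
    cluster_on: str = "embedding",
) -> ClusterResult:
    """Full embed-and-cluster stage: z-score, tSNE, elbow, k-means.

    The elbow scan always runs on the standardized features (the WSS decay
    of the exaggeratedly separated tSNE coordinates is too sharp for the
    exponential-tau rule); ``cluster_on`` selects whether the final k-means
    assignment runs on the 2D tSNE coordinates (default) or on the
    standardized feature matrix.
    """
    feats = zscore_features(feature_matrix) if standardize else feature_matrix
    embedding = embed_tsne(feats, perplexity=perplexity, seed=seed)
    basis = embedding if cluster_on == "embedding" else feats
    if k is None:
        elbow = choose_k(feats, k_range=k_range, seed=seed, restarts=restarts)
        k, tau, wss, fallback = elbow.k, elbow.tau, elbow.wss_by_k, elbow.used_fallback
    else:
        tau, wss, fallback = float("nan"), {}, False
    assignments = kmeans_assign(basis, k=k, seed=seed, restarts=restarts)
    return ClusterResult(
        embedding=embedding,
        k=k,
        assignments=assignments,
        wss_by_k=wss,
        tau=tau,
        seed=seed,
        perplexity=perplexity,
        used_fallback=fallback,
    )


# ---------------------------------------------------------------------------
# subclusters

_REGION_ORDER = {"C": 0, "P": 1, "M": 2}


@dataclass
class SubclusterProfile:
    """One rearing condition's members inside one k-means cluster."""

    label: str
    condition: str
    cluster: int
    member_rows: list
    n: int
    regions: tuple[str, ...]
    mean_features: pd.Series


def annotate_subclusters(
    assignments: pd.Series,
    metadata: pd.DataFrame,
    features: pd.DataFrame,
    min_n: int = 2,
    min_frac: float = 0.20,
) -> list[SubclusterProfile]:
    """Qualify (condition x cluster) groups as subclusters.

    A group qualifies when it has at least ``min_n`` members and makes up
    strictly more than ``min_frac`` of its cluster.  Labels carry the
    cluster id and, when the group does not span all three V1 regions, a
    region subscript (e.g. "MD 3_CP").  Pure bookkeeping: no randomness.
    """
    if not assignments.index.equals(metadata.index):
        raise ValueError("assignments and metadata are not row-aligned")
    cluster_sizes = assignments.value_counts()
    out: list[SubclusterProfile] = []
    grouped = metadata.groupby([metadata["condition"], assignments], sort=False)
    for (condition, cluster), sub in grouped:
        n = len(sub)
        if n < min_n or n / cluster_sizes[cluster] <= min_frac:
            continue
        regions = tuple(sorted(set(sub["region"]), key=lambda x: _REGION_ORDER.get(x, 9)))
        label = f"{condition} {cluster}"
        if len(regions) < 3:
            label += "_" + "".join(regions)
        out.append(
            SubclusterProfile(
                label=label,
                condition=condition,
                cluster=int(cluster),
                member_rows=list(sub.index),
                n=n,
                regions=regions,
                mean_features=features.loc[sub.index].mean(),
            )
        )
    out.sort(key=lambda s: (s.cluster, s.condition))
    return out


@dataclass
class SubclusterSimilarity:
    r: pd.DataFrame
    p_raw: pd.DataFrame
    alpha_adjusted: float
    n_pairs: int
    leaf_order: list[str]
    linkage: np.ndarray


def subcluster_similarity(
    subclusters: list[SubclusterProfile],
    feature_names: list[str] | None = None,
    alpha: float = 0.05,
) -> SubclusterSimilarity:
    """Pairwise Pearson R between subcluster mean-feature vectors.

    With m subclusters there are C(m, 2) pairs and the Bonferroni threshold
    is alpha / C(m, 2).  Correlating 8-dimensional mean vectors leaves n - 2
    = 6 degrees of freedom for the p-values.  Dendrogram order comes from
    average linkage on 1 - R.
    """
    m = len(subclusters)
    if m < 3:
        raise ValueError(f"need >= 3 subclusters, got {m}")
    labels = [s.label for s in subclusters]
    vectors = []
    for s in subclusters:
        v = s.mean_features[feature_names] if feature_names else s.mean_features
        v = v.to_numpy(dtype=float)
        if np.std(v) == 0:
            raise ValueError(f"subcluster {s.label!r} has a constant mean-feature vector")
        vectors.append(v)
    r = np.eye(m)
    p = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            res = pearsonr(vectors[i], vectors[j])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    n_pairs = m * (m - 1) // 2
    d = np.clip(1.0 - r, 0.0, None)
    np.fill_diagonal(d, 0.0)
    link = linkage(squareform((d + d.T) / 2.0, checks=False), method="average")
    order = [labels[i] for i in canonical_leaf_order(link, m)]
    return SubclusterSimilarity(
        r=pd.DataFrame(r, index=labels, columns=labels),
        p_raw=pd.DataFrame(p, index=labels, columns=labels),
        alpha_adjusted=alpha / n_pairs,
        n_pairs=n_pairs,
        leaf_order=order,
        linkage=link,
    )
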