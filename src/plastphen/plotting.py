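"""Figure helpers: correlation heatmaps, phenotype band stacks, kinetics plots.

All figures are companions to CSV tables written by the pipeline; nothing
downstream reads pixels.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .features import FEATURE_NAMES
from .networks import CorrelationResult
from .phenotype import PhenotypeProfile

__all__ = [
    "plot_correlation_heatmap",
    "plot_variance_fractions",
    "plot_embedding",
    "plot_phenotype_bands",
    "plot_kinetics_scatter",
]


def _stars(p: float, alpha_adj: float) -> str:
    # asterisk thresholds at the adjusted 0.05 / 0.01 / 0.001 levels
    for stars, factor in (("***", 0.001 / 0.05), ("**", 0.01 / 0.05), ("*", 1.0)):
        if p < alpha_adj * factor:
            return stars
    return ""


def plot_correlation_heatmap(result: CorrelationResult, path) -> None:
    order = result.leaf_order
    r = result.r.loc[order, order]
    p = result.p_raw.loc[order, order]
    fig, ax = plt.subplots(figsize=(5.2, 4.6))
    im = ax.imshow(r.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(order)), order, rotation=45, ha="right")
    ax.set_yticks(range(len(order)), order)
    for i in range(len(order)):
        for j in range(len(order)):
            if i == j or np.isnan(p.iat[i, j]):
                continue
            s = _stars(p.iat[i, j], result.alpha_adjusted)
            if s:
                ax.text(j, i, s, ha="center", va="center", fontsize=8)
    title = result.condition or "correlations"
    ax.set_title(f"{title} (n={result.n_samples})")
    fig.colorbar(im, ax=ax, label="Pearson R")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_variance_fractions(variance_fraction: np.ndarray, path) -> None:
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    dims = np.arange(1, len(variance_fraction) + 1)
    ax.bar(dims, 100 * variance_fraction, color="steelblue")
    ax.set_xlabel("principal dimension")
    ax.set_ylabel("% of variance")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_embedding(embedding: pd.DataFrame, labels: pd.Series, path, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(5.0, 4.4))
    for value in pd.unique(labels):
        mask = (labels == value).to_numpy()
        ax.scatter(
            embedding.iloc[mask, 0], embedding.iloc[mask, 1], s=18, label=str(value)
        )
    ax.set_xlabel("tSNE 1")
    ax.set_ylabel("tSNE 2")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=7, markerscale=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_phenotype_bands(profiles: list[PhenotypeProfile], path) -> None:
    """Stacked color bands, one column per subcluster, one row per feature."""
    fig, ax = plt.subplots(figsize=(1.0 + 0.6 * len(profiles), 4.2))
    for col, prof in enumerate(profiles):
        for row, feat in enumerate(FEATURE_NAMES):
            color = prof.colors.get(feat)
            ax.add_patch(
                plt.Rectangle(
                    (col, len(FEATURE_NAMES) - 1 - row),
                    0.9,
                    0.9,
                    facecolor=color if color else "none",
                    edgecolor="0.6",
                    hatch=None if color else "//",
                )
            )
    ax.set_xlim(0, len(profiles))
    ax.set_ylim(0, len(FEATURE_NAMES))
    ax.set_xticks([c + 0.45 for c in range(len(profiles))])
    ax.set_xticklabels([p.label for p in profiles], rotation=60, ha="right", fontsize=7)
    ax.set_yticks([len(FEATURE_NAMES) - 1 - i + 0.45 for i in range(len(FEATURE_NAMES))])
    ax.set_yticklabels(FEATURE_NAMES, fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_kinetics_scatter(table: pd.DataFrame, path) -> None:
    """GABA_A_R (x) vs NMDAR (y) predicted decay times per group."""
    fig, ax = plt.subplots(figsize=(4.8, 4.2))
    ax.scatter(table["gabaar_ms"], table["nmdar_ms"], s=28, color="darkred")
    for label, row in table.iterrows():
        ax.annotate(str(label), (row["gabaar_ms"], row["nmdar_ms"]), fontsize=6,
                    xytext=(3, 3), textcoords="offset points")
    ax.set_xlabel("GABA$_A$R population decay (ms)")
    ax.set_ylabel("NMDAR population decay (ms)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
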