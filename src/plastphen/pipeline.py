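"""End-to-end orchestration of the plasticity-phenotype workflow.

Stages run in order — simulate (or ingest), preprocess, networks, PCA +
features, clustering, phenotype, kinetics — with every stage reading only
files written by earlier stages, so any stage can be re-run in place.  A
run manifest records seeds, parameters and the files each stage produced.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clustering import (
    annotate_subclusters,
    cluster_samples,
    subcluster_similarity,
)
from .features import (
    FEATURE_NAMES,
    cos2_by_protein,
    feature_table,
    run_pca,
    screen_features,
)
from .kinetics import kinetics_trajectory_table
from .networks import condition_correlations
from .phenotype import BootstrapConfig, build_phenotype, compare_all
from .preprocess import (
    ExpressionMatrix,
    assemble_matrix,
    average_runs,
    normalize_to_reference,
    read_long_csv,
)
from .synthetic import (
    default_effects,
    design_from_config,
    effects_from_config,
    generate_dataset,
    table2_design,
    write_long_csv,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure with a machine-readable record."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.record = {"stage": stage, "error": message}


@dataclass
class PipelineConfig:
    """Everything a full run needs; see the bundled demo config."""

    outdir: Path
    seed: int = 0
    input_csv: Path | None = None  # user data; None -> synthetic
    design_config: Path | None = None  # synthetic design; None -> bundled layout
    effects_config: Path | None = None
    reference_condition: str = "5wk_normal"
    perplexity: float = 15.0
    k: int | None = None
    kmeans_restarts: int = 50
    cluster_on: str = "embedding"
    reduced_bootstrap: bool = False
    bootstrap_convention: str = "simulate_subcluster"

    @classmethod
    def from_file(cls, path, **overrides) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        raw["outdir"] = Path(raw["outdir"])
        for key in ("input_csv", "design_config", "effects_config"):
            if raw.get(key):
                raw[key] = Path(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        for key in ("input_csv", "design_config", "effects_config"):
            p = getattr(self, key)
            if p is not None and not Path(p).exists():
                raise PipelineError("config", f"{key} path {p} does not exist")


def _stage_seeds(master: int) -> dict[str, int]:
    ss = np.random.SeedSequence(master)
    children = ss.spawn(3)
    names = ("data", "cluster", "bootstrap")
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(names, children)
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the manifest (also written as JSON)."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest: dict = {
        "package_version": __version__,
        "python": sys.version.split()[0],
        "master_seed": config.seed,
        "stage_seeds": seeds,
        "parameters": {
            "reference_condition": config.reference_condition,
            "perplexity": config.perplexity,
            "k": config.k,
            "kmeans_restarts": config.kmeans_restarts,
            "cluster_on": config.cluster_on,
            "reduced_bootstrap": config.reduced_bootstrap,
            "bootstrap_convention": config.bootstrap_convention,
        },
        "stages": {},
    }

    dataset_csv = stage_simulate(config, seeds["data"]) if config.input_csv is None else config.input_csv
    manifest["stages"]["simulate"] = {"dataset": str(dataset_csv)}

    matrix = stage_preprocess(config, dataset_csv)
    manifest["stages"]["preprocess"] = {
        "n_samples": matrix.n_samples,
        "n_dropped": matrix.n_dropped,
        "n_observations": matrix.n_observations,
        "files": ["matrix.csv", "matrix_meta.json"],
    }

    manifest["stages"]["networks"] = stage_networks(config, matrix)
    pca, features, screening = stage_features(config, matrix)
    manifest["stages"]["features"] = {
        "variance_fraction": [float(v) for v in pca.variance_fraction],
        "retained_features": screening.retained,
        "files": ["pca_variance.csv", "pca_loadings.csv", "pca_cos2.csv",
                  "feature_table.csv", "screening.json"],
    }

    clusters, subclusters, similarity = stage_cluster(config, matrix, features, screening, seeds["cluster"])
    manifest["stages"]["cluster"] = {
        "k": clusters.k,
        "tau": clusters.tau,
        "n_subclusters": len(subclusters),
        "files": ["embedding.csv", "assignments.csv", "elbow.json",
                  "subclusters.csv", "subcluster_correlations.csv"],
    }

    manifest["stages"]["phenotype"] = stage_phenotype(
        config, matrix, features, subclusters, seeds["bootstrap"]
    )
    manifest["stages"]["kinetics"] = stage_kinetics(config, matrix)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


# ---------------------------------------------------------------------------
# stages


def stage_simulate(config: PipelineConfig, seed: int) -> Path:
    out = Path(config.outdir)
    design = (
        design_from_config(str(config.design_config))
        if config.design_config
        else table2_design()
    )
    effects = (
        effects_from_config(str(config.effects_config))
        if config.effects_config
        else default_effects()
    )
    missing = set(design.conditions) - set(effects)
    if missing:
        raise PipelineError("simulate", f"no effects for conditions {sorted(missing)}")
    dataset = generate_dataset(design, effects, seed=seed)
    path = out / "dataset.csv"
    write_long_csv(dataset, path)
    return path


def stage_preprocess(config: PipelineConfig, dataset_csv) -> ExpressionMatrix:
    out = Path(config.outdir)
    dataset = read_long_csv(dataset_csv)
    if config.reference_condition not in set(dataset["condition"]):
        raise PipelineError(
            "preprocess",
            f"reference condition {config.reference_condition!r} not present in data",
        )
    dataset = normalize_to_reference(dataset, config.reference_condition)
    dataset = average_runs(dataset)
    matrix = assemble_matrix(dataset, drop_incomplete=True)
    matrix.write(out / "matrix.csv", out / "matrix_meta.json")
    return matrix


def stage_networks(config: PipelineConfig, matrix: ExpressionMatrix) -> dict:
    from .plotting import plot_correlation_heatmap

    out = Path(config.outdir)
    conditions = [
        c
        for c in pd.unique(matrix.metadata["condition"])
        if (matrix.metadata["condition"] == c).sum() >= 3
    ]
    files = []
    for cond in conditions:
        res = condition_correlations(matrix, cond)
        safe = str(cond).replace("/", "_")
        res.r.to_csv(out / f"network_{safe}_r.csv")
        res.p_raw.to_csv(out / f"network_{safe}_p.csv")
        plot_correlation_heatmap(res, out / f"network_{safe}.png")
        files.append(safe)
    return {"conditions": files, "alpha_adjusted": 0.05 / 21}


def stage_features(config: PipelineConfig, matrix: ExpressionMatrix):
    from .plotting import plot_variance_fractions

    out = Path(config.outdir)
    pca = run_pca(matrix)
    pd.DataFrame(
        {"variance_fraction": pca.variance_fraction}, index=pca.dims
    ).to_csv(out / "pca_variance.csv")
    pca.loadings.to_csv(out / "pca_loadings.csv")
    cos2_by_protein(pca, matrix).to_csv(out / "pca_cos2.csv")
    plot_variance_fractions(pca.variance_fraction, out / "pca_variance.png")

    features = feature_table(matrix)
    features.to_csv(out / "feature_table.csv")
    screening = screen_features(features, pca)
    with open(out / "screening.json", "w") as fh:
        json.dump(
            {
                "alpha_adjusted": screening.alpha_adjusted,
                "retained": screening.retained,
                "clustering_features": screening.clustering_features,
                "phenotype_features": screening.phenotype_features,
                "correlations": screening.correlations.round(4).to_dict(),
            },
            fh,
            indent=1,
        )
    return pca, features, screening


def stage_cluster(config, matrix, features, screening, seed: int):
    from .plotting import plot_embedding

    out = Path(config.outdir)
    cluster_features = screening.clustering_features or list(FEATURE_NAMES)
    clusters = cluster_samples(
        features[cluster_features],
        perplexity=config.perplexity,
        seed=seed,
        k=config.k,
        restarts=config.kmeans_restarts,
        cluster_on=config.cluster_on,
    )
    clusters.embedding.to_csv(out / "embedding.csv")
    clusters.assignments.to_frame().join(matrix.metadata).to_csv(out / "assignments.csv")
    with open(out / "elbow.json", "w") as fh:
        json.dump(
            {
                "k": clusters.k,
                "tau": clusters.tau,
                "wss_by_k": {str(k): v for k, v in clusters.wss_by_k.items()},
                "seed": clusters.seed,
                "perplexity": clusters.perplexity,
                "used_fallback": clusters.used_fallback,
            },
            fh,
            indent=1,
        )
    plot_embedding(
        clusters.embedding, matrix.metadata["condition"], out / "embedding.png",
        title=f"tSNE (k={clusters.k})",
    )

    subclusters = annotate_subclusters(clusters.assignments, matrix.metadata, features)
    pd.DataFrame(
        [
            {
                "label": s.label,
                "condition": s.condition,
                "cluster": s.cluster,
                "n": s.n,
                "regions": "".join(s.regions),
                **{f"mean_{k}": v for k, v in s.mean_features.items()},
            }
            for s in subclusters
        ]
    ).to_csv(out / "subclusters.csv", index=False)

    similarity = None
    if len(subclusters) >= 3:
        similarity = subcluster_similarity(subclusters, feature_names=screening.clustering_features)
        similarity.r.to_csv(out / "subcluster_correlations.csv")
    return clusters, subclusters, similarity


def stage_phenotype(config, matrix, features, subclusters, seed: int) -> dict:
    from .plotting import plot_phenotype_bands

    out = Path(config.outdir)
    ref_rows = matrix.metadata.index[
        matrix.metadata["condition"] == config.reference_condition
    ]
    if len(ref_rows) == 0:
        raise PipelineError("phenotype", "no reference rows for bootstrap comparison")
    cfg = (
        BootstrapConfig.reduced(seed=seed, convention=config.bootstrap_convention)
        if config.reduced_bootstrap
        else BootstrapConfig(seed=seed, convention=config.bootstrap_convention)
    )
    sum_max = float(
        features[[f for f in FEATURE_NAMES if f.endswith("_sum")]].max().max()
    )
    profiles = [build_phenotype(s, sum_max=sum_max) for s in subclusters]
    grid = compare_all(subclusters, features, ref_rows, cfg)
    bands = []
    for prof in profiles:
        flags = grid[grid["subcluster"] == prof.label].set_index("feature")
        for feat in FEATURE_NAMES:
            bands.append(
                {
                    "subcluster": prof.label,
                    "feature": feat,
                    "value": prof.feature_values[feat],
                    "color": prof.colors[feat],
                    "direction": flags.loc[feat, "direction"] if feat in flags.index else None,
                    "level": flags.loc[feat, "level"] if feat in flags.index else None,
                }
            )
    pd.DataFrame(bands).to_csv(out / "phenotype_bands.csv", index=False)
    grid.to_csv(out / "phenotype_comparison.csv", index=False)
    plot_phenotype_bands(profiles, out / "phenotype_bands.png")
    return {
        "n_tests": len(grid),
        "sim_size": cfg.sim_size,
        "resamples": cfg.resamples,
        "files": ["phenotype_bands.csv", "phenotype_comparison.csv"],
    }


def stage_kinetics(config, matrix) -> dict:
    from .plotting import plot_kinetics_scatter

    out = Path(config.outdir)
    meta = matrix.metadata
    means = (
        matrix.values.join(meta[["condition", "region"]])
        .groupby(["condition", "region"], sort=False)
        .mean()
    )
    means.index = [f"{c}_{r}" for c, r in means.index]
    table = kinetics_trajectory_table(means)
    table.to_csv(out / "kinetics.csv")
    plot_kinetics_scatter(table, out / "kinetics.png")
    return {"n_groups": len(table), "files": ["kinetics.csv"]}
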