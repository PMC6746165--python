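"""Plasticity-phenotype bands and bootstrap comparison to the normal reference.

A subcluster's phenotype is the stack of its nine feature values rendered as
color-coded bands: grayscale for the three protein sums (white at 0, black
at the displayed maximum) and a red-yellow-green gradient for the six
indices (-1 red, 0 yellow, +1 green).

Each feature is tested against the 5 wk normal reference with the study's
bootstrap Monte-Carlo procedure: simulate a Gaussian population from the
subcluster's mean and SD, repeatedly resample it at the reference group's
size, form two-sided CIs of the resample means at the 95/99/99.9% levels,
and flag the feature when the reference mean falls outside.  A convention
switch mirrors which group is simulated and which mean is tested, since the
two readings of the procedure are both defensible.  Note the procedure
ignores the tested mean's own sampling noise, so its realized false-positive
rate exceeds the nominal level for groups of comparable size (see the
methods note); it is reproduced here as specified, not re-derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from matplotlib import colormaps
from matplotlib.colors import to_hex

from .clustering import SubclusterProfile
from .features import FEATURE_NAMES, INDEX_FEATURES, SUM_FEATURES

__all__ = [
    "BootstrapConfig",
    "BootstrapOutcome",
    "PhenotypeProfile",
    "index_color",
    "sum_color",
    "build_phenotype",
    "bootstrap_compare",
    "compare_all",
]

_RYG = colormaps["RdYlGn"]

#: The three CI levels the procedure reports, most extreme last.
CI_LEVELS = (0.05, 0.01, 0.001)


@dataclass(frozen=True)
class BootstrapConfig:
    """Monte-Carlo sizes and seed for the bootstrap comparison.

    Defaults follow the study protocol (1,000,000-point simulated
    populations, 100,000 resamples); ``reduced()`` gives a test-scale
    configuration.
    """

    sim_size: int = 1_000_000
    resamples: int = 100_000
    seed: int = 0
    convention: Literal["simulate_subcluster", "simulate_reference"] = "simulate_subcluster"

    def __post_init__(self) -> None:
        if self.sim_size < 1 or self.resamples < 1:
            raise ValueError("sim_size and resamples must be positive")

    @classmethod
    def reduced(cls, seed: int = 0, **kw) -> "BootstrapConfig":
        return cls(sim_size=100_000, resamples=10_000, seed=seed, **kw)


@dataclass
class BootstrapOutcome:
    """Direction, strongest exclusion level, and the CI table of one test."""

    direction: Literal["greater", "less", "not_different"]
    level: float | None  # most extreme nominal level excluding the tested mean
    ci_table: pd.DataFrame  # per level: lower, upper
    tested_mean: float
    degenerate: bool = False


def index_color(value: float) -> str:
    """Red-yellow-green hex color for an index in [-1, 1] (clipped)."""
    v = float(np.clip(value, -1.0, 1.0))
    return to_hex(_RYG((v + 1.0) / 2.0))


def sum_color(value: float, max_value: float) -> str:
    """Grayscale hex color for a sum: white at 0, black at the display max."""
    if max_value <= 0:
        raise ValueError("max_value must be positive")
    v = float(np.clip(value / max_value, 0.0, 1.0))
    g = 1.0 - v
    return to_hex((g, g, g))


@dataclass
class PhenotypeProfile:
    """Nine feature bands of one subcluster, with colors and test flags."""

    label: str
    feature_values: pd.Series
    colors: dict[str, str]
    significance: dict[str, BootstrapOutcome] = field(default_factory=dict)


def build_phenotype(
    subcluster: SubclusterProfile,
    sum_max: float | None = None,
) -> PhenotypeProfile:
    """Color-coded phenotype bands for one subcluster.

    ``sum_max`` anchors the grayscale map (the maximum sum across all
    displayed groups); defaults to this subcluster's own largest sum.
    Missing features render as absent bands (color None).
    """
    values = subcluster.mean_features.reindex(list(FEATURE_NAMES))
    if sum_max is None:
        sums = values[list(SUM_FEATURES)].dropna()
        sum_max = float(sums.max()) if len(sums) else 1.0
    colors: dict[str, str | None] = {}
    for name in FEATURE_NAMES:
        v = values[name]
        if pd.isna(v):
            colors[name] = None
        elif name in SUM_FEATURES:
            colors[name] = sum_color(v, sum_max)
        else:
            colors[name] = index_color(v)
    return PhenotypeProfile(label=subcluster.label, feature_values=values, colors=colors)


def _resample_mean_ci(
    population: np.ndarray,
    n: int,
    resamples: int,
    levels: Sequence[float],
    rng: np.random.Generator,
) -> pd.DataFrame:
    idx = rng.integers(0, len(population), size=(resamples, n))
    means = population[idx].mean(axis=1)
    rows = {}
    for lvl in levels:
        lo, hi = np.percentile(means, [100 * lvl / 2, 100 * (1 - lvl / 2)])
        rows[lvl] = {"lower": float(lo), "upper": float(hi)}
    return pd.DataFrame.from_dict(rows, orient="index")


def bootstrap_compare(
    subcluster_values: Sequence[float],
    reference_values: Sequence[float],
    config: BootstrapConfig,
    levels: Sequence[float] = CI_LEVELS,
) -> BootstrapOutcome:
    """Bootstrap Monte-Carlo test of one feature against the reference.

    Under the default convention, a Gaussian population with the
    subcluster's mean and SD is simulated (``sim_size`` points), resampled
    ``resamples`` times at the reference group's n, and the reference mean
    is compared to the two-sided CIs of the resample means.  The returned
    direction describes the *subcluster* relative to the reference: a
    reference mean above the CI means the subcluster is "less".  The
    mirrored convention swaps the roles of the two groups.

    A zero-SD simulated group degenerates to an exact comparison of means.
    """
    sub = np.asarray(subcluster_values, dtype=float)
    ref = np.asarray(reference_values, dtype=float)
    if len(sub) < 2 or len(ref) < 2:
        raise ValueError("both groups need >= 2 values")
    levels = sorted(levels, reverse=True)  # 0.05 first, most extreme last

    if config.convention == "simulate_subcluster":
        sim_mean, sim_sd = sub.mean(), sub.std(ddof=1)
        n_draw = len(ref)
        tested_mean = ref.mean()
        flip = False  # ref above CI -> subcluster less
    else:
        sim_mean, sim_sd = ref.mean(), ref.std(ddof=1)
        n_draw = len(sub)
        tested_mean = sub.mean()
        flip = True  # sub above CI -> subcluster greater

    rng = np.random.default_rng(config.seed)
    if sim_sd == 0:
        direction = (
            "not_different"
            if tested_mean == sim_mean
            else ("less" if (tested_mean > sim_mean) != flip else "greater")
        )
        ci = pd.DataFrame(
            {lvl: {"lower": sim_mean, "upper": sim_mean} for lvl in levels}
        ).T
        return BootstrapOutcome(
            direction=direction,
            level=(levels[-1] if direction != "not_different" else None),
            ci_table=ci,
            tested_mean=float(tested_mean),
            degenerate=True,
        )

    population = rng.normal(sim_mean, sim_sd, size=config.sim_size)
    ci = _resample_mean_ci(population, n_draw, config.resamples, levels, rng)

    direction: str = "not_different"
    hit_level: float | None = None
    for lvl in levels:  # nested CIs: walk towards the most extreme level
        lo, hi = ci.loc[lvl, "lower"], ci.loc[lvl, "upper"]
        if tested_mean > hi:
            direction, hit_level = ("greater" if flip else "less"), lvl
        elif tested_mean < lo:
            direction, hit_level = ("less" if flip else "greater"), lvl
        else:
            break
    return BootstrapOutcome(
        direction=direction,
        level=hit_level,
        ci_table=ci,
        tested_mean=float(tested_mean),
    )


def compare_all(
    subclusters: list[SubclusterProfile],
    feature_values: pd.DataFrame,
    reference_rows: Sequence,
    config: BootstrapConfig,
    correction: Literal["bonferroni", "none"] = "bonferroni",
    features: Sequence[str] = FEATURE_NAMES,
) -> pd.DataFrame:
    """Bootstrap-test every (subcluster, feature) against the reference rows.

    Bonferroni tightens the nominal CI levels by the number of tests
    (subclusters x features), keeping the nested-CI logic intact.  Returns a
    long grid with one row per test: direction, level, tested mean — the
    data behind the red/blue/white significance banding.
    """
    n_tests = len(subclusters) * len(features)
    if correction == "bonferroni":
        levels = tuple(lvl / n_tests for lvl in CI_LEVELS)
    else:
        levels = CI_LEVELS
    ref = feature_values.loc[list(reference_rows)]
    rows = []
    base = np.random.SeedSequence(config.seed)
    streams = iter(base.spawn(n_tests))
    for sc in subclusters:
        for feat in features:
            sub_vals = feature_values.loc[sc.member_rows, feat].dropna()
            ref_vals = ref[feat].dropna()
            cfg = BootstrapConfig(
                sim_size=config.sim_size,
                resamples=config.resamples,
                seed=int(next(streams).generate_state(1)[0] % (2**31)),
                convention=config.convention,
            )
            out = bootstrap_compare(sub_vals, ref_vals, cfg, levels=levels)
            # report on the nominal scale regardless of correction
            nominal = (
                CI_LEVELS[list(levels).index(out.level)] if out.level is not None else None
            )
            rows.append(
                {
                    "subcluster": sc.label,
                    "feature": feat,
                    "direction": out.direction,
                    "level": nominal,
                    "subcluster_mean": float(np.mean(sub_vals)),
                    "reference_mean": float(np.mean(ref_vals)),
                }
            )
    return pd.DataFrame(rows)
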