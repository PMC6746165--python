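"""Receptor-population decay-kinetics model for NMDAR and GABA_A_R subunit mixes.

The decay speed of NMDA and GABA-A receptors is set by their subunit
composition: triheteromeric NMDARs containing both GluN2A and GluN2B decay
with tau ~= 50 ms, GluN2A-only diheteromers are faster (36 ms) and
GluN2B-only diheteromers are much slower (333 ms).  GABA_A receptors behave
analogously with the alpha1 (fast, 42.2 ms) and alpha3 (slow, 129 ms)
subunits and a mixed-pair tau of 49 ms.

Given the *relative* expression of the mature and immature subunit in a
tissue sample, the population model pairs mature with immature subunits as
far as possible (mixed pairs are the most common receptor in cortex), splits
the leftover of the more abundant subunit into same-subunit pairs (divide by
two: two subunits per receptor), and reports the tau-weighted average over
the resulting receptor population.

The model is a piecewise-linear function of the immature-subunit fraction
``b``:  ``tau_fast + 2*(tau_pair - tau_fast)*b`` for ``b <= 1/2`` and
``2*(tau_slow - tau_pair)*b + (2*tau_pair - tau_slow)`` for ``b >= 1/2``,
continuous at ``b = 1/2`` where the population is all mixed pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "SubunitMix",
    "KineticsParams",
    "KineticsPrediction",
    "NMDAR_PARAMS",
    "GABAAR_PARAMS",
    "pair_partition",
    "population_kinetics",
    "nmdar_kinetics",
    "gabaar_kinetics",
    "fit_trajectory",
    "TrajectoryFit",
    "kinetics_trajectory_table",
]


@dataclass(frozen=True)
class SubunitMix:
    """Relative abundance of the mature and immature subunit of one receptor class.

    ``frac_mature`` is the GluN2A (NMDAR) or GABA_A alpha1 (GABA_A_R) share,
    ``frac_immature`` the GluN2B or alpha3 share.  Construct from raw
    normalized optical densities with :meth:`from_od`; fractions are
    normalized to sum to 1.
    """

    frac_mature: float
    frac_immature: float

    def __post_init__(self) -> None:
        if self.frac_mature < 0 or self.frac_immature < 0:
            raise ValueError("subunit fractions must be nonnegative")
        total = self.frac_mature + self.frac_immature
        if total <= 0:
            raise ValueError("at least one subunit fraction must be positive")
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"subunit fractions must sum to 1 (got {total!r}); "
                "use SubunitMix.from_od to normalize raw densities"
            )

    @classmethod
    def from_od(cls, od_mature: float, od_immature: float) -> "SubunitMix":
        """Build a mix from two nonnegative optical densities (any common scale)."""
        if od_mature < 0 or od_immature < 0:
            raise ValueError("optical densities must be nonnegative")
        total = od_mature + od_immature
        if total <= 0:
            raise ValueError("both optical densities are zero; mix undefined")
        return cls(od_mature / total, od_immature / total)


@dataclass(frozen=True)
class KineticsParams:
    """Decay-time constants (ms) for the three receptor stoichiometries."""

    tau_pair: float
    tau_mature_only: float
    tau_immature_only: float

    def __post_init__(self) -> None:
        if min(self.tau_pair, self.tau_mature_only, self.tau_immature_only) <= 0:
            raise ValueError("decay constants must be positive")
        if not (self.tau_mature_only <= self.tau_pair <= self.tau_immature_only):
            raise ValueError(
                "expected tau_mature_only <= tau_pair <= tau_immature_only"
            )


#: NMDAR decay constants: GluN2A/GluN2B pair, GluN2A-only, GluN2B-only.
NMDAR_PARAMS = KineticsParams(tau_pair=50.0, tau_mature_only=36.0, tau_immature_only=333.0)

#: GABA_A_R decay constants: alpha1/alpha3 pair, alpha1-only, alpha3-only.
GABAAR_PARAMS = KineticsParams(tau_pair=49.0, tau_mature_only=42.2, tau_immature_only=129.0)


@dataclass(frozen=True)
class KineticsPrediction:
    """Predicted population decay time and the receptor partition behind it."""

    value_ms: float
    pair_fraction: float
    leftover_mature: float
    leftover_immature: float


def pair_partition(mix: SubunitMix) -> tuple[float, float, float]:
    """Partition a subunit mix into mixed pairs and same-subunit pairs.

    Mixed (mature+immature) pairs are maximized, limited by the scarcer
    subunit; the surplus of the more abundant subunit is divided by 2 to
    count same-subunit receptors (two subunits per receptor).

    Returns ``(pairs, leftover_mature, leftover_immature)``.
    """
    pairs = min(mix.frac_mature, mix.frac_immature)
    surplus = abs(mix.frac_mature - mix.frac_immature) / 2.0
    if mix.frac_mature >= mix.frac_immature:
        return pairs, surplus, 0.0
    return pairs, 0.0, surplus


def population_kinetics(mix: SubunitMix, params: KineticsParams) -> KineticsPrediction:
    """Tau-weighted average decay time (ms) over the receptor population.

    ``(pairs*tau_pair + leftover_mature*tau_mature + leftover_immature*tau_immature)
    / (pairs + leftover_mature + leftover_immature)``.
    """
    pairs, left_m, left_i = pair_partition(mix)
    denom = pairs + left_m + left_i
    value = (
        pairs * params.tau_pair
        + left_m * params.tau_mature_only
        + left_i * params.tau_immature_only
    ) / denom
    return KineticsPrediction(
        value_ms=value,
        pair_fraction=pairs,
        leftover_mature=left_m,
        leftover_immature=left_i,
    )


def nmdar_kinetics(od_glun2a: float, od_glun2b: float) -> float:
    """Predicted NMDAR population decay time (ms) from GluN2A/GluN2B densities."""
    mix = SubunitMix.from_od(od_glun2a, od_glun2b)
    return population_kinetics(mix, NMDAR_PARAMS).value_ms


def gabaar_kinetics(od_alpha1: float, od_alpha3: float) -> float:
    """Predicted GABA_A_R population decay time (ms) from alpha1/alpha3 densities."""
    mix = SubunitMix.from_od(od_alpha1, od_alpha3)
    return population_kinetics(mix, GABAAR_PARAMS).value_ms


# ---------------------------------------------------------------------------
# trajectory curve fitting


@dataclass
class TrajectoryFit:
    """Result of a nonlinear least-squares fit to a kinetics/feature trajectory."""

    model: str
    params: dict[str, float]
    r_squared: float
    residuals: np.ndarray
    converged: bool

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        p = self.params
        if self.model == "exponential_decay":
            return p["y0"] + p["amplitude"] * np.exp(-x / p["tau"])
        return _logistic4(x, p["bottom"], p["top"], p["x_half"], p["hill"])


def _exp_decay(x, y0, amplitude, tau):
    return y0 + amplitude * np.exp(-x / tau)


def _logistic4(x, bottom, top, x_half, hill):
    return bottom + (top - bottom) / (1.0 + (x / x_half) ** hill)


def fit_trajectory(
    x,
    y,
    model: Literal["exponential_decay", "sigmoid"] = "exponential_decay",
    bounds: tuple | None = None,
) -> TrajectoryFit:
    """Fit an exponential decay ``y0 + A*exp(-x/tau)`` or a 4-parameter logistic.

    ``x`` must be strictly positive (ages in weeks or treatment durations).
    Non-convergence is reported via ``converged=False`` rather than raised, so
    callers can plot only significant fits.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(x <= 0):
        raise ValueError("x values must be strictly positive")
    names = (
        ("y0", "amplitude", "tau")
        if model == "exponential_decay"
        else ("bottom", "top", "x_half", "hill")
    )
    if len(x) < len(names) + 1:
        raise ValueError(f"need at least {len(names) + 1} points to fit {model}")

    if model == "exponential_decay":
        func = _exp_decay
        p0 = (float(y.min()), float(y.max() - y.min() or 1.0), float(np.median(x)))
        fit_bounds = bounds if bounds is not None else ((-np.inf, -np.inf, 1e-9), np.inf)
    elif model == "sigmoid":
        func = _logistic4
        p0 = (float(y.min()), float(y.max()), float(np.median(x)), 1.0)
        fit_bounds = bounds if bounds is not None else (
            (-np.inf, -np.inf, 1e-9, -50.0),
            (np.inf, np.inf, np.inf, 50.0),
        )
    else:
        raise ValueError(f"unknown trajectory model {model!r}")

    try:
        popt, _ = curve_fit(func, x, y, p0=p0, bounds=fit_bounds, maxfev=20000)
        converged = True
    except (RuntimeError, ValueError):
        popt = np.full(len(names), np.nan)
        converged = False

    if converged:
        resid = y - func(x, *popt)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    else:
        resid = np.full_like(y, np.nan)
        r2 = float("nan")
    return TrajectoryFit(
        model=model,
        params=dict(zip(names, (float(v) for v in popt))),
        r_squared=r2,
        residuals=resid,
        converged=converged,
    )


def kinetics_trajectory_table(group_subunit_means) -> "pandas.DataFrame":  # noqa: F821
    """Paired (GABA_A_R ms, NMDAR ms) predictions per group for XY trajectory plots.

    ``group_subunit_means`` is a DataFrame indexed by group label with columns
    ``GluN2A``, ``GluN2B``, ``GABAAa1``, ``GABAAa3`` holding group-mean
    normalized densities.
    """
    import pandas as pd

    rows = []
    for label, row in group_subunit_means.iterrows():
        rows.append(
            {
                "group": label,
                "gabaar_ms": gabaar_kinetics(row["GABAAa1"], row["GABAAa3"]),
                "nmdar_ms": nmdar_kinetics(row["GluN2A"], row["GluN2B"]),
            }
        )
    return pd.DataFrame(rows).set_index("group")
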