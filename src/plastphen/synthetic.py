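"""Synthetic Western-blot-style expression data with planted condition effects.

The generator emulates the structure of a visual-cortex rearing study: tissue
pieces sampled from three V1 regions (central C, peripheral P, monocular M)
of animals reared under one of six conditions — normal binocular vision to
5 weeks, monocular deprivation (MD), reverse occlusion (RO), binocular
deprivation (BD), and short/long-term binocular vision treatment (ST-BV,
LT-BV) — each piece assayed in duplicate Western-blot runs for 7 synaptic
proteins (GluA2, GluN1, GluN2A, GluN2B, GABA_A alpha1, GABA_A alpha3,
synapsin).  Values are gel-control-normalized optical densities near 1.

Per condition, the 7 proteins are drawn from a truncated multivariate
Gaussian with a configurable mean vector, correlation matrix and per-protein
noise SD.  Missingness removes an entire (piece, protein) cell — both
duplicate runs — mirroring how single-cell dropouts occur in blot data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PROTEINS",
    "GLUT_PROTEINS",
    "GABA_PROTEINS",
    "REGIONS",
    "LONG_COLUMNS",
    "StudyDesign",
    "ConditionSpec",
    "EffectSpec",
    "table2_design",
    "table2_counts",
    "development_design",
    "default_effects",
    "development_effects",
    "generate_dataset",
    "write_long_csv",
    "design_from_config",
    "effects_from_config",
]

#: Canonical protein order (matrix column order throughout the package).
PROTEINS = ("GluA2", "GluN1", "GluN2A", "GluN2B", "GABAAa1", "GABAAa3", "Synapsin")
GLUT_PROTEINS = ("GluA2", "GluN1", "GluN2A", "GluN2B")
GABA_PROTEINS = ("GABAAa1", "GABAAa3")
REGIONS = ("C", "P", "M")

LONG_COLUMNS = [
    "animal_id",
    "condition",
    "age_wks",
    "region",
    "piece_id",
    "run",
    "protein",
    "od",
]


@dataclass(frozen=True)
class ConditionSpec:
    """One rearing condition: age at sacrifice and piece counts per V1 region."""

    age_wks: float
    pieces: Mapping[str, int]  # region -> piece count
    n_animals: int = 1

    def __post_init__(self) -> None:
        if self.age_wks <= 0:
            raise ValueError("age_wks must be positive")
        bad = set(self.pieces) - set(REGIONS)
        if bad:
            raise ValueError(f"unknown regions {sorted(bad)}; expected subset of {REGIONS}")
        if any(n < 0 for n in self.pieces.values()):
            raise ValueError("piece counts must be nonnegative")
        if sum(self.pieces.values()) < 1:
            raise ValueError("condition needs at least one piece in one region")


@dataclass(frozen=True)
class StudyDesign:
    """Sampling layout: conditions x regions x pieces x duplicate runs."""

    conditions: Mapping[str, ConditionSpec]
    runs_per_piece: int = 2
    proteins: tuple[str, ...] = PROTEINS

    def __post_init__(self) -> None:
        if self.runs_per_piece < 1:
            raise ValueError("runs_per_piece must be positive")
        if len(self.proteins) != 7 or len(set(self.proteins)) != 7:
            raise ValueError("design requires exactly 7 unique protein names")
        if not self.conditions:
            raise ValueError("design needs at least one condition")

    @property
    def n_pieces(self) -> int:
        return sum(sum(c.pieces.values()) for c in self.conditions.values())

    @property
    def n_records(self) -> int:
        return self.n_pieces * self.runs_per_piece


@dataclass
class EffectSpec:
    """Per-condition generative model: mean OD, correlation, noise, missingness."""

    mean_vector: Mapping[str, float]
    correlation: np.ndarray
    noise_sd: Mapping[str, float]
    missing_rate: float = 0.0

    def validate(self, proteins: tuple[str, ...] = PROTEINS, name: str = "effect") -> None:
        missing = set(proteins) - set(self.mean_vector)
        if missing:
            raise ValueError(f"{name}: mean_vector lacks proteins {sorted(missing)}")
        if any(self.mean_vector[p] <= 0 for p in proteins):
            raise ValueError(f"{name}: mean_vector entries must be positive")
        if any(self.noise_sd.get(p, 0.0) < 0 for p in proteins):
            raise ValueError(f"{name}: noise_sd must be nonnegative")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError(f"{name}: missing_rate must be in [0, 1]")
        r = np.asarray(self.correlation, dtype=float)
        if r.shape != (7, 7):
            raise ValueError(f"{name}: correlation must be 7x7, got {r.shape}")
        if not np.allclose(r, r.T, atol=1e-12):
            raise ValueError(f"{name}: correlation matrix is not symmetric")
        if not np.allclose(np.diag(r), 1.0, atol=1e-12):
            raise ValueError(f"{name}: correlation diagonal must be 1")
        eigvals = np.linalg.eigvalsh(r)
        if eigvals.min() < -1e-10:
            raise ValueError(
                f"{name}: correlation matrix is not positive semidefinite "
                f"(min eigenvalue {eigvals.min():.3e})"
            )


# ---------------------------------------------------------------------------
# bundled study layout (tissue pieces and measurement counts per condition)

#: Piece counts per condition and region, and animals per condition.
_TABLE2_PIECES: dict[str, tuple[float, int, dict[str, int]]] = {
    # condition: (age_wks, n_animals, {region: pieces})
    "5wk_normal": (5.0, 1, {"C": 2, "P": 8, "M": 2}),
    "MD": (5.0, 2, {"C": 3, "P": 9, "M": 3}),
    "RO": (7.6, 1, {"C": 2, "P": 8, "M": 2}),
    "BD": (5.6, 1, {"C": 3, "P": 9, "M": 2}),
    "ST-BV": (5.05, 2, {"C": 4, "P": 16, "M": 4}),
    "LT-BV": (5.35, 3, {"C": 6, "P": 24, "M": 6}),
}

#: Realized Western-blot measurement counts (after duplicate runs) per
#: condition, region and protein.  Column order: GluN1, GluN2A, GluN2B,
#: GABAAa1, GABAAa3, GluA2, Synapsin.  A count below 2x pieces reflects a
#: missing cell in the source study.
_TABLE2_MEASUREMENTS: dict[tuple[str, str], tuple[int, ...]] = {
    ("5wk_normal", "C"): (4, 4, 4, 4, 4, 4, 4),
    ("5wk_normal", "P"): (16, 16, 16, 15, 16, 16, 16),
    ("5wk_normal", "M"): (4, 4, 4, 4, 4, 4, 4),
    ("MD", "C"): (6, 6, 6, 6, 6, 6, 4),
    ("MD", "P"): (18, 18, 18, 18, 18, 18, 12),
    ("MD", "M"): (5, 5, 5, 5, 5, 5, 4),
    ("RO", "C"): (4, 4, 4, 4, 4, 4, 4),
    ("RO", "P"): (19, 19, 19, 19, 19, 14, 14),
    ("RO", "M"): (3, 3, 3, 3, 3, 2, 2),
    ("BD", "C"): (6, 6, 5, 6, 5, 6, 5),
    ("BD", "P"): (18, 18, 17, 16, 18, 18, 17),
    ("BD", "M"): (4, 4, 3, 4, 4, 4, 3),
    ("ST-BV", "C"): (8, 8, 8, 8, 8, 8, 8),
    ("ST-BV", "P"): (32, 32, 32, 32, 32, 32, 32),
    ("ST-BV", "M"): (8, 8, 8, 8, 8, 8, 7),
    ("LT-BV", "C"): (12, 10, 12, 11, 12, 12, 10),
    ("LT-BV", "P"): (43, 40, 43, 43, 42, 43, 40),
    ("LT-BV", "M"): (12, 12, 12, 12, 12, 12, 12),
}
_TABLE2_MEASUREMENT_PROTEINS = (
    "GluN1",
    "GluN2A",
    "GluN2B",
    "GABAAa1",
    "GABAAa3",
    "GluA2",
    "Synapsin",
)


def table2_design() -> StudyDesign:
    """The bundled study layout: 113 tissue pieces, duplicate runs (226 records)."""
    conditions = {
        name: ConditionSpec(age_wks=age, pieces=pieces, n_animals=n_animals)
        for name, (age, n_animals, pieces) in _TABLE2_PIECES.items()
    }
    return StudyDesign(conditions=conditions, runs_per_piece=2)


def table2_counts() -> pd.DataFrame:
    """Measurement counts per condition x region x protein (long study layout).

    Column sums give total Western-blot measurements per protein across the
    whole study (e.g. 222 for GluN1).
    """
    rows = []
    for (condition, region), counts in _TABLE2_MEASUREMENTS.items():
        row = {"condition": condition, "region": region}
        row.update(dict(zip(_TABLE2_MEASUREMENT_PROTEINS, counts)))
        rows.append(row)
    return pd.DataFrame(rows)


def development_design(
    ages_wks: tuple[float, ...] = (2, 3, 4, 5, 6, 8, 12, 16, 32),
    pieces_per_region: int = 2,
) -> StudyDesign:
    """Normal-development layout: one condition per age, for trajectory demos."""
    conditions = {
        f"normal_{_fmt_age(a)}wk": ConditionSpec(
            age_wks=float(a), pieces={"C": pieces_per_region, "P": pieces_per_region, "M": pieces_per_region}
        )
        for a in ages_wks
    }
    return StudyDesign(conditions=conditions, runs_per_piece=2)


def _fmt_age(a: float) -> str:
    return str(int(a)) if float(a).is_integer() else str(a)


# ---------------------------------------------------------------------------
# default planted effects

_GLUT_IDX = [PROTEINS.index(p) for p in GLUT_PROTEINS]
_GABA_IDX = [PROTEINS.index(p) for p in GABA_PROTEINS]
_SYN_IDX = PROTEINS.index("Synapsin")


def _block_correlation(
    within_glut: float,
    within_gaba: float,
    glut_gaba: float,
    syn_glut: float,
    syn_gaba: float,
) -> np.ndarray:
    """Correlation matrix from within/between-class blocks; validated PSD."""
    r = np.eye(7)
    for i in _GLUT_IDX:
        for j in _GLUT_IDX:
            if i != j:
                r[i, j] = within_glut
    for i in _GABA_IDX:
        for j in _GABA_IDX:
            if i != j:
                r[i, j] = within_gaba
    for i in _GLUT_IDX:
        for j in _GABA_IDX:
            r[i, j] = r[j, i] = glut_gaba
    for i in _GLUT_IDX:
        r[i, _SYN_IDX] = r[_SYN_IDX, i] = syn_glut
    for j in _GABA_IDX:
        r[j, _SYN_IDX] = r[_SYN_IDX, j] = syn_gaba
    return r


def _means(**overrides: float) -> dict[str, float]:
    m = {p: 1.0 for p in PROTEINS}
    m.update(overrides)
    return m


#: Default per-protein noise SD on the normalized OD scale.
DEFAULT_NOISE_SD = 0.10
#: Default probability that an entire (piece, protein) cell is missing.
DEFAULT_MISSING_RATE = 0.005


def default_effects(
    noise_sd: float = DEFAULT_NOISE_SD,
    missing_rate: float = DEFAULT_MISSING_RATE,
) -> dict[str, EffectSpec]:
    """Planted condition effects mirroring the study's qualitative findings.

    The reference condition (5 wk normal) has all means at 1 by construction
    of the normalization.  MD delays the GluN2A shift (low 2A, high 2B),
    prematurely raises GABA_A alpha1 and decouples glutamatergic from
    GABAergic correlations; RO over-expresses GluA2 and GluN2A; BD is
    dominated by GABA_A alpha1 with less GluN2A; ST-BV is an MD-like state
    beginning to recover; LT-BV has near-normal means apart from a loss of
    GABA_A receptor expression.
    """
    sd = {p: noise_sd for p in PROTEINS}
    mk = lambda means, corr: EffectSpec(  # noqa: E731
        mean_vector=means, correlation=corr, noise_sd=dict(sd), missing_rate=missing_rate
    )
    effects = {
        "5wk_normal": mk(_means(), _block_correlation(0.60, 0.60, 0.45, 0.50, 0.50)),
        "MD": mk(
            _means(GluN2A=0.55, GluN2B=1.25, GABAAa1=1.35, GluN1=0.90, Synapsin=0.90),
            _block_correlation(0.50, 0.50, -0.10, 0.30, 0.35),
        ),
        "RO": mk(
            _means(GluA2=1.60, GluN2A=1.45, GluN2B=0.70, GABAAa3=0.80, Synapsin=0.90),
            _block_correlation(0.50, 0.50, 0.15, 0.30, 0.30),
        ),
        "BD": mk(
            _means(GluN2A=0.80, GluN2B=1.10, GABAAa1=1.70, GABAAa3=1.10, Synapsin=0.80),
            _block_correlation(0.50, 0.50, 0.40, -0.25, -0.25),
        ),
        "ST-BV": mk(
            _means(GluA2=0.85, GluN1=1.05, GluN2A=0.85, GluN2B=1.15, GABAAa1=1.10, Synapsin=1.10),
            _block_correlation(0.50, 0.50, 0.25, 0.40, 0.40),
        ),
        "LT-BV": mk(
            _means(GluN2B=1.10, GABAAa1=0.60, GABAAa3=0.55),
            _block_correlation(0.55, 0.55, 0.35, 0.45, 0.45),
        ),
    }
    for name, eff in effects.items():
        eff.validate(name=name)
    return effects


def development_effects(
    ages_wks: tuple[float, ...] = (2, 3, 4, 5, 6, 8, 12, 16, 32),
    noise_sd: float = DEFAULT_NOISE_SD,
    missing_rate: float = 0.0,
) -> dict[str, EffectSpec]:
    """Maturational mean trajectories for normal development.

    GluN2A and GABA_A alpha1 rise with age while GluN2B and alpha3 fall
    (saturating exponentials anchored so every protein mean is 1 at 5 wks),
    so the implied receptor kinetics speed up through the critical period.
    """
    corr = _block_correlation(0.60, 0.60, 0.45, 0.50, 0.50)
    sd = {p: noise_sd for p in PROTEINS}

    def rise(age, lo, hi, tau=5.0):
        raw = hi - (hi - lo) * np.exp(-age / tau)
        at5 = hi - (hi - lo) * np.exp(-5.0 / tau)
        return float(raw / at5)

    def fall(age, hi, lo, tau=5.0):
        raw = lo + (hi - lo) * np.exp(-age / tau)
        at5 = lo + (hi - lo) * np.exp(-5.0 / tau)
        return float(raw / at5)

    effects = {}
    for a in ages_wks:
        means = _means(
            GluN2A=rise(a, 0.30, 1.35),
            GluN2B=fall(a, 1.60, 0.70),
            GABAAa1=rise(a, 0.35, 1.30),
            GABAAa3=fall(a, 1.50, 0.75),
            GluA2=rise(a, 0.70, 1.15),
        )
        effects[f"normal_{_fmt_age(a)}wk"] = EffectSpec(
            mean_vector=means, correlation=corr, noise_sd=dict(sd), missing_rate=missing_rate
        )
    for name, eff in effects.items():
        eff.validate(name=name)
    return effects


# ---------------------------------------------------------------------------
# generation


def generate_dataset(
    design: StudyDesign,
    effects: Mapping[str, EffectSpec],
    seed: int,
) -> pd.DataFrame:
    """Draw a long-format dataset: one row per (piece, run, protein).

    Every (piece, run) record is an independent draw from the condition's
    truncated multivariate Gaussian.  Missingness removes the (piece,
    protein) cell across all runs.  Deterministic for a fixed seed; each
    condition uses an independent substream derived from the master seed, so
    adding a condition does not perturb the others.
    """
    missing_conditions = set(design.conditions) - set(effects)
    if missing_conditions:
        raise ValueError(
            f"no EffectSpec for conditions {sorted(missing_conditions)}"
        )
    for name in design.conditions:
        effects[name].validate(proteins=design.proteins, name=name)

    master = np.random.SeedSequence(seed)
    substreams = master.spawn(len(design.conditions))
    records = []
    for (cond_name, cond), ss in zip(design.conditions.items(), substreams):
        rng = np.random.default_rng(ss)
        eff = effects[cond_name]
        mean = np.array([eff.mean_vector[p] for p in design.proteins])
        sd = np.array([eff.noise_sd.get(p, 0.0) for p in design.proteins])
        cov = np.asarray(eff.correlation) * np.outer(sd, sd)
        # eigen factor handles PSD (incl. zero-noise) covariances
        w, v = np.linalg.eigh(cov)
        factor = v * np.sqrt(np.clip(w, 0.0, None))

        piece_counter = 0
        for region in REGIONS:
            n_pieces = cond.pieces.get(region, 0)
            for k in range(n_pieces):
                animal = piece_counter % max(cond.n_animals, 1)
                piece_id = f"{cond_name}_{region}{k + 1}"
                # whole-cell missingness: both runs of a protein drop together
                missing = rng.random(len(design.proteins)) < eff.missing_rate
                for run in range(1, design.runs_per_piece + 1):
                    values = mean + factor @ rng.standard_normal(len(mean))
                    values = np.clip(values, 0.0, None)  # OD cannot be negative
                    for j, protein in enumerate(design.proteins):
                        records.append(
                            (
                                f"{cond_name}_a{animal + 1}",
                                cond_name,
                                cond.age_wks,
                                region,
                                piece_id,
                                run,
                                protein,
                                np.nan if missing[j] else values[j],
                            )
                        )
                piece_counter += 1
    return pd.DataFrame.from_records(records, columns=LONG_COLUMNS)


def write_long_csv(dataset: pd.DataFrame, path) -> None:
    """Write the long-format dataset to CSV (schema of LONG_COLUMNS)."""
    dataset.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# config-file round trip


def design_from_config(config: Mapping | str) -> StudyDesign:
    """Build a StudyDesign from a dict or a YAML/JSON file path.

    Expected keys: ``conditions`` (name -> {age_wks, pieces, n_animals}),
    optional ``runs_per_piece`` and ``proteins``.
    """
    cfg = _load_config(config)
    conditions = {
        name: ConditionSpec(
            age_wks=float(c["age_wks"]),
            pieces={k: int(v) for k, v in c["pieces"].items()},
            n_animals=int(c.get("n_animals", 1)),
        )
        for name, c in cfg["conditions"].items()
    }
    return StudyDesign(
        conditions=conditions,
        runs_per_piece=int(cfg.get("runs_per_piece", 2)),
        proteins=tuple(cfg.get("proteins", PROTEINS)),
    )


def effects_from_config(config: Mapping | str) -> dict[str, EffectSpec]:
    """Build per-condition EffectSpecs from a dict or a YAML/JSON file path."""
    cfg = _load_config(config)
    effects = {}
    for name, e in cfg["effects"].items():
        effects[name] = EffectSpec(
            mean_vector={k: float(v) for k, v in e["mean_vector"].items()},
            correlation=np.asarray(e["correlation"], dtype=float),
            noise_sd={k: float(v) for k, v in e["noise_sd"].items()},
            missing_rate=float(e.get("missing_rate", 0.0)),
        )
        effects[name].validate(name=name)
    return effects


def _load_config(config: Mapping | str) -> Mapping:
    if isinstance(config, Mapping):
        return config
    text = open(config).read()
    if str(config).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)
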