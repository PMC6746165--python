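"""Normalization, replicate averaging and assembly of the expression matrix.

Raw band densities are first expressed relative to the per-gel control
sample (done upstream or via :func:`normalize_to_gel_control`), then each
protein is scaled so the reference condition (5 wk normal) has mean 1.
Duplicate runs are averaged to one value per tissue piece, and pieces with
any missing protein are dropped before multivariate analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import LONG_COLUMNS, PROTEINS

__all__ = [
    "ExpressionMatrix",
    "normalize_to_gel_control",
    "normalize_to_reference",
    "average_runs",
    "assemble_matrix",
    "read_long_csv",
]

_META_COLS = ["condition", "age_wks", "region", "animal_id"]


@dataclass
class ExpressionMatrix:
    """Complete samples x proteins matrix with aligned per-row metadata.

    ``values`` has one row per tissue piece (indexed by piece_id) and one
    column per protein; ``metadata`` is row-aligned and carries condition,
    age, region and animal labels.  ``n_dropped`` counts pieces removed for
    missing cells.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("ExpressionMatrix must not contain missing cells")
        if len(self.values) != len(self.metadata):
            raise ValueError("values and metadata row counts differ")
        if self.values.shape[1] != 7:
            raise ValueError(f"expected 7 protein columns, got {self.values.shape[1]}")

    @property
    def proteins(self) -> tuple[str, ...]:
        return tuple(self.values.columns)

    @property
    def n_samples(self) -> int:
        return len(self.values)

    @property
    def n_observations(self) -> int:
        """Total measurements entering the analysis: rows x 7 proteins."""
        return self.values.size

    def rows_for_condition(self, condition: str) -> pd.DataFrame:
        """Values for one condition pooled across the three V1 regions."""
        mask = (self.metadata["condition"] == condition).to_numpy()
        return self.values.iloc[mask]

    def write(self, values_path, metadata_path) -> None:
        self.values.to_csv(values_path)
        sidecar = {
            "n_samples": self.n_samples,
            "n_dropped": self.n_dropped,
            "proteins": list(self.proteins),
            "rows": self.metadata.reset_index().to_dict(orient="records"),
        }
        with open(metadata_path, "w") as fh:
            json.dump(sidecar, fh, indent=1, default=str)


def normalize_to_gel_control(band_density: float, control_density: float) -> float:
    """Express a band density relative to the per-gel control sample."""
    if band_density < 0:
        raise ValueError("band density must be nonnegative")
    if control_density <= 0:
        raise ValueError(
            f"control band density must be positive (got {control_density}); degenerate gel"
        )
    return band_density / control_density


def normalize_to_reference(dataset: pd.DataFrame, reference_condition: str) -> pd.DataFrame:
    """Scale each protein so the reference condition's mean is exactly 1.

    Reference means are computed per protein over all non-missing values of
    the reference condition, pooled across regions and runs.  Idempotent:
    applying twice equals applying once.
    """
    ref = dataset[dataset["condition"] == reference_condition]
    if ref.empty:
        raise ValueError(f"reference condition {reference_condition!r} not in dataset")
    ref_means = ref.groupby("protein")["od"].mean()
    proteins = dataset["protein"].unique()
    lacking = [p for p in proteins if p not in ref_means.index or not np.isfinite(ref_means[p])]
    if lacking:
        raise ValueError(
            f"reference condition has no usable values for proteins {sorted(lacking)}"
        )
    out = dataset.copy()
    out["od"] = out["od"] / out["protein"].map(ref_means)
    return out


def average_runs(dataset: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicate runs to one value per (piece, protein).

    The arithmetic mean of the non-missing runs; a cell stays absent only if
    every run is absent.  The returned frame keeps the long schema with
    ``run`` fixed at 0.
    """
    keys = ["animal_id", "condition", "age_wks", "region", "piece_id", "protein"]
    grouped = dataset.groupby(keys, sort=False, dropna=False)["od"].mean().reset_index()
    grouped["run"] = 0
    return grouped[LONG_COLUMNS]


def assemble_matrix(dataset: pd.DataFrame, drop_incomplete: bool = True) -> ExpressionMatrix:
    """Pivot the piece-level dataset to a complete samples x proteins matrix.

    With ``drop_incomplete`` (the default), every piece with at least one
    absent protein cell is removed; the count of dropped rows is reported on
    the result.  Raises if no complete rows remain.
    """
    proteins = [p for p in PROTEINS if p in set(dataset["protein"])]
    if len(proteins) != 7:
        proteins = list(pd.unique(dataset["protein"]))
    wide = dataset.pivot_table(
        index="piece_id", columns="protein", values="od", aggfunc="mean", sort=False
    ).reindex(columns=proteins)
    meta = (
        dataset[["piece_id"] + _META_COLS]
        .drop_duplicates("piece_id")
        .set_index("piece_id")
        .reindex(wide.index)
    )
    incomplete = wide.isna().any(axis=1)
    n_dropped = int(incomplete.sum())
    if drop_incomplete:
        wide = wide.loc[~incomplete]
        meta = meta.loc[~incomplete]
    elif n_dropped:
        raise ValueError("matrix has missing cells and drop_incomplete is off")
    if wide.empty:
        raise ValueError("no complete rows: cannot assemble expression matrix")
    return ExpressionMatrix(values=wide, metadata=meta, n_dropped=n_dropped)


def read_long_csv(path) -> pd.DataFrame:
    """Read a long-format expression CSV (columns of LONG_COLUMNS)."""
    df = pd.read_csv(path)
    missing = set(LONG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"long-format CSV lacks columns {sorted(missing)}")
    return df[LONG_COLUMNS]
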