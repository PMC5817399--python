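"""Jaw functional characters: computation, species averaging, missingness.

Five dimensionless lower-jaw characters, each a ratio of linear (or, for
average depth, areal) measurements and each tied to feeding mechanics:

1. anterior mechanical advantage  = inlever / outlever to the anterior-most teeth
2. posterior mechanical advantage = inlever / outlever to the posterior-most teeth
3. maximum relative jaw depth     = max depth / jaw length
4. average relative jaw depth     = jaw area (without teeth) / jaw length²
5. relative tooth-row length      = tooth-row length / jaw length

Fossil preservation leaves holes: a character is missing whenever any of its
inputs is missing, species means ignore missing entries per character, and
the primary analysis path filters to complete cases (imputation is
deliberately not offered — on this kind of data it manufactures degenerate
morphospace axes rather than biological signal).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .io import TRAIT_COLUMNS

logger = logging.getLogger(__name__)

__all__ = [
    "JawMeasurements",
    "MEASUREMENT_COLUMNS",
    "compute_characters",
    "characters_from_measurements",
    "average_by_species",
    "missingness_rate",
    "complete_case_filter",
]

MEASUREMENT_COLUMNS = (
    "inlever",
    "outlever_anterior",
    "outlever_posterior",
    "max_depth",
    "jaw_length",
    "jaw_area",
    "tooth_row",
)

# character -> the raw measurements it needs
_RECIPES: dict[str, tuple[str, ...]] = {
    "char1": ("inlever", "outlever_anterior"),
    "char2": ("inlever", "outlever_posterior"),
    "char3": ("max_depth", "jaw_length"),
    "char4": ("jaw_area", "jaw_length"),
    "char5": ("tooth_row", "jaw_length"),
}


@dataclass
class JawMeasurements:
    """Raw lower-jaw measurements for one specimen; None means not preserved."""

    specimen_id: str
    inlever: float | None = None
    outlever_anterior: float | None = None
    outlever_posterior: float | None = None
    max_depth: float | None = None
    jaw_length: float | None = None
    jaw_area: float | None = None
    tooth_row: float | None = None

    def __post_init__(self) -> None:
        for name in MEASUREMENT_COLUMNS:
            value = getattr(self, name)
            if value is not None and isinstance(value, float) and math.isnan(value):
                setattr(self, name, None)
                value = None
            if value is not None and value <= 0:
                raise ValueError(
                    f"{self.specimen_id!r}: measurement {name} must be positive, "
                    f"got {value}"
                )
        if (
            self.jaw_length is not None
            and self.max_depth is not None
            and self.max_depth > self.jaw_length
        ):
            logger.warning(
                "%s: max_depth exceeds jaw_length (unusual proportions)",
                self.specimen_id,
            )


def compute_characters(measurements: JawMeasurements) -> dict[str, float]:
    """Five functional characters; NaN where any ingredient is missing."""
    m = measurements
    out: dict[str, float] = {}
    for char, needs in _RECIPES.items():
        if any(getattr(m, field) is None for field in needs):
            out[char] = float("nan")
            continue
        if char == "char1":
            out[char] = m.inlever / m.outlever_anterior
        elif char == "char2":
            out[char] = m.inlever / m.outlever_posterior
        elif char == "char3":
            out[char] = m.max_depth / m.jaw_length
        elif char == "char4":
            out[char] = m.jaw_area / m.jaw_length**2
        else:
            out[char] = m.tooth_row / m.jaw_length
    return out


def characters_from_measurements(measurements: pd.DataFrame) -> pd.DataFrame:
    """Vectorized character table from a measurement table.

    Expects columns ``inlever..tooth_row`` indexed by specimen_id (empty
    cells = NaN = not preserved); returns ``char1..char5``.
    """
    df = measurements
    missing_cols = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"measurement table lacks column(s) {missing_cols}")
    vals = df[list(MEASUREMENT_COLUMNS)].astype(float)
    if (vals <= 0).any().any():
        bad = vals.index[(vals <= 0).any(axis=1)].tolist()
        raise ValueError(f"non-positive measurements for specimens {bad[:5]}")
    out = pd.DataFrame(index=df.index)
    out["char1"] = vals["inlever"] / vals["outlever_anterior"]
    out["char2"] = vals["inlever"] / vals["outlever_posterior"]
    out["char3"] = vals["max_depth"] / vals["jaw_length"]
    out["char4"] = vals["jaw_area"] / vals["jaw_length"] ** 2
    out["char5"] = vals["tooth_row"] / vals["jaw_length"]
    return out


def average_by_species(
    traits: pd.DataFrame,
    species_map: Mapping[str, str],
) -> pd.DataFrame:
    """Average characters across conspecific specimens.

    Per character the mean is over the specimens where it is present
    (pairwise-available mean), so a character is missing for a species only
    when no specimen of that species preserves it.  The result is indexed by
    species name, in order of first appearance.
    """
    missing = [sid for sid in traits.index if sid not in species_map]
    if missing:
        raise KeyError(f"specimens without a species assignment: {missing[:5]}")
    species = pd.Series([species_map[sid] for sid in traits.index], index=traits.index)
    grouped = traits.groupby(species, sort=False).mean()  # mean skips NaN
    return grouped


def missingness_rate(traits: pd.DataFrame) -> float:
    """Fraction of missing cells over rows × five characters."""
    if traits.empty:
        raise ValueError("empty trait table")
    block = traits[list(TRAIT_COLUMNS)]
    return float(block.isna().to_numpy().mean())


def complete_case_filter(traits: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Keep rows with all five characters present, preserving row order."""
    block = traits[list(TRAIT_COLUMNS)]
    keep = block.notna().all(axis=1)
    subset = traits.loc[keep]
    return subset, int(keep.sum())
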