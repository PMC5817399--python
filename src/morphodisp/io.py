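"""Readers and writers for the file formats the pipeline touches.

Landmark data arrive as TPS files (the plain-text format of the tpsDig
digitizing lineage), semilandmark sliding topology as a small ``before,
slider,after`` CSV, specimen metadata and jaw traits as CSV tables, and
disparity series leave as CSV.  All indices are 1-based on disk and 0-based
in memory.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LandmarkScheme",
    "LandmarkConfiguration",
    "SpecimenRecord",
    "TpsParseError",
    "SchemaError",
    "INFRACLASSES",
    "ENVIRONMENTS",
    "TRAIT_COLUMNS",
    "read_tps",
    "write_tps",
    "read_sliders",
    "write_sliders",
    "read_metadata",
    "write_metadata",
    "read_trait_table",
    "write_trait_table",
    "write_series",
    "read_series",
    "check_join",
]

INFRACLASSES = ("Chondrostei", "Holostei", "Teleostei", "Incertae sedis")
ENVIRONMENTS = ("marine", "freshwater")
TRAIT_COLUMNS = ("char1", "char2", "char3", "char4", "char5")

METADATA_COLUMNS = (
    "specimen_id",
    "species",
    "genus",
    "family",
    "infraclass",
    "environment",
    "stage",
    "lagerstatten_only",
)


class TpsParseError(ValueError):
    """Malformed TPS input; message carries record index / line number."""


class SchemaError(ValueError):
    """A CSV table does not match the expected schema."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LandmarkScheme:
    """Identity of fixed landmarks and sliding semilandmarks.

    Parameters
    ----------
    n_landmarks:
        Total number of points per configuration.
    slider_triples:
        0-based ``(before, slider, after)`` triples; ``slider`` is displaced
        along the chord from ``before`` to ``after`` during sliding.
    curves:
        Optional partition of the semilandmarks into named curves, purely
        descriptive (the sliding solver only needs the triples).
    """

    n_landmarks: int
    slider_triples: tuple[tuple[int, int, int], ...] = ()
    curves: dict[str, tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        k = self.n_landmarks
        if k < 3:
            raise ValueError("a landmark scheme needs at least 3 points")
        seen: set[int] = set()
        for before, slider, after in self.slider_triples:
            for idx in (before, slider, after):
                if not 0 <= idx < k:
                    raise ValueError(
                        f"slider triple ({before},{slider},{after}) has index "
                        f"{idx} outside 0..{k - 1}"
                    )
            if slider in (before, after):
                raise ValueError(
                    f"slider {slider} cannot be its own tangent neighbor"
                )
            if slider in seen:
                raise ValueError(f"landmark {slider} appears twice as a slider")
            seen.add(slider)
        if self.curves:
            covered = [i for pts in self.curves.values() for i in pts]
            if sorted(covered) != sorted(seen):
                raise ValueError("curves must partition exactly the slider set")

    @property
    def slider_indices(self) -> tuple[int, ...]:
        return tuple(t[1] for t in self.slider_triples)

    @property
    def fixed_indices(self) -> tuple[int, ...]:
        sliders = set(self.slider_indices)
        return tuple(i for i in range(self.n_landmarks) if i not in sliders)


@dataclass
class LandmarkConfiguration:
    """One specimen's digitized 2-D landmarks (image units × optional scale)."""

    specimen_id: str
    coords: np.ndarray  # (k, 2) float
    scale: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be a (k, 2) array")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates in {self.specimen_id!r}")
        if self.scale is not None and self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[0]


@dataclass(frozen=True)
class SpecimenRecord:
    """Metadata row joining a specimen to taxonomy, environment and stage."""

    specimen_id: str
    species: str
    genus: str
    family: str
    infraclass: str
    environment: str
    stage: str
    lagerstatten_only: bool

    def __post_init__(self) -> None:
        if self.infraclass not in INFRACLASSES:
            raise ValueError(
                f"unknown infraclass {self.infraclass!r} "
                f"(expected one of {INFRACLASSES})"
            )
        if self.environment not in ENVIRONMENTS:
            raise ValueError(
                f"unknown environment {self.environment!r} "
                f"(expected one of {ENVIRONMENTS})"
            )


# ---------------------------------------------------------------------------
# TPS landmark files
# ---------------------------------------------------------------------------

_KEY_RE = re.compile(r"^([A-Za-z]+)\s*=\s*(.*)$")


def read_tps(path: str | Path) -> list[LandmarkConfiguration]:
    """Parse a TPS file into landmark configurations, preserving file order.

    Supported keys: ``LM=`` (starts a record), ``ID=``, ``IMAGE=``,
    ``SCALE=``, ``COMMENT=``.  ``CURVES=``/``POINTS=`` blocks are ignored;
    sliding topology comes from the sliders file.  If ``SCALE=`` is present
    the coordinates are multiplied by it; the specimen id is ``ID=`` or,
    failing that, the ``IMAGE=`` basename, or a positional fallback.
    """
    lines = Path(path).read_text().splitlines()
    configs: list[LandmarkConfiguration] = []
    i = 0
    n_record = 0
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        m = _KEY_RE.match(line)
        if not m or m.group(1).upper() != "LM":
            raise TpsParseError(
                f"line {i}: expected LM= to open record {n_record + 1}, "
                f"got {line!r}"
            )
        try:
            n_lm = int(m.group(2))
        except ValueError as exc:
            raise TpsParseError(f"line {i}: bad LM count {m.group(2)!r}") from exc
        coords = np.empty((n_lm, 2), dtype=float)
        for j in range(n_lm):
            if i >= len(lines):
                raise TpsParseError(
                    f"record {n_record + 1}: LM={n_lm} but file ends after "
                    f"{j} coordinate lines"
                )
            parts = lines[i].split()
            if len(parts) != 2 or _KEY_RE.match(lines[i].strip()):
                raise TpsParseError(
                    f"record {n_record + 1}: LM={n_lm} but only {j} "
                    f"coordinate lines before line {i + 1}"
                )
            try:
                coords[j] = [float(parts[0]), float(parts[1])]
            except ValueError as exc:
                raise TpsParseError(
                    f"line {i + 1}: non-numeric coordinate {lines[i]!r}"
                ) from exc
            i += 1
        specimen_id: str | None = None
        image: str | None = None
        scale: float | None = None
        # trailing key lines until the next LM= or EOF
        while i < len(lines):
            nxt = lines[i].strip()
            if not nxt:
                i += 1
                continue
            km = _KEY_RE.match(nxt)
            if km is None:
                raise TpsParseError(
                    f"line {i + 1}: unexpected content {nxt!r} in record "
                    f"{n_record + 1}"
                )
            key = km.group(1).upper()
            if key == "LM":
                break
            value = km.group(2).strip()
            if key == "ID":
                specimen_id = value
            elif key == "IMAGE":
                image = value
            elif key == "SCALE":
                try:
                    scale = float(value)
                except ValueError as exc:
                    raise TpsParseError(
                        f"line {i + 1}: bad SCALE {value!r}"
                    ) from exc
            # COMMENT= and any CURVES=/POINTS= payloads are skipped
            i += 1
        if scale is not None:
            coords = coords * scale
        if specimen_id is None:
            specimen_id = (
                Path(image).stem if image else f"specimen_{n_record + 1}"
            )
        configs.append(
            LandmarkConfiguration(specimen_id=specimen_id, coords=coords, scale=scale)
        )
        n_record += 1
    return configs


def write_tps(path: str | Path, configs: Iterable[LandmarkConfiguration]) -> None:
    """Write configurations as TPS records (full float precision, no SCALE)."""
    out: list[str] = []
    for cfg in configs:
        out.append(f"LM={cfg.n_landmarks}")
        for x, y in cfg.coords:
            out.append(f"{float(x)!r} {float(y)!r}")
        out.append(f"ID={cfg.specimen_id}")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# sliders definition
# ---------------------------------------------------------------------------


def read_sliders(path: str | Path) -> tuple[tuple[int, int, int], ...]:
    """Read ``before,slider,after`` triples (1-based on disk → 0-based).

    Validation against a particular landmark count happens at scheme
    assembly; here only per-file consistency (no duplicate slider) is
    enforced.
    """
    triples: list[tuple[int, int, int]] = []
    seen: set[int] = set()
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p.strip() for p in line.split(",")]
        if len(parts) != 3:
            raise ValueError(f"sliders line {ln}: expected 3 fields, got {line!r}")
        try:
            before, slider, after = (int(p) for p in parts)
        except ValueError as exc:
            raise ValueError(f"sliders line {ln}: non-integer index in {line!r}") from exc
        if min(before, slider, after) < 1:
            raise ValueError(f"sliders line {ln}: indices are 1-based, got {line!r}")
        if slider in seen:
            raise ValueError(f"sliders line {ln}: landmark {slider} listed twice as slider")
        seen.add(slider)
        triples.append((before - 1, slider - 1, after - 1))
    return tuple(triples)


def write_sliders(path: str | Path, triples: Sequence[tuple[int, int, int]]) -> None:
    lines = [f"{b + 1},{s + 1},{a + 1}" for b, s, a in triples]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# CSV tables
# ---------------------------------------------------------------------------


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing required column(s) {missing}")


def read_metadata(path: str | Path) -> list[SpecimenRecord]:
    """Read the specimen metadata table; enumerations are enforced per row."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, METADATA_COLUMNS, "metadata")
    records: list[SpecimenRecord] = []
    for i, row in df.iterrows():
        flag = row["lagerstatten_only"].strip().lower()
        if flag not in {"true", "false", "0", "1"}:
            raise SchemaError(
                f"metadata row {i}: lagerstatten_only must be boolean, got {flag!r}"
            )
        try:
            records.append(
                SpecimenRecord(
                    specimen_id=row["specimen_id"],
                    species=row["species"],
                    genus=row["genus"],
                    family=row["family"],
                    infraclass=row["infraclass"],
                    environment=row["environment"],
                    stage=row["stage"],
                    lagerstatten_only=flag in {"true", "1"},
                )
            )
        except ValueError as exc:
            raise SchemaError(f"metadata row {i}: {exc}") from exc
    return records


def write_metadata(path: str | Path, records: Iterable[SpecimenRecord]) -> None:
    df = pd.DataFrame([vars(r) for r in records], columns=METADATA_COLUMNS)
    df.to_csv(path, index=False)


def read_trait_table(path: str | Path) -> pd.DataFrame:
    """Read the five-character trait table; empty cells become NaN.

    Returns a DataFrame indexed by ``specimen_id`` with float columns
    ``char1..char5``; present values must be strictly positive.
    """
    df = pd.read_csv(path)
    _require_columns(df, ("specimen_id", *TRAIT_COLUMNS), "trait table")
    df = df.set_index("specimen_id")
    traits = df[list(TRAIT_COLUMNS)].astype(float)
    bad = traits[(traits <= 0).any(axis=1)]
    if len(bad):
        raise SchemaError(
            f"trait table: non-positive character value(s) for specimens "
            f"{list(bad.index[:5])}"
        )
    return traits


def write_trait_table(path: str | Path, traits: pd.DataFrame) -> None:
    traits.to_csv(path, index_label="specimen_id")


def write_series(path: str | Path, series: pd.DataFrame) -> None:
    """Write one or more disparity series (columns: bin, metric, value,
    ci_low, ci_high, n) to CSV."""
    cols = ["bin", "metric", "value", "ci_low", "ci_high", "n"]
    _require_columns(series, cols, "disparity series")
    series[cols].to_csv(path, index=False)


def read_series(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ("bin", "metric", "value", "ci_low", "ci_high", "n"), "series")
    return df


def check_join(
    configs: Sequence[LandmarkConfiguration] | None,
    records: Sequence[SpecimenRecord],
    traits: pd.DataFrame | None = None,
) -> None:
    """Hard-fail if the inputs do not share specimen ids.

    Silently dropping unmatched specimens would corrupt per-bin sample sizes,
    so any id present in the landmark/trait data but absent from the metadata
    (or vice versa where relevant) raises listing the offenders.
    """
    meta_ids = {r.specimen_id for r in records}
    if configs is not None:
        lm_ids = [c.specimen_id for c in configs]
        missing = sorted(set(lm_ids) - meta_ids)
        if missing:
            raise SchemaError(f"landmark specimens absent from metadata: {missing}")
    if traits is not None:
        missing = sorted(set(traits.index) - meta_ids)
        if missing:
            raise SchemaError(f"trait specimens absent from metadata: {missing}")
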