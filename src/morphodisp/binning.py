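"""Time binning: stage → bin assignment, sample sizes, subgroup subsets.

The default scheme spans the Permian–Jurassic study interval: 27
stratigraphic stages (Asselian through Tithonian) collapsed into 17 bins —
12 single-stage bins around the two extinction boundaries plus five
combined bins (early/middle/late Permian, Early Triassic, Middle Jurassic)
where sampled fish faunas are sparse.  Midpoint ages follow the ICS
chronostratigraphic chart.  The scheme is plain data and can be replaced
from a YAML file, e.g. to run series-level bins across the Permo-Triassic
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .io import SpecimenRecord

__all__ = [
    "TimeBin",
    "TimeBinScheme",
    "BinnedDataset",
    "DEFAULT_SCHEME",
    "assign_bins",
    "bin_sizes",
    "min_bin_size",
    "subset",
]


@dataclass(frozen=True)
class TimeBin:
    name: str
    stages: tuple[str, ...]
    midpoint_ma: float

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError(f"bin {self.name!r} has no member stages")


@dataclass(frozen=True)
class TimeBinScheme:
    """Ordered (oldest → youngest) disjoint stage bins."""

    bins: tuple[TimeBin, ...]

    def __post_init__(self) -> None:
        ages = [b.midpoint_ma for b in self.bins]
        if any(a <= b for a, b in zip(ages, ages[1:])):
            raise ValueError("bins must be ordered oldest (largest Ma) to youngest")
        seen: dict[str, str] = {}
        for b in self.bins:
            for stage in b.stages:
                if stage in seen:
                    raise ValueError(
                        f"stage {stage!r} in both {seen[stage]!r} and {b.name!r}"
                    )
                seen[stage] = b.name

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.bins)

    @property
    def stage_to_bin(self) -> dict[str, str]:
        return {s: b.name for b in self.bins for s in b.stages}

    @property
    def n_stages(self) -> int:
        return sum(len(b.stages) for b in self.bins)

    def midpoints(self) -> dict[str, float]:
        return {b.name: b.midpoint_ma for b in self.bins}

    def to_yaml(self, path: str | Path) -> None:
        data = [
            {"name": b.name, "stages": list(b.stages), "midpoint_ma": b.midpoint_ma}
            for b in self.bins
        ]
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TimeBinScheme":
        data = yaml.safe_load(Path(path).read_text())
        return cls(
            bins=tuple(
                TimeBin(
                    name=d["name"],
                    stages=tuple(d["stages"]),
                    midpoint_ma=float(d["midpoint_ma"]),
                )
                for d in data
            )
        )


DEFAULT_SCHEME = TimeBinScheme(
    bins=(
        TimeBin("early Permian", ("Asselian", "Sakmarian", "Artinskian", "Kungurian"), 286.0),
        TimeBin("middle Permian", ("Roadian", "Wordian", "Capitanian"), 266.3),
        TimeBin("late Permian", ("Wuchiapingian", "Changhsingian"), 255.7),
        TimeBin("Early Triassic", ("Induan", "Olenekian"), 249.6),
        TimeBin("Anisian", ("Anisian",), 244.6),
        TimeBin("Ladinian", ("Ladinian",), 239.5),
        TimeBin("Carnian", ("Carnian",), 232.0),
        TimeBin("Norian", ("Norian",), 217.8),
        TimeBin("Rhaetian", ("Rhaetian",), 204.9),
        TimeBin("Hettangian", ("Hettangian",), 200.4),
        TimeBin("Sinemurian", ("Sinemurian",), 196.2),
        TimeBin("Pliensbachian", ("Pliensbachian",), 188.6),
        TimeBin("Toarcian", ("Toarcian",), 179.4),
        TimeBin("Middle Jurassic", ("Aalenian", "Bajocian", "Bathonian", "Callovian"), 168.1),
        TimeBin("Oxfordian", ("Oxfordian",), 158.2),
        TimeBin("Kimmeridgian", ("Kimmeridgian",), 152.0),
        TimeBin("Tithonian", ("Tithonian",), 147.1),
    )
)


@dataclass
class BinnedDataset:
    """Specimens partitioned into time bins (every bin listed, even empty)."""

    scheme: TimeBinScheme
    members: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_total(self) -> int:
        return sum(len(v) for v in self.members.values())

    def __getitem__(self, bin_name: str) -> list[str]:
        return self.members[bin_name]


def assign_bins(
    records: Sequence[SpecimenRecord],
    scheme: TimeBinScheme = DEFAULT_SCHEME,
) -> BinnedDataset:
    """Assign every specimen to its time bin (input order kept within bins)."""
    lookup = scheme.stage_to_bin
    members: dict[str, list[str]] = {name: [] for name in scheme.names}
    unknown: list[tuple[str, str]] = []
    for r in records:
        bin_name = lookup.get(r.stage)
        if bin_name is None:
            unknown.append((r.specimen_id, r.stage))
        else:
            members[bin_name].append(r.specimen_id)
    if unknown:
        raise ValueError(
            f"stage(s) outside the bin scheme for specimens: {unknown[:10]}"
        )
    return BinnedDataset(scheme=scheme, members=members)


def bin_sizes(binned: BinnedDataset) -> pd.Series:
    """Per-bin specimen counts in scheme order (a within-study diversity proxy)."""
    return pd.Series(
        {name: len(binned.members[name]) for name in binned.scheme.names},
        name="n",
    )


def min_bin_size(binned: BinnedDataset, nonempty: bool = True) -> tuple[str, int]:
    """Smallest bin and its count; by default empty bins are ignored."""
    sizes = bin_sizes(binned)
    if nonempty:
        sizes = sizes[sizes > 0]
    if sizes.empty:
        raise ValueError("no occupied bins")
    name = sizes.idxmin()
    return str(name), int(sizes.loc[name])


def subset(
    records: Iterable[SpecimenRecord],
    infraclass: str | None = None,
    environment: str | None = None,
    exclude_lagerstatten: bool = False,
) -> list[SpecimenRecord]:
    """Filter records by subgroup; filters compose as a conjunction."""
    out = []
    for r in records:
        if infraclass is not None and r.infraclass != infraclass:
            continue
        if environment is not None and r.environment != environment:
            continue
        if exclude_lagerstatten and r.lagerstatten_only:
            continue
        out.append(r)
    return out
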