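"""End-to-end orchestration of the body-shape and jaw-function analyses.

A single :class:`RunConfig` drives both arms.  The body-shape arm runs
superimposition (GPA + semilandmark sliding), tangent-space PCA, per-bin
disparity series with bootstrap intervals, boundary permutation tests and
partial disparity by infraclass and environment.  The functional arm runs
character computation / species averaging, the complete-case filter, PCA on
the five ratios and the same disparity battery.

Reproducibility: one master seed is split into independent substreams per
stage (bootstrap per metric, each permutation test), so changing the
replicate count of one stage never shifts another stage's draws.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .binning import DEFAULT_SCHEME, TimeBinScheme, assign_bins, bin_sizes, subset
from .disparity import disparity_series, partial_disparity
from .functional import (
    average_by_species,
    characters_from_measurements,
    complete_case_filter,
    missingness_rate,
)
from .geometry import gpa, slide_semilandmarks
from .inference import centroid_shift_test, disparity_difference_test
from .io import LandmarkScheme, SpecimenRecord
from .ordination import pca

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_body_shape", "run_functional"]

BOUNDARY_PAIRS = (
    ("late Permian", "Early Triassic"),  # Permo-Triassic boundary
    ("Rhaetian", "Hettangian"),          # Triassic-Jurassic boundary
)


@dataclass
class RunConfig:
    """Analysis parameters; paths may be omitted when data are passed in-memory."""

    tps_path: str | None = None
    sliders_path: str | None = None
    metadata_path: str | None = None
    trait_path: str | None = None
    measurement_path: str | None = None
    bin_scheme_path: str | None = None

    metrics: tuple[str, ...] = ("variance", "mpd", "hull")
    axes: int | None = None          # None = all axes (variance / MPD)
    hull_n_axes: int = 2
    n_bootstrap: int = 1000
    n_perm_centroid: int = 9999
    n_perm_disparity: int = 1000
    alpha: float = 0.05
    min_bin_n: int = 3
    boundary_pairs: tuple[tuple[str, str], ...] = BOUNDARY_PAIRS
    drop_lagerstatten: bool = False
    pca_mode: str = "covariance"
    species_average: bool = False
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        for name in ("n_bootstrap", "n_perm_centroid", "n_perm_disparity"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        for name in (
            "tps_path", "sliders_path", "metadata_path",
            "trait_path", "measurement_path", "bin_scheme_path",
        ):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{name}: {path}")

    def scheme(self) -> TimeBinScheme:
        if self.bin_scheme_path is not None:
            return TimeBinScheme.from_yaml(self.bin_scheme_path)
        return DEFAULT_SCHEME

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        for key in ("metrics",):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        if "boundary_pairs" in data and data["boundary_pairs"] is not None:
            data["boundary_pairs"] = tuple(tuple(p) for p in data["boundary_pairs"])
        return cls(**data)


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _members_by_bin(binned, id_to_row) -> dict[str, list[int]]:
    return {
        name: [id_to_row[sid] for sid in sids]
        for name, sids in binned.members.items()
    }


def _boundary_tests(
    scores: np.ndarray,
    members: dict[str, list[int]],
    config: RunConfig,
    rng_centroid: np.random.Generator,
    rng_disp: np.random.Generator,
    log: list,
) -> pd.DataFrame:
    rows = []
    for bin_a, bin_b in config.boundary_pairs:
        a, b = members.get(bin_a, []), members.get(bin_b, [])
        if len(a) < 2 or len(b) < 2:
            log.append(
                {"stage": "tests", "warning": f"{bin_a} vs {bin_b}: too few specimens"}
            )
            continue
        res = centroid_shift_test(
            scores, a, b, n_permutations=config.n_perm_centroid, seed=rng_centroid
        )
        rows.append(
            ("centroid_shift", bin_a, bin_b, "all-axes", res.observed, res.p_value,
             res.n_permutations, res.exhaustive)
        )
        for metric in config.metrics:
            try:
                res = disparity_difference_test(
                    scores, a, b, metric=metric,
                    n_permutations=config.n_perm_disparity,
                    seed=rng_disp, n_axes=config.hull_n_axes,
                )
            except ValueError as exc:
                log.append({"stage": "tests", "warning": f"{metric}: {exc}"})
                continue
            rows.append(
                ("disparity_difference", bin_a, bin_b, metric, res.observed,
                 res.p_value, res.n_permutations, res.exhaustive)
            )
    return pd.DataFrame(
        rows,
        columns=["test", "bin_A", "bin_B", "metric", "observed", "p", "n_perm",
                 "exhaustive"],
    )


def _partial_tables(
    scores: np.ndarray,
    members: dict[str, list[int]],
    record_of: dict[str, SpecimenRecord],
    binned,
    axes,
) -> dict[str, pd.DataFrame]:
    out: dict[str, pd.DataFrame] = {}
    for partition, getter in (
        ("infraclass", lambda r: r.infraclass),
        ("environment", lambda r: r.environment),
    ):
        rows = []
        for bin_name, sids in binned.members.items():
            idx = members[bin_name]
            if len(idx) < 2:
                continue
            labels = [getter(record_of[sid]) for sid in sids]
            pd_row = partial_disparity(scores, idx, labels, axes=axes)
            total = pd_row.pop("total")
            for group, value in pd_row.items():
                share = value / total if total > 0 else float("nan")
                rows.append((bin_name, group, value, share))
        out[partition] = pd.DataFrame(
            rows, columns=["bin", "subgroup", "partial", "share"]
        )
    return out


def _write_outputs(outdir: str, config: RunConfig, results: dict, prefix: str) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for metric, df in results["series"].items():
        mio.write_series(out / f"{prefix}_series_{metric}.csv", df)
    results["tests"].to_csv(out / f"{prefix}_tests.csv", index=False)
    for partition, df in results["partial"].items():
        df.to_csv(out / f"{prefix}_partial_{partition}.csv", index=False)
    results["scores"].to_csv(out / f"{prefix}_scores.csv", index_label="specimen_id")
    config.to_yaml(out / f"{prefix}_config_resolved.yaml")
    with open(out / f"{prefix}_run_log.yaml", "w") as fh:
        yaml.safe_dump(results["log"], fh, sort_keys=False)


def _series_bundle(
    scores: np.ndarray,
    members: dict[str, list[int]],
    config: RunConfig,
    rngs: Sequence[np.random.Generator],
) -> dict[str, pd.DataFrame]:
    series: dict[str, pd.DataFrame] = {}
    for metric, rng in zip(config.metrics, rngs):
        series[metric] = disparity_series(
            scores,
            members,
            metric=metric,
            axes=config.axes,
            n_axes=config.hull_n_axes,
            min_n=config.min_bin_n,
            n_replicates=config.n_bootstrap,
            rng=rng,
        )
    return series


def run_body_shape(
    config: RunConfig,
    configurations=None,
    records: Sequence[SpecimenRecord] | None = None,
    scheme: LandmarkScheme | None = None,
) -> dict:
    """Run the geometric body-shape arm; returns the results bundle.

    Inputs come from the config's paths unless passed directly.  The bundle
    holds the aligned sample, the ordination, tidy disparity series per
    metric, the boundary test table, partial-disparity tables, and the run
    log.  With ``config.outdir`` set, CSV/YAML outputs are written.
    """
    t0 = time.time()
    log: list[dict] = []
    if configurations is None:
        configurations = mio.read_tps(config.tps_path)
    if records is None:
        records = mio.read_metadata(config.metadata_path)
    if scheme is None:
        k = configurations[0].n_landmarks
        triples = (
            mio.read_sliders(config.sliders_path) if config.sliders_path else ()
        )
        scheme = LandmarkScheme(n_landmarks=k, slider_triples=triples)
    mio.check_join(configurations, records)

    if config.drop_lagerstatten:
        records = subset(records, exclude_lagerstatten=True)
        keep = {r.specimen_id for r in records}
        configurations = [c for c in configurations if c.specimen_id in keep]
        log.append({"stage": "filter", "n_out": len(configurations),
                    "note": "Lagerstätten-only specimens removed"})
    record_of = {r.specimen_id: r for r in records}
    records = [record_of[c.specimen_id] for c in configurations]

    sample = gpa(configurations)
    log.append({"stage": "gpa", "n": sample.n_specimens,
                "iterations": sample.n_iterations, "converged": sample.converged})
    sample = slide_semilandmarks(sample, scheme)
    log.append({"stage": "slide", "cycles": len(sample.slide_log)})

    flat = sample.aligned.reshape(sample.n_specimens, -1)
    ordination = pca(flat, mode="covariance", row_ids=sample.specimen_ids)
    log.append({"stage": "pca", "n_axes": ordination.n_axes,
                "pc12_share": float(ordination.proportion[:2].sum())})

    binned = assign_bins(records, config.scheme())
    id_to_row = {sid: i for i, sid in enumerate(sample.specimen_ids)}
    members = _members_by_bin(binned, id_to_row)

    rngs = _substreams(config.seed, len(config.metrics) + 2)
    series = _series_bundle(ordination.scores, members, config, rngs[:-2])
    tests = _boundary_tests(
        ordination.scores, members, config, rngs[-2], rngs[-1], log
    )
    partial = _partial_tables(
        ordination.scores, members, record_of, binned, config.axes
    )
    log.append({"stage": "done", "seconds": round(time.time() - t0, 2),
                "seed": config.seed})

    results = {
        "sample": sample,
        "ordination": ordination,
        "binned": binned,
        "bin_sizes": bin_sizes(binned),
        "series": series,
        "tests": tests,
        "partial": partial,
        "scores": ordination.scores_frame(),
        "log": log,
    }
    if config.outdir:
        _write_outputs(config.outdir, config, results, "body")
    return results


def run_functional(
    config: RunConfig,
    traits: pd.DataFrame | None = None,
    records: Sequence[SpecimenRecord] | None = None,
) -> dict:
    """Run the jaw-functional arm; returns the results bundle.

    Accepts a ready character table or a raw measurement table (via
    ``config.measurement_path``) from which the five ratios are computed.
    """
    t0 = time.time()
    log: list[dict] = []
    if traits is None:
        if config.trait_path is not None:
            traits = mio.read_trait_table(config.trait_path)
        elif config.measurement_path is not None:
            meas = pd.read_csv(config.measurement_path).set_index("specimen_id")
            traits = characters_from_measurements(meas)
        else:
            raise ValueError("functional arm needs trait_path or measurement_path")
    if records is None:
        records = mio.read_metadata(config.metadata_path)
    mio.check_join(None, records, traits)

    record_of = {r.specimen_id: r for r in records}
    if config.drop_lagerstatten:
        keep = [sid for sid in traits.index if not record_of[sid].lagerstatten_only]
        traits = traits.loc[keep]
        log.append({"stage": "filter", "n_out": len(traits),
                    "note": "Lagerstätten-only specimens removed"})

    if config.species_average:
        species_map = {sid: record_of[sid].species for sid in traits.index}
        n_before = len(traits)
        traits = average_by_species(traits, species_map)
        # one representative record per species (first specimen's metadata)
        rep: dict[str, SpecimenRecord] = {}
        for sid, sp in species_map.items():
            rep.setdefault(sp, record_of[sid])
        record_of = {
            sp: SpecimenRecord(
                specimen_id=sp, species=sp, genus=r.genus, family=r.family,
                infraclass=r.infraclass, environment=r.environment,
                stage=r.stage, lagerstatten_only=r.lagerstatten_only,
            )
            for sp, r in rep.items()
        }
        log.append({"stage": "species_average", "n_in": n_before,
                    "n_out": len(traits)})

    rate = missingness_rate(traits)
    complete, n_complete = complete_case_filter(traits)
    log.append({"stage": "complete_case", "missingness": round(rate, 4),
                "n_in": len(traits), "n_out": n_complete})

    ordination = pca(
        complete.to_numpy(), mode=config.pca_mode, row_ids=list(complete.index)
    )
    log.append({"stage": "pca", "n_axes": ordination.n_axes,
                "pc12_share": float(ordination.proportion[:2].sum())})

    kept_records = [record_of[sid] for sid in complete.index]
    binned = assign_bins(kept_records, config.scheme())
    id_to_row = {sid: i for i, sid in enumerate(complete.index)}
    members = _members_by_bin(binned, id_to_row)

    rngs = _substreams(config.seed, len(config.metrics) + 2)
    series = _series_bundle(ordination.scores, members, config, rngs[:-2])
    tests = _boundary_tests(
        ordination.scores, members, config, rngs[-2], rngs[-1], log
    )
    partial = _partial_tables(
        ordination.scores, members, record_of, binned, config.axes
    )
    log.append({"stage": "done", "seconds": round(time.time() - t0, 2),
                "seed": config.seed})

    results = {
        "traits": traits,
        "complete": complete,
        "missingness": rate,
        "n_complete": n_complete,
        "ordination": ordination,
        "binned": binned,
        "bin_sizes": bin_sizes(binned),
        "series": series,
        "tests": tests,
        "partial": partial,
        "scores": ordination.scores_frame(),
        "log": log,
    }
    if config.outdir:
        _write_outputs(config.outdir, config, results, "functional")
    return results
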