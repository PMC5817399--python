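"""Per-bin disparity metrics, bootstrap intervals, and partial disparity.

Three complementary views of morphospace occupation:

* **sum of variances** — per-axis sample variance (n−1 denominator) summed
  over the chosen ordination axes; a density measure, rotation-invariant
  when all axes are used.
* **mean pairwise distance (MPD)** — average dissimilarity between all
  specimen pairs in a bin.
* **convex-hull content** — area (2 axes) up to 5-D hypervolume of the
  smallest convex region containing the bin's points; a range measure.
  Because content in different dimensionalities is incommensurable, each
  temporal series is normalized by its own maximum.

Uncertainty comes from a percentile bootstrap over specimens within each
bin.  Partial disparity decomposes a bin's sum of variances additively into
subgroup contributions: with the grand centroid c of all N bin members,
``PD(g) = Σ_{i∈g} ‖x_i − c‖² / (N−1)``, so Σ_g PD(g) equals the bin's total
exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)

__all__ = [
    "BootstrapCI",
    "sum_of_variances",
    "mean_pairwise_distance",
    "hull_measure",
    "normalize_series",
    "bootstrap_ci",
    "partial_disparity",
    "disparity_series",
    "AXIS_PRESETS",
]

# axis-count presets for the sensitivity analysis (None = all axes)
AXIS_PRESETS: tuple[int | None, ...] = (2, 5, 20, None)


def _select(scores: np.ndarray, members, axes) -> np.ndarray:
    pts = np.asarray(scores, dtype=float)
    if members is not None:
        pts = pts[np.asarray(members)]
    if axes is not None:
        pts = pts[:, axes] if not np.isscalar(axes) else pts[:, :axes]
    return pts


def sum_of_variances(
    scores: np.ndarray,
    members: Sequence[int] | None = None,
    axes=None,
) -> float:
    """Sum over axes of the sample variance (ddof=1) of the members' scores.

    ``axes`` may be None (all), an int (first so-many axes) or an index
    sequence.  Returns NaN for fewer than two members.
    """
    pts = _select(scores, members, axes)
    if pts.shape[0] < 2:
        return float("nan")
    return float(pts.var(axis=0, ddof=1).sum())


def mean_pairwise_distance(
    points: np.ndarray,
    members: Sequence[int] | None = None,
) -> float:
    """Mean Euclidean distance over all C(n,2) member pairs (NaN if n < 2)."""
    pts = _select(points, members, None)
    if pts.shape[0] < 2:
        return float("nan")
    return float(pdist(pts).mean())


def hull_measure(
    scores: np.ndarray,
    members: Sequence[int] | None = None,
    n_axes: int = 2,
) -> float:
    """Convex-hull content of the members in the first ``n_axes`` axes.

    Missing (NaN) when there are too few points (n ≤ n_axes) or the points
    are affinely dependent — a degenerate hull is an undefined volume, not a
    zero one.
    """
    if not 2 <= n_axes <= 5:
        raise ValueError("n_axes must be between 2 and 5")
    pts = _select(scores, members, n_axes)
    if pts.shape[1] < n_axes:
        raise ValueError(f"scores have fewer than {n_axes} axes")
    if pts.shape[0] < n_axes + 1:
        return float("nan")
    try:
        return float(ConvexHull(pts).volume)
    except QhullError:
        logger.debug("degenerate convex hull (affinely dependent points)")
        return float("nan")


def normalize_series(values) -> np.ndarray:
    """Divide a series by its maximum; NaN entries stay NaN.

    Used so hull series computed in different dimensionalities can share an
    axis: the largest bin maps to exactly 1.
    """
    arr = np.asarray(values, dtype=float)
    if np.all(np.isnan(arr)):
        raise ValueError("cannot normalize an all-missing series")
    return arr / np.nanmax(arr)


@dataclass(frozen=True)
class BootstrapCI:
    mean: float
    low: float
    high: float
    n_replicates: int
    n_skipped: int


def bootstrap_ci(
    metric_fn: Callable[[np.ndarray], float],
    points: np.ndarray,
    n_replicates: int = 1000,
    level: float = 0.95,
    rng: np.random.Generator | int | None = None,
) -> BootstrapCI:
    """Percentile bootstrap of a disparity metric over specimens.

    Resamples rows with replacement at the original n, applies
    ``metric_fn`` to each resample, and reports the replicate mean with the
    (1−level)/2 and 1−(1−level)/2 percentiles.  Replicates where the metric
    is undefined (NaN, e.g. a degenerate hull) are skipped and counted; if
    more than half are skipped the interval is reported missing.
    """
    rng = np.random.default_rng(rng)
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    idx = rng.integers(0, n, size=(n_replicates, n))
    values = np.array([metric_fn(pts[row]) for row in idx])
    ok = values[~np.isnan(values)]
    n_skipped = n_replicates - ok.size
    if ok.size < n_replicates / 2:
        logger.warning(
            "bootstrap: %d/%d replicates undefined; interval reported missing",
            n_skipped,
            n_replicates,
        )
        return BootstrapCI(float("nan"), float("nan"), float("nan"), n_replicates, n_skipped)
    alpha = (1.0 - level) / 2.0
    low, high = np.quantile(ok, [alpha, 1.0 - alpha])
    return BootstrapCI(float(ok.mean()), float(low), float(high), n_replicates, n_skipped)


def partial_disparity(
    scores: np.ndarray,
    members: Sequence[int],
    group_labels: Sequence[str],
    axes=None,
) -> dict[str, float]:
    """Additive subgroup decomposition of a bin's sum of variances.

    Squared distances are always measured from the centroid of *all* bin
    members, so a subgroup's value reflects its spread about the whole
    fauna's mean form, and the values sum exactly to the bin's sum of
    variances.  Returns ``{group: PD, ..., "total": Σ}``; a singleton bin is
    undefined (all NaN).
    """
    if len(group_labels) != len(members):
        raise ValueError("one group label per member is required")
    pts = _select(scores, members, axes)
    n = pts.shape[0]
    labels = np.asarray(group_labels)
    if n < 2:
        return {g: float("nan") for g in dict.fromkeys(labels)} | {"total": float("nan")}
    sq = np.sum((pts - pts.mean(axis=0)) ** 2, axis=1)
    out: dict[str, float] = {}
    for g in dict.fromkeys(labels):  # first-appearance order
        out[str(g)] = float(sq[labels == g].sum() / (n - 1))
    out["total"] = float(sq.sum() / (n - 1))
    return out


def disparity_series(
    scores: np.ndarray,
    binned_members: dict[str, Sequence[int]],
    metric: str = "variance",
    axes=None,
    n_axes: int = 2,
    min_n: int = 3,
    n_replicates: int = 1000,
    level: float = 0.95,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Per-bin disparity with bootstrap CIs, as a tidy frame.

    ``binned_members`` maps bin name → row indices into ``scores``.  Bins
    below ``min_n`` members are reported with value/CI missing but their n
    retained.  Metrics: ``variance`` (sum of variances over ``axes``),
    ``mpd`` (over ``axes``), ``hull`` (first ``n_axes`` axes, normalized by
    the series maximum; degenerate bins stay missing and are excluded from
    the maximum).
    """
    if metric == "variance":
        fn = lambda pts: sum_of_variances(pts)  # noqa: E731
        prep = lambda m: _select(scores, m, axes)  # noqa: E731
    elif metric == "mpd":
        fn = mean_pairwise_distance
        prep = lambda m: _select(scores, m, axes)  # noqa: E731
    elif metric == "hull":
        fn = lambda pts: hull_measure(pts, n_axes=min(n_axes, pts.shape[1]))  # noqa: E731
        prep = lambda m: _select(scores, m, n_axes)  # noqa: E731
    else:
        raise ValueError(f"unknown metric {metric!r}")

    rng = np.random.default_rng(rng)
    rows = []
    for bin_name, members in binned_members.items():
        n = len(members)
        if n < max(min_n, 2):
            rows.append((bin_name, metric, np.nan, np.nan, np.nan, n))
            continue
        pts = prep(members)
        value = fn(pts)
        ci = bootstrap_ci(fn, pts, n_replicates=n_replicates, level=level, rng=rng)
        rows.append((bin_name, metric, value, ci.low, ci.high, n))
    df = pd.DataFrame(rows, columns=["bin", "metric", "value", "ci_low", "ci_high", "n"])
    if metric == "hull" and not df["value"].isna().all():
        peak = np.nanmax(df["value"].to_numpy())
        for col in ("value", "ci_low", "ci_high"):
            df[col] = df[col] / peak
    return df
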