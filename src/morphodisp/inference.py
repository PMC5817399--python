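"""Permutation tests across time-bin pairs.

Two tests, both built on random re-partitioning of the pooled specimens
into the two observed group sizes:

* **centroid-shift test** (NPMANOVA-style) — the statistic is the Euclidean
  distance between the two group mean positions in full score space; a
  significant value indicates the bins occupy different regions of
  morphospace.
* **disparity-difference test** — the statistic is the absolute difference
  in a disparity metric (sum of variances, MPD, or hull content) between
  the groups.

Sampled p-values use the add-one correction p = (#{null ≥ obs} + 1)/(B + 1),
which can never be zero and is valid at any B.  When the number of distinct
assignments C(nA+nB, nA) does not exceed the permutation budget the null is
enumerated exhaustively and the p-value is exact (the observed assignment is
part of the enumeration).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np

from .disparity import hull_measure, mean_pairwise_distance, sum_of_variances

logger = logging.getLogger(__name__)

__all__ = ["PermutationResult", "centroid_shift_test", "disparity_difference_test"]

_GE_TOL = 1e-12  # ties in the null count as >= observed


@dataclass(frozen=True)
class PermutationResult:
    statistic_name: str
    observed: float
    p_value: float
    n_permutations: int
    exhaustive: bool
    seed: int | None
    null_mean: float
    null_q95: float
    n_skipped: int = 0

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        mode = "exact" if self.exhaustive else f"{self.n_permutations} perms"
        return (
            f"{self.statistic_name}: observed={self.observed:.6g}, "
            f"p={self.p_value:.4g} ({mode})"
        )


def _pool(scores: np.ndarray, members_a, members_b) -> tuple[np.ndarray, int, int]:
    a = np.asarray(members_a, dtype=int)
    b = np.asarray(members_b, dtype=int)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.intersect1d(a, b).size:
        raise ValueError("groups overlap")
    pooled = np.asarray(scores, dtype=float)[np.concatenate([a, b])]
    return pooled, a.size, b.size


def _finish(
    name: str,
    observed: float,
    null: np.ndarray,
    exhaustive: bool,
    seed,
    n_skipped: int = 0,
) -> PermutationResult:
    if exhaustive:
        p = float(np.mean(null >= observed - _GE_TOL))
        n_perm = null.size
    else:
        n_perm = null.size
        p = (float(np.sum(null >= observed - _GE_TOL)) + 1.0) / (n_perm + 1.0)
    return PermutationResult(
        statistic_name=name,
        observed=float(observed),
        p_value=p,
        n_permutations=n_perm,
        exhaustive=exhaustive,
        seed=seed if isinstance(seed, int) else None,
        null_mean=float(null.mean()) if null.size else float("nan"),
        null_q95=float(np.quantile(null, 0.95)) if null.size else float("nan"),
        n_skipped=n_skipped,
    )


def _exhaustive_assignments(n: int, n_a: int):
    """Yield boolean masks (length n, n_a True) over all distinct assignments."""
    for combo in combinations(range(n), n_a):
        mask = np.zeros(n, dtype=bool)
        mask[list(combo)] = True
        yield mask


def centroid_shift_test(
    scores: np.ndarray,
    members_a: Sequence[int],
    members_b: Sequence[int],
    n_permutations: int = 9999,
    seed: np.random.Generator | int | None = None,
) -> PermutationResult:
    """Permutation test for a shift in morphospace centroid between two bins.

    All score axes are used.  Null distances come from re-partitioning the
    pooled specimens into the observed group sizes.
    """
    pooled, n_a, n_b = _pool(scores, members_a, members_b)
    n = n_a + n_b

    def stat(mask: np.ndarray) -> float:
        return float(
            np.linalg.norm(pooled[mask].mean(axis=0) - pooled[~mask].mean(axis=0))
        )

    obs_mask = np.zeros(n, dtype=bool)
    obs_mask[:n_a] = True
    observed = stat(obs_mask)

    if comb(n, n_a) <= n_permutations:
        null = np.array([stat(m) for m in _exhaustive_assignments(n, n_a)])
        return _finish("centroid_shift", observed, null, True, seed)

    rng = np.random.default_rng(seed)
    # vectorized: each permutation is a row of shuffled indices
    order = np.argsort(rng.random((n_permutations, n)), axis=1)
    grp_a = pooled[order[:, :n_a]].mean(axis=1)
    grp_b = pooled[order[:, n_a:]].mean(axis=1)
    null = np.linalg.norm(grp_a - grp_b, axis=1)
    return _finish(
        "centroid_shift", observed, null, False, seed
    )


def disparity_difference_test(
    scores: np.ndarray,
    members_a: Sequence[int],
    members_b: Sequence[int],
    metric: str = "variance",
    n_permutations: int = 1000,
    seed: np.random.Generator | int | None = None,
    n_axes: int = 2,
) -> PermutationResult:
    """Two-sided permutation test for a disparity difference between bins.

    The statistic is |D(A) − D(B)| for the chosen metric.  For the hull
    metric, permutations yielding a degenerate hull in either group are
    skipped and counted.
    """
    pooled, n_a, n_b = _pool(scores, members_a, members_b)
    n = n_a + n_b

    if metric == "variance":
        metric_fn = lambda pts: sum_of_variances(pts)  # noqa: E731
    elif metric == "mpd":
        metric_fn = mean_pairwise_distance
    elif metric == "hull":
        metric_fn = lambda pts: hull_measure(pts, n_axes=n_axes)  # noqa: E731
        pooled = pooled[:, :n_axes]
    else:
        raise ValueError(f"unknown metric {metric!r}")

    def stat(mask: np.ndarray) -> float:
        return abs(metric_fn(pooled[mask]) - metric_fn(pooled[~mask]))

    obs_mask = np.zeros(n, dtype=bool)
    obs_mask[:n_a] = True
    observed = stat(obs_mask)
    if np.isnan(observed):
        raise ValueError(f"metric {metric!r} undefined on the observed groups")

    exhaustive = comb(n, n_a) <= n_permutations
    if exhaustive:
        null = np.array([stat(m) for m in _exhaustive_assignments(n, n_a)])
        keep = ~np.isnan(null)
        return _finish(
            f"disparity_diff_{metric}",
            observed,
            null[keep],
            True,
            seed,
            n_skipped=int((~keep).sum()),
        )

    rng = np.random.default_rng(seed)
    if metric == "variance":
        order = np.argsort(rng.random((n_permutations, n)), axis=1)
        var_a = pooled[order[:, :n_a]].var(axis=1, ddof=1).sum(axis=1)
        var_b = pooled[order[:, n_a:]].var(axis=1, ddof=1).sum(axis=1)
        null = np.abs(var_a - var_b)
        n_skipped = 0
    else:
        null_list = []
        n_skipped = 0
        for _ in range(n_permutations):
            mask = np.zeros(n, dtype=bool)
            mask[rng.choice(n, size=n_a, replace=False)] = True
            value = stat(mask)
            if np.isnan(value):
                n_skipped += 1
            else:
                null_list.append(value)
        null = np.array(null_list)
    return _finish(
        f"disparity_diff_{metric}", observed, null, False, seed, n_skipped=n_skipped
    )
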