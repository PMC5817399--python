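"""Principal component analysis of aligned coordinates or functional traits.

A covariance-mode PCA of Procrustes-aligned coordinates yields the tangent
space axes used as the morphospace; the same routine on the five jaw ratios
yields the functional morphospace.  Scores, eigenvalues, variance
proportions and loadings are all exposed, and shapes can be reconstructed
along any axis (the basis of deformation-grid visualization).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Ordination", "pca", "shape_along_axis"]


@dataclass
class Ordination:
    scores: np.ndarray        # (n, m)
    axis_variance: np.ndarray  # (m,) eigenvalues
    proportion: np.ndarray     # (m,) sums to 1, non-increasing
    loadings: np.ndarray       # (p, m), orthonormal columns
    center: np.ndarray         # (p,)
    scale: np.ndarray | None   # (p,) column SDs, correlation mode only
    mode: str                  # "covariance" | "correlation"
    row_ids: tuple[str, ...] | None = None

    @property
    def n_axes(self) -> int:
        return self.scores.shape[1]

    def reconstruct(self, scores_row: np.ndarray) -> np.ndarray:
        """Map a score vector back to the original variable space."""
        x = self.center + np.asarray(scores_row) @ self.loadings.T * (
            self.scale if self.scale is not None else 1.0
        )
        return x

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.n_axes)]
        idx = list(self.row_ids) if self.row_ids is not None else None
        return pd.DataFrame(self.scores, columns=cols, index=idx)


def pca(
    data_matrix: np.ndarray,
    mode: str = "covariance",
    row_ids=None,
) -> Ordination:
    """PCA by singular value decomposition of the centered data matrix.

    ``mode="correlation"`` additionally standardizes each column by its
    sample standard deviation (a zero-variance column is an error there).
    The number of axes reported is min(n-1, p); eigenvalues below
    1e-12 × the largest are reported as exact zeros.  Sign convention: the
    largest-magnitude entry of every loading column is positive, so results
    are reproducible across runs and platforms.
    """
    X = np.asarray(data_matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("data matrix must be 2-D")
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 rows")
    if np.isnan(X).any():
        raise ValueError(
            "missing values in PCA input; apply the complete-case filter first"
        )
    if mode not in ("covariance", "correlation"):
        raise ValueError(f"unknown mode {mode!r}")

    center = X.mean(axis=0)
    Xc = X - center
    scale = None
    if mode == "correlation":
        scale = Xc.std(axis=0, ddof=1)
        if np.any(scale < 1e-15):
            bad = np.nonzero(scale < 1e-15)[0].tolist()
            raise ValueError(f"zero-variance column(s) {bad} under correlation mode")
        Xc = Xc / scale

    m = min(n - 1, p)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    U, s, Vt = U[:, :m], s[:m], Vt[:m]
    eigenvalues = s**2 / (n - 1)
    eigenvalues[eigenvalues < 1e-12 * max(eigenvalues[0], 1e-300)] = 0.0

    loadings = Vt.T
    scores = U * s
    # deterministic sign: largest-|.| entry of each loading column positive
    flip = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(m)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = scores * flip

    total = eigenvalues.sum()
    proportion = eigenvalues / total if total > 0 else np.zeros(m)
    return Ordination(
        scores=scores,
        axis_variance=eigenvalues,
        proportion=proportion,
        loadings=loadings,
        center=center,
        scale=scale,
        mode=mode,
        row_ids=tuple(row_ids) if row_ids is not None else None,
    )


def shape_along_axis(
    ordination: Ordination,
    consensus: np.ndarray,
    axis: int,
    score: float,
) -> np.ndarray:
    """Model shape at a given score along one morphospace axis.

    Assumes the ordination was fitted on flattened (k·2) aligned
    coordinates; returns consensus + score × loading, reshaped to (k, 2).
    At score 0 this is exactly the consensus.
    """
    consensus = np.asarray(consensus, dtype=float)
    if not 0 <= axis < ordination.n_axes:
        raise ValueError(f"axis {axis} out of range 0..{ordination.n_axes - 1}")
    k2 = ordination.loadings.shape[0]
    if consensus.size != k2:
        raise ValueError("consensus size does not match the ordination variables")
    vec = ordination.loadings[:, axis]
    if ordination.scale is not None:
        vec = vec * ordination.scale
    return consensus + score * vec.reshape(consensus.shape)
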