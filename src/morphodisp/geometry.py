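"""Generalized Procrustes superimposition and semilandmark sliding.

Shape is what remains of a landmark configuration after position, scale and
orientation are removed.  The superimposition here is the classic iterative
scheme: every configuration is translated to the origin and scaled to unit
centroid size, rotated to the running consensus, and the consensus is the
renormalized mean, iterated to a fixed point.  Semilandmarks — points whose
position along a curve carries no anatomical identity — are then allowed to
slide along their local tangent so as to minimize the thin-plate-spline
bending energy relative to the consensus, and the whole sample is
re-superimposed, cycling until the consensus stops moving.

Rotations are proper (determinant +1): a reflection would silently equate a
left-facing with a right-facing body, so input images are assumed to be
standardized to the same facing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import LandmarkConfiguration, LandmarkScheme

logger = logging.getLogger(__name__)

__all__ = [
    "AlignedSample",
    "BendingEnergyMatrix",
    "DegenerateShapeError",
    "center_and_scale",
    "centroid_size",
    "optimal_rotation",
    "gpa",
    "bending_energy_matrix",
    "bending_energy",
    "slide_semilandmarks",
    "procrustes_distance",
    "pairwise_distances",
]


class DegenerateShapeError(ValueError):
    """All landmarks coincident (or otherwise geometrically degenerate)."""


@dataclass
class AlignedSample:
    """A jointly superimposed sample of landmark configurations.

    ``aligned`` holds the n configurations in a common frame — centroid at
    the origin, centroid size 1, rotated to the consensus.  ``consensus`` is
    the mean shape renormalized to unit centroid size.  ``centroid_sizes``
    are the pre-scaling sizes (the classic size proxy).  ``slide_log``, when
    sliding has run, records per cycle the total bending energy before and
    after the tangent slide against that cycle's reference.
    """

    aligned: np.ndarray  # (n, k, 2)
    consensus: np.ndarray  # (k, 2)
    centroid_sizes: np.ndarray  # (n,)
    specimen_ids: tuple[str, ...]
    n_iterations: int
    converged: bool
    slide_log: list[dict] = field(default_factory=list)

    @property
    def n_specimens(self) -> int:
        return self.aligned.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.aligned.shape[1]

    def index_of(self, specimen_id: str) -> int:
        return self.specimen_ids.index(specimen_id)


def centroid_size(coords: np.ndarray) -> float:
    """Root summed squared deviation of landmarks from their centroid."""
    coords = np.asarray(coords, dtype=float)
    return float(np.linalg.norm(coords - coords.mean(axis=0)))


def center_and_scale(coords: np.ndarray) -> tuple[np.ndarray, float]:
    """Translate centroid to origin and rescale to unit centroid size.

    Returns the normalized shape and the original centroid size.
    """
    coords = np.asarray(coords, dtype=float)
    centered = coords - coords.mean(axis=0)
    size = float(np.linalg.norm(centered))
    if size < 1e-12:
        raise DegenerateShapeError("all landmarks coincident")
    return centered / size, size


def optimal_rotation(shape: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Rotate ``shape`` (proper rotation only) to best fit ``reference``.

    Minimizes the summed squared landmark distance over SO(2); reflections
    are excluded, so a mirror image keeps a positive residual.
    Both inputs must already be centered.
    """
    R = _rotations(shape[None], reference)[0]
    return shape @ R


def _rotations(shapes: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Batched Kabsch: per shape the proper rotation R minimizing |S R - ref|."""
    M = np.einsum("nki,kj->nij", shapes, reference)  # (n, 2, 2)
    U, _, Vt = np.linalg.svd(M)
    det = np.linalg.det(U @ Vt)
    D = np.repeat(np.eye(2)[None], len(shapes), axis=0)
    D[:, 1, 1] = np.sign(det)
    return U @ D @ Vt


def gpa(
    configurations,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> AlignedSample:
    """Generalized Procrustes analysis of two or more configurations.

    Accepts ``LandmarkConfiguration`` objects or bare (k, 2) arrays.  All
    configurations are normalized to unit centroid size (partial Procrustes:
    no further scaling during rotation), then iteratively rotated to the
    consensus until the consensus moves by less than ``tol`` (RMS coordinate
    change) or ``max_iter`` is hit, in which case the result is returned with
    ``converged=False`` and a warning is logged.
    """
    shapes, sizes, ids = _as_shape_stack(configurations)
    n, k, _ = shapes.shape
    if n < 2:
        raise ValueError("GPA needs at least 2 configurations")

    reference = shapes[0]
    n_it = 0
    converged = False
    for n_it in range(1, max_iter + 1):
        R = _rotations(shapes, reference)
        shapes = np.einsum("nki,nij->nkj", shapes, R)
        mean = shapes.mean(axis=0)
        new_ref, _ = center_and_scale(mean)
        delta = np.sqrt(np.mean((new_ref - reference) ** 2))
        reference = new_ref
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning("GPA did not converge in %d iterations", max_iter)

    # final pass so every configuration faces the final consensus
    R = _rotations(shapes, reference)
    shapes = np.einsum("nki,nij->nkj", shapes, R)
    consensus, _ = center_and_scale(shapes.mean(axis=0))
    consensus, shapes = _canonical_orientation(consensus, shapes)
    return AlignedSample(
        aligned=shapes,
        consensus=consensus,
        centroid_sizes=sizes,
        specimen_ids=ids,
        n_iterations=n_it,
        converged=converged,
    )


def _canonical_orientation(consensus, shapes):
    """Rotate the whole frame so the consensus lies along its principal axes.

    The Procrustes fixed point is only defined up to a global rotation; this
    makes the output frame deterministic (hence invariant to input ordering
    and orientation).  The remaining 180° ambiguity is settled by making the
    x-coordinate of the most eccentric landmark positive.
    """
    _, _, Vt = np.linalg.svd(consensus, full_matrices=False)
    R = Vt.T
    if np.linalg.det(R) < 0:
        R[:, 1] = -R[:, 1]
    c = consensus @ R
    if c[np.argmax(np.abs(c[:, 0])), 0] < 0:
        R = -R  # rotate by pi (still proper)
        c = -c
    return c, shapes @ R


def _as_shape_stack(configurations):
    shapes, sizes, ids = [], [], []
    for i, cfg in enumerate(configurations):
        if isinstance(cfg, LandmarkConfiguration):
            coords, sid = cfg.coords, cfg.specimen_id
        else:
            coords, sid = np.asarray(cfg, dtype=float), f"specimen_{i + 1}"
        normalized, size = center_and_scale(coords)
        shapes.append(normalized)
        sizes.append(size)
        ids.append(sid)
    ks = {s.shape[0] for s in shapes}
    if len(ks) != 1:
        raise ValueError(f"configurations disagree on landmark count: {sorted(ks)}")
    return np.stack(shapes), np.asarray(sizes), tuple(ids)


# ---------------------------------------------------------------------------
# thin-plate-spline bending energy
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BendingEnergyMatrix:
    """Bending-energy quadratic form of a reference configuration.

    ``matrix`` is the upper-left k×k block of the inverse of the bordered
    thin-plate-spline system built on the reference landmarks with kernel
    U(r) = r² log r².  It is symmetric positive semi-definite and
    annihilates affine terms (constant, x and y vectors of the reference),
    so the bending energy xᵀMx + yᵀMy of a deformation measures only its
    non-affine part.
    """

    reference: np.ndarray  # (k, 2)
    matrix: np.ndarray  # (k, k)


def _tps_kernel(r2: np.ndarray) -> np.ndarray:
    # U(r) = r^2 log r^2, with U(0) = 0
    out = np.zeros_like(r2)
    nz = r2 > 0
    out[nz] = r2[nz] * np.log(r2[nz])
    return out


def bending_energy_matrix(reference: np.ndarray) -> BendingEnergyMatrix:
    """Build the bending-energy matrix of a reference shape."""
    ref = np.asarray(reference, dtype=float)
    k = ref.shape[0]
    diff = ref[:, None, :] - ref[None, :, :]
    r2 = np.sum(diff**2, axis=-1)
    if np.any(r2[~np.eye(k, dtype=bool)] < 1e-24):
        raise DegenerateShapeError("coincident landmarks in bending-energy reference")
    K = _tps_kernel(r2)
    Q = np.column_stack([np.ones(k), ref])  # affine block [1 | x | y]
    L = np.zeros((k + 3, k + 3))
    L[:k, :k] = K
    L[:k, k:] = Q
    L[k:, :k] = Q.T
    try:
        Linv = np.linalg.inv(L)
    except np.linalg.LinAlgError as exc:
        raise DegenerateShapeError("singular thin-plate-spline system") from exc
    M = Linv[:k, :k]
    M = 0.5 * (M + M.T)  # symmetrize against round-off
    return BendingEnergyMatrix(reference=ref, matrix=M)


def bending_energy(bem: BendingEnergyMatrix, target: np.ndarray) -> float:
    """Bending energy of deforming the reference into ``target``."""
    offsets = np.asarray(target, dtype=float) - bem.reference
    return float(
        offsets[:, 0] @ bem.matrix @ offsets[:, 0]
        + offsets[:, 1] @ bem.matrix @ offsets[:, 1]
    )


# ---------------------------------------------------------------------------
# semilandmark sliding
# ---------------------------------------------------------------------------


def _slide_one(
    shape: np.ndarray,
    consensus: np.ndarray,
    M: np.ndarray,
    triples,
    max_cond: float = 1e10,
) -> np.ndarray:
    """Slide one specimen's semilandmarks along their tangents.

    Each semilandmark moves only along the unit chord between its ``before``
    and ``after`` neighbors; the tangent offsets jointly minimize the
    bending energy of the specimen relative to the consensus.  Falls back to
    plain tangent projection (minimizing Procrustes distance to the
    consensus) if the restricted system is ill-conditioned.

    The tangent is a linearization of the curve, so the joint step is
    scaled back (one scalar factor, which preserves the energy decrease of
    the quadratic model) whenever it would carry a semilandmark further
    than ~half its local chord.
    """
    sliders = [t[1] for t in triples]
    tangents = np.empty((len(triples), 2))
    for j, (b, _, a) in enumerate(triples):
        chord = shape[a] - shape[b]
        norm = np.linalg.norm(chord)
        if norm < 1e-12:
            tangents[j] = 0.0
            continue
        tangents[j] = chord / norm

    k = shape.shape[0]
    # T maps slider offsets alpha (s,) to coordinate perturbations (2k,),
    # coordinates flattened as [x_1..x_k, y_1..y_k]
    s = len(triples)
    T = np.zeros((2 * k, s))
    for j, lm in enumerate(sliders):
        T[lm, j] = tangents[j, 0]
        T[k + lm, j] = tangents[j, 1]

    v = np.concatenate([shape[:, 0] - consensus[:, 0], shape[:, 1] - consensus[:, 1]])
    M2 = np.zeros((2 * k, 2 * k))
    M2[:k, :k] = M
    M2[k:, k:] = M

    A = T.T @ M2 @ T
    b_vec = T.T @ (M2 @ v)
    use_projection = False
    try:
        if np.linalg.cond(A) > max_cond:
            use_projection = True
        else:
            alpha = np.linalg.solve(A, -b_vec)
    except np.linalg.LinAlgError:
        use_projection = True
    if use_projection:
        logger.info("ill-conditioned slide system; falling back to tangent projection")
        offsets = shape[sliders] - consensus[sliders]
        alpha = -np.einsum("ji,ji->j", tangents, offsets)

    # trust region: stay within ~half the local chord so the tangent
    # linearization remains valid and sliders cannot run along the outline
    chords = np.array(
        [np.linalg.norm(shape[a] - shape[b]) for b, _, a in triples]
    )
    limits = 0.45 * chords
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = limits / np.abs(alpha)
    t_step = min(1.0, float(np.nanmin(ratios[np.abs(alpha) > 0], initial=1.0)))
    alpha = t_step * alpha

    slid = shape.copy()
    slid[sliders] += alpha[:, None] * tangents
    return slid


def slide_semilandmarks(
    sample: AlignedSample,
    scheme: LandmarkScheme,
    tol: float = 1e-6,
    max_cycles: int = 10,
    reference: str = "updated",
) -> AlignedSample:
    """Slide semilandmarks by bending-energy minimization, then re-align.

    Cycles of: (re)build the bending-energy matrix on the current consensus,
    slide every specimen (fixed landmarks never move except through the
    subsequent superimposition), re-run GPA; stop when the consensus moves by
    less than ``tol`` or after ``max_cycles``.  With ``reference="fixed"``
    the bending-energy matrix of the initial consensus is reused throughout.

    The returned sample's ``slide_log`` holds, per cycle, the total bending
    energy of the sample against that cycle's reference before and after the
    slide; the slide step never increases it.
    """
    if scheme.n_landmarks != sample.n_landmarks:
        raise ValueError("scheme landmark count does not match the sample")
    if not scheme.slider_triples:
        return sample

    current = sample
    log: list[dict] = []
    bem = bending_energy_matrix(current.consensus)
    for cycle in range(1, max_cycles + 1):
        if reference == "updated":
            bem = bending_energy_matrix(current.consensus)
        ref_shape, M = bem.reference, bem.matrix
        before = sum(bending_energy(bem, s) for s in current.aligned)
        slid = np.stack(
            [
                _slide_one(s, ref_shape, M, scheme.slider_triples)
                for s in current.aligned
            ]
        )
        after = sum(bending_energy(bem, s) for s in slid)
        log.append({"cycle": cycle, "energy_before": before, "energy_after": after})

        realigned = gpa([s for s in slid])
        delta = np.sqrt(np.mean((realigned.consensus - current.consensus) ** 2))
        current = AlignedSample(
            aligned=realigned.aligned,
            consensus=realigned.consensus,
            centroid_sizes=sample.centroid_sizes,
            specimen_ids=sample.specimen_ids,
            n_iterations=realigned.n_iterations,
            converged=realigned.converged,
            slide_log=log,
        )
        if delta < tol:
            break
    return current


# ---------------------------------------------------------------------------
# Procrustes distances
# ---------------------------------------------------------------------------


def procrustes_distance(
    aligned_a: np.ndarray,
    aligned_b: np.ndarray,
    method: str = "common",
) -> float:
    """Shape distance between two configurations of one aligned sample.

    ``common`` (default): Euclidean norm of the coordinate difference in the
    shared frame — the partial Procrustes distance after one joint
    superimposition.  ``pairwise``: the two shapes are re-centered, rescaled
    and optimally rotated to each other before taking the norm.
    """
    a = np.asarray(aligned_a, dtype=float)
    b = np.asarray(aligned_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("configurations must share the same landmark count")
    if method == "common":
        return float(np.linalg.norm(a - b))
    if method == "pairwise":
        a, _ = center_and_scale(a)
        b, _ = center_and_scale(b)
        return float(np.linalg.norm(optimal_rotation(a, b) - b))
    raise ValueError(f"unknown method {method!r}")


def pairwise_distances(sample: AlignedSample, method: str = "common") -> np.ndarray:
    """Full n×n matrix of Procrustes distances within an aligned sample."""
    n = sample.n_specimens
    flat = sample.aligned.reshape(n, -1)
    if method == "common":
        diff = flat[:, None, :] - flat[None, :, :]
        return np.sqrt(np.sum(diff**2, axis=-1))
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = procrustes_distance(
                sample.aligned[i], sample.aligned[j], method="pairwise"
            )
    return D
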