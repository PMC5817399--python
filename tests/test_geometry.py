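import numpy as np
import pytest

from morphodisp.geometry import (
    DegenerateShapeError,
    bending_energy,
    bending_energy_matrix,
    center_and_scale,
    gpa,
    optimal_rotation,
    pairwise_distances,
    procrustes_distance,
    slide_semilandmarks,
)
from morphodisp.io import LandmarkScheme

from conftest import random_similarity_copies


def rotation(theta):
    return np.array(
        [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
    )


class TestCenterAndScale:
    def test_unit_square_size_is_sqrt2(self):
        square = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        normalized, size = center_and_scale(square)
        assert size == pytest.approx(np.sqrt(2))
        np.testing.assert_allclose(normalized, (square - 0.5) / np.sqrt(2))

    def test_idempotent_on_normalized_shape(self):
        shape, _ = center_and_scale(np.random.default_rng(0).random((6, 2)))
        again, size = center_and_scale(shape)
        np.testing.assert_allclose(again, shape, atol=1e-12)
        assert size == pytest.approx(1.0)

    def test_translation_invariance(self):
        rng = np.random.default_rng(1)
        shape = rng.random((5, 2))
        a, _ = center_and_scale(shape)
        b, _ = center_and_scale(shape + 5.0)
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_coincident_landmarks_rejected(self):
        with pytest.raises(DegenerateShapeError):
            center_and_scale(np.ones((4, 2)))


class TestOptimalRotation:
    def test_recovers_reference_from_rotated_copy(self):
        rng = np.random.default_rng(2)
        ref, _ = center_and_scale(rng.random((7, 2)))
        rotated = ref @ rotation(np.pi / 2).T
        np.testing.assert_allclose(optimal_rotation(rotated, ref), ref, atol=1e-12)

    def test_reflection_not_undone(self):
        rng = np.random.default_rng(3)
        ref, _ = center_and_scale(rng.random((7, 2)))
        mirrored = ref * [-1, 1]
        best = optimal_rotation(mirrored, ref)
        assert np.linalg.norm(best - ref) > 1e-3  # residual stays positive

    def test_identity_on_itself(self):
        rng = np.random.default_rng(4)
        ref, _ = center_and_scale(rng.random((5, 2)))
        np.testing.assert_allclose(optimal_rotation(ref, ref), ref, atol=1e-12)


class TestGpa:
    def test_exact_superimposability(self, base_outline):
        rng = np.random.default_rng(5)
        copies = random_similarity_copies(base_outline, 20, rng)
        sample = gpa(copies)
        flat = sample.aligned.reshape(20, -1)
        d = np.linalg.norm(flat[:, None] - flat[None], axis=-1)
        assert d.max() < 1e-8
        assert sample.converged

    def test_aligned_invariants(self, small_aligned):
        centroids = small_aligned.aligned.mean(axis=1)
        np.testing.assert_allclose(centroids, 0, atol=1e-9)
        sizes = np.linalg.norm(small_aligned.aligned, axis=(1, 2))
        np.testing.assert_allclose(sizes, 1, atol=1e-9)
        mean = small_aligned.aligned.mean(axis=0)
        np.testing.assert_allclose(
            small_aligned.consensus, mean / np.linalg.norm(mean), atol=1e-9
        )

    def test_order_invariance(self, base_outline):
        rng = np.random.default_rng(6)
        shapes = [
            base_outline + 0.05 * rng.standard_normal(base_outline.shape)
            for _ in range(8)
        ]
        fwd = gpa(shapes, tol=1e-12, max_iter=300)
        rev = gpa(shapes[::-1], tol=1e-12, max_iter=300)
        np.testing.assert_allclose(fwd.consensus, rev.consensus, atol=1e-9)

    def test_input_similarity_invariance(self, base_outline):
        rng = np.random.default_rng(7)
        shapes = [
            base_outline + 0.05 * rng.standard_normal(base_outline.shape)
            for _ in range(6)
        ]
        plain = gpa(shapes, tol=1e-12, max_iter=300)
        transformed = [
            2.5 * (s @ rotation(0.7).T) + [3.0, -1.0] for s in shapes
        ]
        again = gpa(transformed, tol=1e-12, max_iter=300)
        np.testing.assert_allclose(plain.consensus, again.consensus, atol=1e-9)
        np.testing.assert_allclose(plain.aligned, again.aligned, atol=1e-9)

    def test_consensus_approaches_true_base(self, base_outline):
        base, _ = center_and_scale(base_outline)
        rng = np.random.default_rng(8)
        errors = []
        for n in (10, 640):
            shapes = [
                base + 0.01 * rng.standard_normal(base.shape) for _ in range(n)
            ]
            sample = gpa(shapes)
            consensus = optimal_rotation(sample.consensus, base)
            errors.append(np.linalg.norm(consensus - base))
        # per-specimen displacement is ~0.01*sqrt(2k)≈0.075; the mean of n
        # shapes should sit well inside that, shrinking with n
        assert errors[0] < 0.05
        assert errors[1] < errors[0] / 2

    def test_needs_two_configurations(self, base_outline):
        with pytest.raises(ValueError):
            gpa([base_outline])


class TestBendingEnergy:
    def test_affine_deformation_has_zero_energy(self, base_outline):
        bem = bending_energy_matrix(base_outline)
        A = np.array([[1.3, 0.4], [-0.2, 0.8]])
        target = base_outline @ A.T + [2.0, -1.0]
        assert abs(bending_energy(bem, target)) < 1e-9

    def test_reference_against_itself_is_zero(self, base_outline):
        bem = bending_energy_matrix(base_outline)
        assert bending_energy(bem, base_outline) == 0.0

    def test_nonaffine_displacement_positive(self, base_outline):
        bem = bending_energy_matrix(base_outline)
        target = base_outline.copy()
        target[5] += [0.0, 0.2]
        assert bending_energy(bem, target) > 0

    def test_psd_and_affine_annihilation(self, base_outline):
        bem = bending_energy_matrix(base_outline)
        M = bem.matrix
        np.testing.assert_allclose(M, M.T, atol=1e-12)
        assert np.linalg.eigvalsh(M).min() > -1e-9
        k = base_outline.shape[0]
        for vec in (np.ones(k), base_outline[:, 0], base_outline[:, 1]):
            np.testing.assert_allclose(M @ vec, 0, atol=1e-9)

    def test_matches_bruteforce_block_inverse(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            ref = rng.random((8, 2)) * 3
            bem = bending_energy_matrix(ref)
            k = 8
            diff = ref[:, None] - ref[None]
            r2 = (diff**2).sum(-1)
            K = np.where(r2 > 0, r2 * np.log(np.where(r2 > 0, r2, 1.0)), 0.0)
            Q = np.column_stack([np.ones(k), ref])
            L = np.block([[K, Q], [Q.T, np.zeros((3, 3))]])
            expected = np.linalg.inv(L)[:k, :k]
            np.testing.assert_allclose(
                bem.matrix, 0.5 * (expected + expected.T), atol=1e-9
            )

    def test_coincident_landmarks_rejected(self):
        ref = np.array([[0, 0], [0, 0], [1, 1], [2, 0]], dtype=float)
        with pytest.raises(DegenerateShapeError):
            bending_energy_matrix(ref)


class TestSliding:
    def test_identical_shapes_are_a_fixed_point(self, base_outline, scheme):
        shapes = [base_outline.copy() for _ in range(5)]
        sample = gpa(shapes)
        slid = slide_semilandmarks(sample, scheme)
        np.testing.assert_allclose(slid.aligned, sample.aligned, atol=1e-9)
        assert len(slid.slide_log) == 1

    def test_straight_segment_sliders_stay_on_line(self):
        # square with a slider at the midpoint of the bottom edge
        ref = np.array(
            [[0, 0], [1, 0], [2, 0], [2, 2], [0, 2]], dtype=float
        )
        scheme = LandmarkScheme(n_landmarks=5, slider_triples=((0, 1, 2),))
        shapes = [ref.copy() for _ in range(3)]
        shapes[1] = ref.copy()
        shapes[1][1, 0] = 0.7  # slid along the same edge
        sample = gpa(shapes)
        slid = slide_semilandmarks(sample, scheme)
        # the slider stays on the (aligned) line through its neighbors
        for spec in slid.aligned:
            chord = spec[2] - spec[0]
            offset = spec[1] - spec[0]
            cross = chord[0] * offset[1] - chord[1] * offset[0]
            assert abs(cross) < 1e-9

    def test_energy_never_increases_within_cycles(self, small_landmark_dataset,
                                                  scheme):
        _, configs, _, _ = small_landmark_dataset
        slid = slide_semilandmarks(gpa(configs), scheme)
        assert slid.slide_log
        for entry in slid.slide_log:
            assert entry["energy_after"] <= entry["energy_before"] + 1e-9

    def test_agrees_with_grid_search_oracle(self):
        # toy 8-landmark case with two sliders; oracle: exhaustive 2-D grid
        # over tangent offsets minimizing the same bending energy
        ref = np.array(
            [[0, 0], [1, 0], [2, 0], [3, 0], [3, 2], [2, 2], [1, 2], [0, 2]],
            dtype=float,
        )
        triples = ((0, 1, 2), (4, 5, 6))
        bem = bending_energy_matrix(ref)
        shape = ref.copy()
        shape[1] += [0.12, 0.0]
        shape[5] += [-0.08, 0.0]
        shape[3] += [0.0, 0.15]  # non-affine fixed-landmark perturbation

        from morphodisp.geometry import _slide_one

        slid = _slide_one(shape, ref, bem.matrix, triples)

        tangents = []
        for b, s, a in triples:
            chord = shape[a] - shape[b]
            tangents.append(chord / np.linalg.norm(chord))
        grid = np.linspace(-0.5, 0.5, 401)
        best, best_e = None, np.inf
        for a1 in grid:
            for a2 in grid:
                trial = shape.copy()
                trial[1] += a1 * tangents[0]
                trial[5] += a2 * tangents[1]
                e = bending_energy(bem, trial)
                if e < best_e:
                    best_e, best = e, (a1, a2)
        np.testing.assert_allclose(slid[1], shape[1] + best[0] * tangents[0],
                                   atol=1e-2)
        np.testing.assert_allclose(slid[5], shape[5] + best[1] * tangents[1],
                                   atol=1e-2)
        assert bending_energy(bem, slid) <= best_e + 1e-4

    def test_fixed_landmarks_only_move_through_superimposition(
        self, small_landmark_dataset, scheme
    ):
        _, configs, _, _ = small_landmark_dataset
        sample = gpa(configs)
        slid = slide_semilandmarks(sample, scheme)
        # Procrustes-fit each slid specimen back onto its unslid self: fixed
        # landmarks should match far better than sliders moved
        fixed = list(scheme.fixed_indices)
        for i in range(0, sample.n_specimens, 37):
            a = optimal_rotation(slid.aligned[i], sample.aligned[i])
            residual = np.linalg.norm(a[fixed] - sample.aligned[i][fixed])
            assert residual < 0.05


class TestProcrustesDistance:
    def test_identical_shapes_zero(self, small_aligned):
        assert procrustes_distance(
            small_aligned.aligned[0], small_aligned.aligned[0]
        ) == 0.0

    def test_single_landmark_offset_hand_value(self):
        a = np.zeros((4, 2))
        b = np.zeros((4, 2))
        b[2] = [0.3, 0.4]
        assert procrustes_distance(a, b) == pytest.approx(0.5)

    def test_metric_axioms_on_sample(self, small_aligned):
        D = pairwise_distances(small_aligned)
        np.testing.assert_allclose(D, D.T, atol=1e-12)
        assert np.all(np.diag(D) == 0)
        n = min(12, D.shape[0])
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert D[i, k] <= D[i, j] + D[j, k] + 1e-12

    def test_pairwise_method_never_exceeds_common_frame(self, small_aligned):
        a, b = small_aligned.aligned[0], small_aligned.aligned[1]
        assert procrustes_distance(a, b, "pairwise") <= procrustes_distance(
            a, b, "common"
        ) + 1e-12

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            procrustes_distance(np.zeros((4, 2)), np.zeros((5, 2)))
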