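import numpy as np
import pytest

from morphodisp.binning import assign_bins
from morphodisp.geometry import gpa
from morphodisp.disparity import sum_of_variances
from morphodisp.ordination import pca
from morphodisp.synthetic import (
    default_body_design,
    default_trait_design,
    fish_outline,
    generate_landmark_dataset,
    generate_null_pair,
    generate_trait_dataset,
    orthonormalize_modes,
    recovery_design,
    write_landmark_dataset,
)


class TestDesigns:
    def test_body_design_matches_study_scale(self):
        design = default_body_design()
        sizes = list(design.per_bin_n.values())
        assert sum(sizes) == 453
        assert design.per_bin_n["middle Permian"] == 5
        assert min(sizes) == 5

    def test_trait_design_matches_study_scale(self):
        design = default_trait_design()
        sizes = list(design.per_bin_n.values())
        assert sum(sizes) == 365
        assert design.per_bin_n["middle Permian"] == 2
        # expected MCAR cell missingness matches the empirical table's rate,
        # concentrated in characters two and five
        rates = np.asarray(design.missing_rates)
        assert np.mean(rates) == pytest.approx(0.172)
        assert rates[1] > 5 * rates[0] and rates[4] > 5 * rates[0]

    def test_modes_orthonormal_and_similarity_free(self):
        design = default_body_design()
        base = fish_outline()
        centered = base - base.mean(axis=0)
        base_norm = centered / np.linalg.norm(centered)
        flat = design.deformation_modes.reshape(len(design.deformation_modes), -1)
        gram = flat @ flat.T
        np.testing.assert_allclose(gram, np.eye(len(flat)), atol=1e-9)
        k = base.shape[0]
        rot90 = np.column_stack([-base_norm[:, 1], base_norm[:, 0]])
        for direction in (
            np.repeat([[1.0, 0.0]], k, axis=0).ravel(),
            np.repeat([[0.0, 1.0]], k, axis=0).ravel(),
            base_norm.ravel(),
            rot90.ravel(),
        ):
            np.testing.assert_allclose(flat @ direction, 0, atol=1e-9)

    def test_mode_inside_similarity_subspace_rejected(self):
        base = fish_outline()
        with pytest.raises(ValueError, match="similarity"):
            orthonormalize_modes(np.repeat([[[1.0, 0.0]]], base.shape[0], axis=1),
                                 base)


class TestLandmarkGenerator:
    def test_deterministic_under_seed(self, tmp_path):
        design = recovery_design(3)
        a = generate_landmark_dataset(design, seed=5)
        b = generate_landmark_dataset(design, seed=5)
        for ca, cb in zip(a[0], b[0]):
            np.testing.assert_array_equal(ca.coords, cb.coords)
        assert a[1] == b[1]
        pa = write_landmark_dataset(tmp_path / "a", *a[:2], design)
        pb = write_landmark_dataset(tmp_path / "b", *b[:2], design)
        assert pa["tps"].read_bytes() == pb["tps"].read_bytes()

    def test_zero_signal_gives_zero_disparity(self):
        design = recovery_design(5)
        design.landmark_noise_sd = 0.0
        design.bin_amplitudes = {
            name: np.zeros(6) for name in design.bins.names
        }
        configs, _, truth = generate_landmark_dataset(design, seed=2)
        sample = gpa(configs)
        scores = pca(sample.aligned.reshape(sample.n_specimens, -1)).scores
        assert sum_of_variances(scores) < 1e-20
        assert all(v == 0 for v in truth["per_bin_variance"].values())

    def test_planted_variance_ratio_recovered(self):
        # one bin's amplitude doubled vs another: estimated variance ratio ~4
        # (sampling SD of a variance ratio at n=400 is ~10%, so 20% is ~2 sigma)
        design = recovery_design(2)
        sigma = 0.02
        design.landmark_noise_sd = 0.0001
        design.per_bin_n = dict(design.per_bin_n, Anisian=400, Norian=400)
        design.bin_amplitudes = {
            name: np.zeros(6) for name in design.bins.names
        }
        design.bin_amplitudes["Anisian"] = sigma * np.eye(6)[0]
        design.bin_amplitudes["Norian"] = 2 * sigma * np.eye(6)[0]
        configs, records, _ = generate_landmark_dataset(design, seed=3)
        sample = gpa(configs)
        scores = pca(sample.aligned.reshape(sample.n_specimens, -1)).scores
        binned = assign_bins(records, design.bins)
        row = {sid: i for i, sid in enumerate(sample.specimen_ids)}
        var_a = sum_of_variances(scores, [row[s] for s in binned["Anisian"]])
        var_b = sum_of_variances(scores, [row[s] for s in binned["Norian"]])
        assert var_b / var_a == pytest.approx(4.0, rel=0.2)

    def test_bins_and_stages_consistent(self):
        design = recovery_design(4)
        _, records, _ = generate_landmark_dataset(design, seed=4)
        binned = assign_bins(records, design.bins)
        assert all(len(v) == 4 for v in binned.members.values())

    def test_planted_ordering_recovered_end_to_end(self, scheme):
        from morphodisp.geometry import slide_semilandmarks

        design = recovery_design(50)
        configs, records, truth = generate_landmark_dataset(design, seed=19)
        sample = slide_semilandmarks(gpa(configs), scheme)
        scores = pca(sample.aligned.reshape(sample.n_specimens, -1)).scores
        binned = assign_bins(records, design.bins)
        row = {sid: i for i, sid in enumerate(sample.specimen_ids)}
        est = [
            sum_of_variances(scores, [row[s] for s in binned[name]])
            for name in design.bins.names
        ]
        planted = [truth["per_bin_variance"][name] for name in design.bins.names]
        assert np.argsort(est).tolist() == np.argsort(planted).tolist()

    def test_too_small_bin_rejected(self):
        design = recovery_design(3)
        design.per_bin_n["Anisian"] = 1
        with pytest.raises(ValueError, match="Anisian"):
            generate_landmark_dataset(design, seed=0)


class TestTraitGenerator:
    def test_missingness_matches_expectation(self):
        design = default_trait_design()
        design.per_bin_n = {name: 60 for name in design.bins.names}  # 1020 rows
        traits, _, truth = generate_trait_dataset(design, seed=6)
        observed = traits.isna().to_numpy().mean()
        assert observed == pytest.approx(truth["expected_missingness"], abs=0.02)

    def test_missingness_concentrated_in_chars_two_and_five(self):
        design = default_trait_design()
        traits, _, _ = generate_trait_dataset(design, seed=7)
        per_char = traits.isna().mean()
        assert per_char["char2"] > 0.25 and per_char["char5"] > 0.35
        assert per_char["char1"] < 0.08

    def test_all_present_values_positive(self):
        traits, _, _ = generate_trait_dataset(default_trait_design(), seed=8)
        assert (traits.stack() > 0).all()

    def test_separated_clusters_detected_by_centroid_test(self):
        from morphodisp.inference import centroid_shift_test

        design = default_trait_design()
        traits, records, _ = generate_trait_dataset(design, seed=9)
        record_of = {r.specimen_id: r for r in records}
        complete = traits.dropna()
        labels = np.array([record_of[s].infraclass for s in complete.index])
        holo = np.nonzero(labels == "Holostei")[0][:50]
        chon = np.nonzero(labels == "Chondrostei")[0][:50]
        res = centroid_shift_test(complete.to_numpy(), holo, chon,
                                  n_permutations=999, seed=0)
        assert res.p_value <= 0.001


class TestNullPair:
    def test_exchangeable_and_seeded(self):
        a1, b1 = generate_null_pair(10, 12, 4, seed=3)
        a2, b2 = generate_null_pair(10, 12, 4, seed=3)
        np.testing.assert_array_equal(a1, a2)
        np.testing.assert_array_equal(b1, b2)
        assert a1.shape == (10, 4) and b1.shape == (12, 4)

    def test_minimum_group_size(self):
        with pytest.raises(ValueError):
            generate_null_pair(1, 5, 2, seed=0)
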