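"""Generator contracts: schedules, image banks, features and the simulator."""

import numpy as np
import pandas as pd
import pytest

from shrewhier.synthetic import (
    GroundTruthNeuron,
    Session,
    extract_features,
    make_grating_schedule,
    make_image_schedule,
    make_object_bank,
    make_sparse_noise_schedule,
    make_texture_bank,
    simulate_response_tensor,
    simulate_session,
)


class TestSparseNoise:
    def test_frame_counts_and_polarity_balance(self):
        frames = make_sparse_noise_schedule(grid_shape=(4, 3), n_frames=100, seed=0)
        assert len(frames) == 100
        assert all(len(f.dot_positions) == 12 for f in frames)
        assert sum(f.polarity == "white" for f in frames) == 50

    def test_default_dot_and_frame_timing(self):
        frames = make_sparse_noise_schedule(n_frames=10, seed=0)
        assert frames[0].dot_size_deg == 5.0
        assert frames[0].duration_s == 0.1
        assert frames[1].onset_s - frames[0].onset_s == pytest.approx(0.1)

    def test_determinism_and_seed_sensitivity(self):
        a = make_sparse_noise_schedule(n_frames=20, seed=7)
        b = make_sparse_noise_schedule(n_frames=20, seed=7)
        c = make_sparse_noise_schedule(n_frames=20, seed=8)
        assert a == b
        assert a != c

    def test_dot_positions_on_lattice_inside_cells(self):
        frames = make_sparse_noise_schedule(n_frames=4, lattice_shape=(32, 18), seed=0)
        pos = np.array([p for f in frames for p in f.dot_positions])
        assert np.all(np.abs(pos[:, 0]) <= 54) and np.all(np.abs(pos[:, 1]) <= 38)
        # 12 dots per frame, one per scheduling cell
        for f in frames:
            cols = np.digitize([p[0] for p in f.dot_positions], np.linspace(-54, 54, 5)) - 1
            rows = np.digitize([p[1] for p in f.dot_positions], np.linspace(-38, 38, 4)) - 1
            assert len({(c, r) for c, r in zip(cols, rows)}) == 12

    def test_invalid_configurations(self):
        with pytest.raises(ValueError, match="does not fit"):
            make_sparse_noise_schedule(dot_size_deg=30.0, n_frames=10)
        with pytest.raises(ValueError, match="even"):
            make_sparse_noise_schedule(n_frames=11)


class TestGratings:
    def test_default_condition_cardinality(self):
        conds, events = make_grating_schedule(seed=0)
        assert len(conds) == 120  # 6 orientations x 5 SFs x 4 phases
        assert len(events) == 120 * 5

    def test_minimal_grid(self):
        conds, _ = make_grating_schedule(1, [0.5], 1, 1, seed=0)
        assert len(conds) == 1

    def test_shuffle_is_permutation_of_condition_multiset(self):
        _, ev_a = make_grating_schedule(n_repeats=3, seed=1)
        _, ev_b = make_grating_schedule(n_repeats=3, seed=2)
        assert sorted(ev_a["stim_id"]) == sorted(ev_b["stim_id"])
        assert not ev_a["stim_id"].equals(ev_b["stim_id"])

    def test_sf_range_and_errors(self):
        _, ev = make_grating_schedule(seed=0)
        assert ev["spatial_frequency"].min() == pytest.approx(0.1)
        assert ev["spatial_frequency"].max() == pytest.approx(1.6)
        with pytest.raises(ValueError):
            make_grating_schedule(n_repeats=0)


class TestTextureBank:
    def test_default_set_size(self, texture_bank):
        assert len(texture_bank) == 150  # 15 families x 5 samples + matched noise

    def test_amplitude_spectra_match(self, texture_bank):
        tex = np.flatnonzero(texture_bank.category == "texture")[:10]
        for i in tex:
            j = texture_bank.index_of(int(texture_bank.partner_id[i]))
            a = np.abs(np.fft.fft2(texture_bank.pixels[i]))
            b = np.abs(np.fft.fft2(texture_bank.pixels[j]))
            assert np.max(np.abs(a - b) / (np.abs(a) + 1e-12)) < 1e-6

    def test_within_family_correlation_exceeds_across(self, texture_bank):
        tex = texture_bank.category == "texture"
        pix = texture_bank.pixels[tex].reshape(tex.sum(), -1)
        fam = texture_bank.family[tex]
        c = np.corrcoef(pix)
        same = fam[:, None] == fam[None, :]
        off = ~np.eye(len(fam), dtype=bool)
        assert c[same & off].mean() > c[~same].mean()

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            make_texture_bank(2, 2, (8, 8))
        with pytest.raises(ValueError):
            make_texture_bank(2, 2, (32, 48))


class TestObjectBank:
    def test_no_faces_option(self):
        bank = make_object_bank(10, 0, (32, 32), seed=0)
        assert "face" not in set(bank.category)

    def test_faces_cluster_in_feature_space(self, small_object_bank, small_features):
        f = small_features.pc_scores
        is_face = small_object_bank.category == "face"
        faces, objs = f[is_face], f[~is_face]

        def mean_dist(a, b):
            return np.mean(np.linalg.norm(a[:, None, :] - b[None, :50, :], axis=2))

        within = np.mean(
            [np.linalg.norm(faces[i] - faces[j]) for i in range(20) for j in range(i + 1, 20)]
        )
        across = mean_dist(faces[:20], objs)
        assert within < across


class TestFeatures:
    def test_pc_basis_orthonormal(self, small_features):
        g = small_features.pc_basis.T @ small_features.pc_basis
        assert np.abs(g - np.eye(small_features.n_pcs)).max() < 1e-8

    def test_scores_consistent_with_basis(self, small_features):
        recon = (small_features.features - small_features.pc_mean) @ small_features.pc_basis
        assert np.allclose(recon, small_features.pc_scores)

    def test_pca_reconstruction_error_bound(self, small_features):
        x = small_features.features - small_features.pc_mean
        approx = small_features.pc_scores @ small_features.pc_basis.T
        err = ((x - approx) ** 2).sum()
        total = (x**2).sum()
        top = (small_features.pc_scores**2).sum()
        assert err == pytest.approx(total - top, rel=1e-8)

    def test_determinism(self, small_object_bank):
        a = extract_features(small_object_bank, layers=(2,), n_pcs=10, out_dim=64, seed=5)
        b = extract_features(small_object_bank, layers=(2,), n_pcs=10, out_dim=64, seed=5)
        assert np.array_equal(a["layer2"].features, b["layer2"].features)
        assert np.array_equal(a["layer2"].pc_scores, b["layer2"].pc_scores)

    def test_unknown_extractor_lists_plugins(self, small_object_bank):
        with pytest.raises(ValueError, match="builtin-gabor-random"):
            extract_features(small_object_bank, extractor="alexnet")


class TestSimulator:
    def test_constant_rate_neuron_matches_baseline(self):
        n = GroundTruthNeuron(
            unit_id=0, area="V1", baseline_rate=5.0, rf_polarity="none",
            axis_true=np.ones(50), axis_gain=0.0, object_base_gain=0.0,
        )
        tensor = simulate_response_tensor([n], np.random.default_rng(0).standard_normal((200, 50)),
                                          n_repeats=10, seed=1)
        mean = tensor.mean()
        se = tensor.std() / np.sqrt(tensor.size)
        assert abs(mean - 5.0 * 0.1) < 3 * se + 1e-9

    def test_poisson_dispersion(self):
        n = GroundTruthNeuron(
            unit_id=0, area="V1", baseline_rate=20.0, rf_polarity="none",
            axis_true=np.ones(50), axis_gain=0.0, object_base_gain=0.0,
        )
        tensor = simulate_response_tensor([n], np.zeros((250, 50)) + np.random.default_rng(1).standard_normal((250, 50)),
                                          n_repeats=10, seed=2)
        counts = tensor.ravel()  # 2,500 iid Poisson trials
        assert 0.8 < counts.var() / counts.mean() < 1.2

    def test_doubling_gain_doubles_evoked_response(self, small_features):
        rng = np.random.default_rng(3)
        axis = rng.standard_normal(50)
        kw = dict(unit_id=0, area="V2", baseline_rate=0.0, object_base_gain=5.0,
                  axis_true=axis, axis_nonlinearity="rectified")
        t1 = simulate_response_tensor(
            [GroundTruthNeuron(axis_gain=8.0, **kw)], small_features.pc_scores, 34, seed=4
        )
        t2 = simulate_response_tensor(
            [GroundTruthNeuron(axis_gain=16.0, object_base_gain=10.0, **{k: v for k, v in kw.items() if k != "object_base_gain"})],
            small_features.pc_scores, 34, seed=4,
        )
        m1, m2 = t1.mean(), t2.mean()
        se = np.sqrt(t2.var() / t2.size + 4 * t1.var() / t1.size)
        assert abs(m2 - 2 * m1) < 3 * se

    def test_session_determinism(self):
        frames = make_sparse_noise_schedule(n_frames=50, seed=0)
        neurons = [
            GroundTruthNeuron(unit_id=0, area="V1", rf_polarity="ON", rf_center=(5, 5),
                              axis_true=np.ones(50))
        ]
        sess = Session(sparse_noise=frames)
        s1, _, _ = simulate_session(neurons, sess, seed=9)
        s2, _, _ = simulate_session(neurons, sess, seed=9)
        pd.testing.assert_frame_equal(s1, s2)

    def test_events_must_reference_bank_images(self, texture_bank):
        ev = make_image_schedule(np.array([9999]), 2, "texture_noise", seed=0)
        with pytest.raises(ValueError, match="not in bank"):
            Session(texture_events=ev, texture_bank=texture_bank)
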