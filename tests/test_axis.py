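"""Preferred-axis estimation, explainable variance and tuning curves."""

import numpy as np
import pytest
from scipy import stats

from shrewhier.axis import (
    explainable_variance,
    fit_preferred_axis,
    layer_encoding_profile,
    principal_orthogonal_axis,
    rescale_projections,
    tuning_curve,
)
from shrewhier.synthetic import GroundTruthNeuron, extract_features, simulate_response_tensor
from shrewhier.synthetic.simulate import zscored_projection


def _unit_axis(rng, n=50, lead_bias=1.0):
    a = rng.standard_normal(n)
    a[:5] *= lead_bias
    return a / np.linalg.norm(a)


class TestExplainableVariance:
    def test_identical_halves_give_one(self):
        rng = np.random.default_rng(0)
        per_image = rng.random((1, 50, 1))
        tensor = np.repeat(per_image, 4, axis=2)
        r = explainable_variance(tensor)[0]
        assert r.rho == pytest.approx(1.0)
        assert r.explainable == pytest.approx(1.0)

    def test_spearman_brown_algebra(self):
        # rho = 1/3 -> 2*(1/3)/(4/3) = 0.5; verified against the closed form
        # on a constructed tensor whose halves correlate at exactly 1/3
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([2.0, 1.0, 3.0])  # corr(x, y) = 0.5 -> pick to taste
        rho = np.corrcoef(x, y)[0, 1]
        tensor = np.stack([x, y], axis=1)[None, :, :]
        r = explainable_variance(tensor)[0]
        assert r.rho == pytest.approx(rho)
        assert r.explainable == pytest.approx(2 * rho / (1 + rho))

    def test_negative_reliability_clamped_with_audit_trail(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        tensor = np.stack([x, -x], axis=1)[None, :, :]
        r = explainable_variance(tensor)[0]
        assert r.explainable == 0.0
        assert r.raw_explainable < 0 and r.clamped

    def test_half_relabelling_invariance(self):
        rng = np.random.default_rng(1)
        tensor = rng.poisson(5.0, (3, 40, 4)).astype(float)
        a = explainable_variance(tensor)
        swapped = tensor[:, :, [1, 0, 3, 2]]  # swap halves
        b = explainable_variance(swapped)
        for ra, rb in zip(a, b):
            assert ra.rho == pytest.approx(rb.rho)

    def test_signal_fraction_recovery(self):
        # Spearman-Brown estimates the signal fraction of the repeat-averaged
        # response: with per-trial noise variance n_repeats*(1-s)/s relative
        # to signal variance s, that fraction is exactly s
        rng = np.random.default_rng(2)
        s = 0.6
        n_images, n_repeats, n_sims = 400, 10, 30
        est = []
        for _ in range(n_sims):
            signal = rng.standard_normal(n_images) * np.sqrt(s)
            noise = rng.standard_normal((n_images, n_repeats)) * np.sqrt(n_repeats * (1 - s))
            tensor = (signal[:, None] + noise)[None, :, :]
            est.append(explainable_variance(tensor)[0].explainable)
        assert abs(np.mean(est) - s) < 0.05

    def test_requires_two_repeats(self):
        with pytest.raises(ValueError):
            explainable_variance(np.zeros((1, 10, 1)))


class TestPreferredAxis:
    def test_noiseless_linear_cell_exact(self, small_features):
        rng = np.random.default_rng(3)
        beta = _unit_axis(rng)
        y = small_features.pc_scores @ beta
        pa = fit_preferred_axis(y, small_features.pc_scores, seed=0)
        assert abs(pa.axis @ beta) > 1.0 - 1e-10

    def test_noisy_recovery_at_moderate_reliability(self, small_features):
        rng = np.random.default_rng(4)
        cos = []
        for s in range(6):
            axis = _unit_axis(np.random.default_rng(40 + s))
            cell = GroundTruthNeuron(
                unit_id=0, area="V2", baseline_rate=3.0, object_base_gain=8.0,
                axis_true=axis, axis_gain=6.0, axis_nonlinearity="linear",
            )
            tensor = simulate_response_tensor([cell], small_features.pc_scores, 10, seed=50 + s)
            pa = fit_preferred_axis(tensor.mean(axis=2)[0], small_features.pc_scores, seed=0)
            cos.append(abs(pa.axis @ axis))
        assert np.median(cos) > 0.85  # 300 images; tightens with the full bank

    def test_feature_independent_cell_has_zero_ev(self, small_features):
        rng = np.random.default_rng(5)
        evs = [
            fit_preferred_axis(
                rng.poisson(5.0, small_features.pc_scores.shape[0]).astype(float),
                small_features.pc_scores,
                seed=s,
            ).ev_cv
            for s in range(40)
        ]
        assert abs(np.mean(evs)) < 0.02

    def test_rotation_equivariance(self, small_features):
        rng = np.random.default_rng(6)
        y = rng.poisson(6.0, small_features.pc_scores.shape[0]).astype(float)
        q, _ = np.linalg.qr(rng.standard_normal((50, 50)))
        pa = fit_preferred_axis(y, small_features.pc_scores, seed=1)
        pa_rot = fit_preferred_axis(y, small_features.pc_scores @ q, seed=1)
        assert np.allclose(q @ pa_rot.axis, pa.axis, atol=1e-8)

    def test_ev_cv_cannot_beat_reliability(self, small_features):
        rng = np.random.default_rng(7)
        margins = []
        for s in range(20):
            axis = _unit_axis(np.random.default_rng(70 + s))
            cell = GroundTruthNeuron(
                unit_id=0, area="V2", baseline_rate=3.0, object_base_gain=6.0,
                axis_true=axis, axis_gain=5.0, axis_nonlinearity="linear",
            )
            tensor = simulate_response_tensor([cell], small_features.pc_scores, 10, seed=90 + s)
            rel = explainable_variance(tensor)[0].explainable
            pa = fit_preferred_axis(tensor.mean(axis=2)[0], small_features.pc_scores, seed=0)
            margins.append(pa.ev_cv - rel)
        assert np.mean(margins) < 0.05

    def test_needs_hundred_images(self):
        with pytest.raises(ValueError):
            fit_preferred_axis(np.ones(50), np.ones((50, 10)))


class TestPrincipalOrthogonalAxis:
    def test_e2_gives_e1(self):
        a = np.zeros(50)
        a[1] = 1.0
        o = principal_orthogonal_axis(a)
        assert o[0] == pytest.approx(1.0)

    def test_always_orthogonal(self):
        for s in range(10):
            a = _unit_axis(np.random.default_rng(s))
            o = principal_orthogonal_axis(a)
            assert abs(o @ a) < 1e-12
            assert np.linalg.norm(o) == pytest.approx(1.0)

    def test_parallel_axis_falls_back_to_e2(self):
        a = np.zeros(50)
        a[0] = 1.0
        o = principal_orthogonal_axis(a)
        assert o[1] == pytest.approx(1.0)

    def test_ramp_cell_flat_along_orthogonal_axis(self, small_features):
        axis = _unit_axis(np.random.default_rng(11))
        cell = GroundTruthNeuron(
            unit_id=0, area="V2", baseline_rate=3.0, object_base_gain=8.0,
            axis_true=axis, axis_gain=10.0,
        )
        tensor = simulate_response_tensor([cell], small_features.pc_scores, 10, seed=12)
        y = tensor.mean(axis=2)[0]
        o = principal_orthogonal_axis(axis)
        proj = small_features.pc_scores @ o
        slope, _, _, _, se = stats.linregress(proj, y)[:2] + stats.linregress(proj, y)[2:]
        res = stats.linregress(proj, y)
        assert abs(res.slope) < 3 * res.stderr


class TestTuningCurve:
    def test_rescaling_covers_98_percent(self, small_features):
        proj = small_features.pc_scores[:, 0]
        scaled, lo, hi = rescale_projections(proj)
        frac = np.mean((scaled >= -1) & (scaled <= 1))
        assert abs(frac - 0.98) <= 2.0 / len(proj)

    def test_linear_cell_monotone_bins(self, small_features):
        axis = _unit_axis(np.random.default_rng(13))
        z = zscored_projection(small_features.pc_scores, axis)
        y = 3.0 + 2.0 * z + np.random.default_rng(14).normal(0, 0.3, z.size)
        curve = tuning_curve(y, small_features.pc_scores @ axis)
        ok = np.isfinite(curve.bin_means)
        rho, _ = stats.spearmanr(np.arange(curve.bin_means.size)[ok], curve.bin_means[ok])
        assert rho > 0.9

    def test_shuffled_responses_flat(self, small_features):
        axis = _unit_axis(np.random.default_rng(15))
        rng = np.random.default_rng(16)
        y = rng.permutation(small_features.pc_scores @ axis)
        curve = tuning_curve(y, small_features.pc_scores @ axis)
        ok = np.isfinite(curve.bin_means)
        rho, _ = stats.spearmanr(np.arange(curve.bin_means.size)[ok], curve.bin_means[ok])
        assert abs(rho) < 0.5

    def test_empty_bins_are_nan(self):
        proj = np.concatenate([np.zeros(60), np.ones(40) * 10])
        y = np.ones(100)
        curve = tuning_curve(y, proj, n_bins=16)
        assert np.isnan(curve.bin_means).any()
        assert np.nansum(curve.bin_counts) == 100


class TestLayerEncodingProfile:
    def test_generating_layer_is_modal_best(self, small_object_bank):
        banks = extract_features(small_object_bank, layers=(2, 3, 4), n_pcs=30, out_dim=256, seed=20)
        rng = np.random.default_rng(21)
        n_cells = 10
        resp = []
        for c in range(n_cells):
            axis = _unit_axis(np.random.default_rng(200 + c), n=30)
            z = zscored_projection(banks["layer3"].pc_scores, axis)
            lam = np.maximum(3.0 + 5.0 * z, 0.0)
            resp.append(rng.poisson(np.maximum(lam, 0.01) * 10) / 10.0)
        resp = np.asarray(resp)
        prof = layer_encoding_profile(resp, banks, np.ones(n_cells), n_folds=5)
        counts = np.bincount(prof.best_layer, minlength=3)
        assert prof.layer_names[np.argmax(counts)] == "layer3"

    def test_noise_cells_profile_near_zero(self, small_object_bank):
        banks = extract_features(small_object_bank, layers=(2, 3), n_pcs=20, out_dim=128, seed=22)
        rng = np.random.default_rng(23)
        resp = rng.poisson(5.0, (6, len(small_object_bank))).astype(float)
        prof = layer_encoding_profile(resp, banks, np.ones(6), n_folds=5)
        assert np.all(prof.normalized < 0.05)
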