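"""Orientation/SF tuning fits, variance decomposition and texture modulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shrewhier.tuning import (
    area_variance_explained,
    circular_orientation_error,
    fit_orientation,
    fit_spatial_frequency,
    texture_divergence,
    texture_family_variance_timecourse,
    variance_explained_categorical,
)

ORIS = np.repeat(np.arange(6) * 30.0, 5)
SFS = np.repeat(np.geomspace(0.1, 1.6, 5), 6)


def _vm(theta_deg, theta_pref, kappa, a=10.0, b=2.0):
    t = np.deg2rad(theta_deg)
    return b + a * np.exp(kappa * (np.cos(2 * (t - np.deg2rad(theta_pref))) - 1))


class TestOrientation:
    def test_recovery_with_poisson_noise(self):
        hits = 0
        n_runs = 25
        for s in range(n_runs):
            rng = np.random.default_rng(s)
            r = rng.poisson(_vm(ORIS, 60.0, 2.0))
            fit = fit_orientation(ORIS, r)
            if circular_orientation_error(fit.theta_pref, 60.0) <= 10.0:
                hits += 1
        assert hits >= 0.9 * n_runs  # >= 90% within 10 degrees

    def test_wraparound_uses_circular_metric(self):
        rng = np.random.default_rng(4)
        r = rng.poisson(_vm(ORIS, 170.0, 3.0, a=20.0))
        fit = fit_orientation(ORIS, r)
        assert circular_orientation_error(fit.theta_pref, 170.0) <= 15.0
        assert circular_orientation_error(-10.0, 170.0) == 0.0

    def test_uniform_responses_not_included(self):
        fit = fit_orientation(ORIS, np.full_like(ORIS, 5.0))
        assert fit.amplitude == 0.0 and not fit.included

    def test_requires_four_orientations(self):
        with pytest.raises(ValueError):
            fit_orientation(np.repeat([0.0, 90.0], 5), np.ones(10))


class TestSpatialFrequency:
    def _logg(self, f, f0, sig=0.6, a=10.0, b=2.0):
        return b + a * np.exp(-((np.log(f) - np.log(f0)) ** 2) / (2 * sig**2))

    def test_recovery_within_half_octave(self):
        hits = 0
        n_runs = 25
        for s in range(n_runs):
            rng = np.random.default_rng(100 + s)
            r = rng.poisson(self._logg(SFS, 0.4))
            fit = fit_spatial_frequency(SFS, r)
            if abs(np.log2(fit.f_pref / 0.4)) <= 0.5:
                hits += 1
        assert hits >= 0.9 * n_runs

    def test_flat_not_included(self):
        fit = fit_spatial_frequency(SFS, np.full_like(SFS, 3.0))
        assert not fit.included

    def test_amplitude_scales_f_pref_invariant(self):
        rng = np.random.default_rng(7)
        r = self._logg(SFS, 0.4) + rng.normal(0, 0.1, SFS.size)
        f1 = fit_spatial_frequency(SFS, r)
        f2 = fit_spatial_frequency(SFS, 2 * r)
        assert f2.amplitude == pytest.approx(2 * f1.amplitude, rel=1e-3)
        assert f2.f_pref == pytest.approx(f1.f_pref, rel=1e-3)

    def test_monotone_response_flagged_unbounded(self):
        r = np.log(SFS) * 5 + 20  # strictly increasing over the range
        fit = fit_spatial_frequency(SFS, r)
        assert fit.unbounded
        assert SFS.min() <= fit.f_pref <= SFS.max()


class TestVarianceDecomposition:
    def test_worked_two_level_table(self):
        # {A: 1,3; B: 5,7}: V_total = 5 (population), V_residual = 1 -> 80%
        d = variance_explained_categorical(
            np.array([1.0, 3.0, 5.0, 7.0]), np.array(["A", "A", "B", "B"])
        )
        assert d.v_total == pytest.approx(5.0)
        assert d.v_residual == pytest.approx(1.0)
        assert d.pct_explained == pytest.approx(80.0)

    def test_pure_level_structure_gives_100(self):
        d = variance_explained_categorical(
            np.array([2.0, 2.0, 9.0, 9.0]), np.array([0, 0, 1, 1])
        )
        assert d.pct_explained == pytest.approx(100.0)

    def test_shuffle_matches_anova_dof_inflation(self):
        # with labels random, E[pct] ~= 100*(k-1)/(n-1)
        rng = np.random.default_rng(0)
        n, k = 60, 6
        labels = np.repeat(np.arange(k), n // k)
        pcts = []
        for _ in range(1000):
            r = rng.standard_normal(n)
            pcts.append(variance_explained_categorical(r, labels).pct_explained)
        expected = 100.0 * (k - 1) / (n - 1)
        assert np.mean(pcts) == pytest.approx(expected, abs=1.0)

    @given(a=st.floats(0.1, 10.0), b=st.floats(-5.0, 5.0))
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance(self, a, b):
        r = np.array([1.0, 3.0, 5.0, 7.0, 2.0, 8.0])
        labels = np.array([0, 0, 1, 1, 2, 2])
        p1 = variance_explained_categorical(r, labels).pct_explained
        p2 = variance_explained_categorical(a * r + b, labels).pct_explained
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_area_scope_is_weighted_mean(self):
        rng = np.random.default_rng(1)
        labels = np.repeat(np.arange(3), 4)
        cells = [variance_explained_categorical(rng.standard_normal(12) + 2.0, labels)
                 for _ in range(5)]
        area = area_variance_explained(cells)
        pcts = [c.pct_explained for c in cells]
        assert min(pcts) <= area.pct_explained <= max(pcts)
        assert area.v_total == pytest.approx(sum(c.v_total for c in cells))

    def test_degenerate_total_variance_is_nan(self):
        d = variance_explained_categorical(np.zeros(4), np.array([0, 0, 1, 1]))
        assert np.isnan(d.pct_explained)


class TestTextureDivergence:
    TIME = np.arange(0.0, 0.16, 0.01)

    def _rates(self, rng, n_cells, tex_extra=0.0, onset=0.05):
        base = rng.uniform(5, 15, n_cells)[:, None] + rng.normal(0, 1, (n_cells, len(self.TIME)))
        noise = base + rng.normal(0, 1, base.shape)
        tex = base + rng.normal(0, 1, base.shape)
        tex[:, self.TIME >= onset] += tex_extra
        return tex, noise

    def test_modulated_population_latency_at_onset(self):
        rng = np.random.default_rng(2)
        tex, noi = self._rates(rng, 30, tex_extra=5.0, onset=0.05)
        div = texture_divergence(tex, noi, self.TIME)
        assert div.divergence_latency == pytest.approx(0.05, abs=0.011)

    def test_area_latency_ordering_recovered(self):
        # V2-like modulation at 45 ms, V1-like at 90 ms
        rng = np.random.default_rng(3)
        tex2, noi2 = self._rates(rng, 30, tex_extra=6.0, onset=0.045)
        tex1, noi1 = self._rates(rng, 30, tex_extra=6.0, onset=0.090)
        lat2 = texture_divergence(tex2, noi2, self.TIME, area="V2").divergence_latency
        lat1 = texture_divergence(tex1, noi1, self.TIME, area="V1").divergence_latency
        assert lat2 < lat1

    def test_sign_flip_still_diverges(self):
        rng = np.random.default_rng(4)
        tex, noi = self._rates(rng, 30, tex_extra=-5.0, onset=0.05)
        div = texture_divergence(tex, noi, self.TIME)
        assert div.divergence_latency is not None

    def test_null_false_positive_rate(self):
        # per-bin alpha=0.01 with no correction -> family-wise nominal rate
        # 1 - 0.99**n_bins; the observed any-bin rate must respect it
        hits = 0
        n_runs = 200
        for s in range(n_runs):
            rng = np.random.default_rng(500 + s)
            tex, noi = self._rates(rng, 20, tex_extra=0.0)
            if texture_divergence(tex, noi, self.TIME).divergence_latency is not None:
                hits += 1
        nominal = 1 - 0.99 ** len(self.TIME)
        assert hits <= n_runs * nominal + 3 * np.sqrt(n_runs * nominal * (1 - nominal))

    def test_requires_ten_cells(self):
        with pytest.raises(ValueError):
            texture_divergence(np.ones((5, 16)), np.ones((5, 16)), self.TIME)


class TestFamilyVarianceTimecourse:
    def test_family_coding_rises_after_latency(self):
        rng = np.random.default_rng(6)
        n_cells, n_trials, n_bins = 12, 150, 12
        fams = np.repeat(np.arange(15), 10)
        fam_gain = rng.normal(0, 2, (n_cells, 15))
        rates = rng.normal(10, 1, (n_cells, n_trials, n_bins))
        late = np.arange(n_bins) >= 5
        rates[:, :, late] += fam_gain[:, fams][:, :, None]
        pct = texture_family_variance_timecourse(rates, fams, np.arange(n_bins) * 0.01)
        # early bins sit at the degrees-of-freedom floor (~9%), late bins
        # carry genuine family signal
        assert pct[late].mean() > pct[~late].mean() + 20.0

    def test_label_shuffle_sits_at_dof_floor(self):
        rng = np.random.default_rng(7)
        rates = rng.normal(10, 1, (10, 45, 6))
        fams = np.repeat(np.arange(15), 3)
        pct = texture_family_variance_timecourse(rates, fams, np.arange(6) * 0.01)
        floor = 100.0 * 14 / 44  # (k-1)/(n-1)
        assert abs(pct.mean() - floor) < 10.0

    def test_single_family_undefined(self):
        rates = np.random.default_rng(8).normal(10, 1, (10, 6, 4))
        pct = texture_family_variance_timecourse(rates, np.zeros(6, dtype=int), np.arange(4) * 0.01)
        assert np.isnan(pct).all()
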