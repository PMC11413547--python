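"""Unit and property tests for the continuous-wavelet machinery."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra.numpy import arrays

from affsync import wavelet_core as wc
from _oracles import direct_cwt


class TestPercentileTransform:
    def test_distinct_values_give_rank_over_n(self):
        np.testing.assert_allclose(
            wc.percentile_transform(np.array([1.0, 2.0, 3.0, 4.0])),
            [0.25, 0.5, 0.75, 1.0],
        )

    def test_ties_get_average_ranks(self):
        out = wc.percentile_transform(np.full(5, 3.7))
        assert np.all(out == out[0])

    @given(
        arrays(
            float,
            st.integers(5, 60),
            elements=st.floats(-1e6, 1e6, allow_nan=False, width=64),
        ).filter(lambda a: len(np.unique(a)) == len(a))
    )
    def test_rank_order_preserved(self, x):
        out = wc.percentile_transform(x)
        assert np.array_equal(np.argsort(out), np.argsort(x))

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            wc.percentile_transform(np.array([1.0, np.nan, 2.0]))


class TestMorletCwt:
    def test_zero_vector_gives_zero_coefficients(self):
        sp = wc.morlet_cwt(np.zeros(64))
        assert np.all(sp.coefficients == 0)

    def test_cosine_peak_period_within_one_scale_step(self):
        n = 512
        x = np.cos(2 * np.pi * np.arange(n) / 24.0)
        sp = wc.morlet_cwt(x)
        power = (np.abs(sp.coefficients) ** 2).mean(axis=1)
        peak = sp.grid.periods[np.argmax(power)]
        step = 2 ** sp.grid.dj
        assert 24.0 / step <= peak <= 24.0 * step

    def test_matches_direct_convolution(self, rng):
        x = rng.standard_normal(128)
        scales = np.array([8.0, 16.0, 32.0])
        grid = wc.WaveletGrid(dt=1.0, s0=8.0, dj=1.0, omega0=6.0, scales=scales)
        sp = wc.morlet_cwt(x, grid)
        ref = direct_cwt(x, scales)
        for i in range(3):
            rel = np.max(np.abs(sp.coefficients[i] - ref[i])) / np.max(np.abs(ref[i]))
            assert rel < 1e-8

    def test_white_noise_spectrum_flat(self, rng):
        # time-averaged power, averaged over seeds, should not vary by more
        # than ~3x across the well-sampled middle scales
        n = 256
        grid = wc.WaveletGrid.for_length(n)
        acc = np.zeros(grid.n_scales)
        for _ in range(60):
            sp = wc.morlet_cwt(rng.standard_normal(n), grid)
            rel = wc.reliable_mask(grid, sp.coi)
            pw = np.abs(sp.coefficients) ** 2
            acc += np.array(
                [pw[i][rel[i]].mean() if rel[i].any() else np.nan for i in range(grid.n_scales)]
            )
        mid = acc[4:-12] / 60
        assert np.nanmax(mid) / np.nanmin(mid) < 3.0

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            wc.morlet_cwt(np.ones(4))

    def test_coi_symmetric(self):
        sp = wc.morlet_cwt(np.random.default_rng(0).standard_normal(101))
        np.testing.assert_allclose(sp.coi, sp.coi[::-1])


class TestEstimateAr1:
    def test_white_noise_near_zero(self, rng):
        assert abs(wc.estimate_ar1(rng.standard_normal(4096))) < 0.05

    def test_recovers_phi(self, rng):
        ests = [
            wc.estimate_ar1(wc._ar1_series(rng, 0.7, 4096)) for _ in range(100)
        ]
        assert 0.65 < np.mean(ests) < 0.75

    def test_ramp_clipped(self):
        assert wc.estimate_ar1(np.arange(1000.0), max_abs=0.99) == pytest.approx(0.99)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            wc.estimate_ar1(np.ones(50))


class TestXwt:
    def test_self_cross_spectrum_is_power_with_zero_phase(self, rng):
        sp = wc.morlet_cwt(rng.standard_normal(128))
        cross = wc.xwt(sp, sp)
        np.testing.assert_allclose(cross.power, np.abs(sp.coefficients) ** 2)
        assert np.allclose(cross.phase, 0.0)

    def test_quarter_period_shift_gives_quarter_phase(self):
        n, period = 512, 32
        t = np.arange(n)
        a = np.sin(2 * np.pi * t / period)
        b = np.sin(2 * np.pi * (t - period / 4) / period)  # b delayed => a leads
        sa, sb = wc.morlet_cwt(a), wc.morlet_cwt(b)
        cross = wc.xwt(sa, sb)
        row = np.argmin(np.abs(cross.grid.periods - period))
        mid = slice(n // 4, 3 * n // 4)
        mean_phase = np.angle(np.mean(np.exp(1j * cross.phase[row, mid])))
        assert abs(np.degrees(mean_phase) - 90.0) < 5.0

    def test_grid_mismatch_rejected(self, rng):
        a = wc.morlet_cwt(rng.standard_normal(128))
        b = wc.morlet_cwt(rng.standard_normal(256))
        with pytest.raises(ValueError):
            wc.xwt(a, b)

    def test_independent_inputs_phase_roughly_uniform(self, rng):
        # resultant length of pooled phases over independent pairs is small
        vecs = []
        for _ in range(30):
            sa = wc.morlet_cwt(rng.standard_normal(128))
            sb = wc.morlet_cwt(rng.standard_normal(128))
            cross = wc.xwt(sa, sb)
            rel = wc.reliable_mask(cross.grid, cross.coi)
            vecs.append(np.exp(1j * cross.phase[rel]))
        resultant = np.abs(np.mean(np.concatenate(vecs)))
        assert resultant < 0.1


class TestXwtSignificance:
    def test_tiny_alpha_empties_mask(self, rng):
        sa = wc.morlet_cwt(rng.standard_normal(256))
        sb = wc.morlet_cwt(rng.standard_normal(256))
        cross = wc.xwt(sa, sb)
        mask = wc.xwt_significance(cross, 0.0, 0.0, alpha=1e-12)
        assert mask.mean() < 0.001

    def test_shared_sinusoid_flags_its_band(self, rng):
        n, period = 512, 24
        t = np.arange(n)
        base = np.sin(2 * np.pi * t / period)
        a = base + 0.3 * rng.standard_normal(n)
        b = base + 0.3 * rng.standard_normal(n)
        sa, sb = wc.morlet_cwt(a), wc.morlet_cwt(b)
        cross = wc.xwt(sa, sb)
        mask = wc.xwt_significance(cross, wc.estimate_ar1(a), wc.estimate_ar1(b))
        rel = wc.reliable_mask(cross.grid, cross.coi)
        row = np.argmin(np.abs(cross.grid.periods - period))
        in_band = mask[row][rel[row]]
        assert in_band.mean() > 0.9
        far = np.argmin(np.abs(cross.grid.periods - 6))
        assert mask[far][rel[far]].mean() < 0.3

    def test_alpha_bounds_checked(self, rng):
        sa = wc.morlet_cwt(rng.standard_normal(64))
        cross = wc.xwt(sa, sa)
        with pytest.raises(ValueError):
            wc.xwt_significance(cross, 0.0, 0.0, alpha=1.5)
        with pytest.raises(ValueError):
            wc.xwt_significance(cross, 1.2, 0.0)


class TestSmoothing:
    def test_constant_matrix_unchanged_away_from_edges(self):
        # zero-padding attenuates within a few scales of the series edges,
        # so the identity is checked on the interior of small-scale rows
        grid = wc.WaveletGrid.for_length(128)
        m = np.full((grid.n_scales, 128), 2.5)
        out = wc.smooth_spectrum(m, grid)
        small = grid.scales <= 8.0
        np.testing.assert_allclose(out[small][:, 40:-40], 2.5, rtol=1e-4)
        assert np.all(out <= 2.5 + 1e-9)

    def test_impulse_mass_conserved(self):
        grid = wc.WaveletGrid.for_length(128)
        m = np.zeros((grid.n_scales, 128))
        m[grid.n_scales // 2, 64] = 1.0
        out = wc.smooth_spectrum(m, grid)
        assert out.sum() == pytest.approx(1.0, rel=1e-6)

    def test_smoothing_contracts_variance(self, rng):
        grid = wc.WaveletGrid.for_length(128)
        m = rng.standard_normal((grid.n_scales, 128))
        once = wc.smooth_spectrum(m, grid)
        assert once.var() < m.var()
        twice = wc.smooth_spectrum(once, grid)
        assert twice.var() < once.var()


class TestWtc:
    def test_self_coherence_is_one(self, rng):
        x = rng.standard_normal(256)
        sp = wc.morlet_cwt(x)
        r2 = wc.wtc(sp, sp)
        assert np.max(np.abs(r2 - 1.0)) < 1e-6

    def test_independent_noise_has_low_median_coherence(self, rng):
        sa = wc.morlet_cwt(rng.standard_normal(256))
        sb = wc.morlet_cwt(rng.standard_normal(256))
        r2 = wc.wtc(sa, sb)
        assert np.median(r2) < 0.6

    def test_lagged_copy_stays_coherent_in_band(self, rng):
        n, period = 512, 24
        t = np.arange(n)
        noise = 0.2 * rng.standard_normal((2, n))
        a = np.sin(2 * np.pi * t / period) + noise[0]
        b = np.sin(2 * np.pi * (t - 6) / period) + noise[1]
        sa, sb = wc.morlet_cwt(a), wc.morlet_cwt(b)
        r2 = wc.wtc(sa, sb)
        row = np.argmin(np.abs(sa.grid.periods - period))
        assert np.median(r2[row, n // 4 : 3 * n // 4]) > 0.9


class TestSpectrumSerialization:
    def test_npz_roundtrip(self, tmp_path, rng):
        sp = wc.morlet_cwt(rng.standard_normal(128))
        path = tmp_path / "spec.npz"
        wc.save_spectrum(path, sp)
        back = wc.load_spectrum(path)
        np.testing.assert_array_equal(back.coefficients, sp.coefficients)
        np.testing.assert_array_equal(back.coi, sp.coi)
        assert back.grid.compatible(sp.grid)
        assert back.variance == sp.variance


class TestWtcSignificanceMc:
    def test_critical_values_in_unit_interval(self):
        crit = wc.wtc_significance_mc(0.3, 0.3, 128, nsim=30, seed=1)
        assert np.all((crit > 0) & (crit < 1))

    def test_deterministic_in_seed(self):
        a = wc.wtc_significance_mc(0.3, 0.3, 128, nsim=20, seed=7)
        b = wc.wtc_significance_mc(0.3, 0.3, 128, nsim=20, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_invalid_phi_rejected(self):
        with pytest.raises(ValueError):
            wc.wtc_significance_mc(1.5, 0.3, 128, nsim=20, seed=0)
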