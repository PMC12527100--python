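"""Wavelet back-end: scale grid, Morlet weights, CWT, smoothing, coherence."""
import numpy as np
import pytest

import camon
from camon import InvalidConfiguration
from camon.cwt import _boxcar_scale_smooth, _TimeSmoother

from oracles import direct_cwt


class TestScaleGrid:
    def test_smallest_scale_is_twice_dt(self):
        cfg = camon.CwtConfig(dt=0.01)
        grid = camon.build_scales(cfg, 16384)
        assert grid.scales[0] == pytest.approx(0.02)

    def test_default_grid_has_157_scales(self):
        # J = floor(log2(N dt / s0) / dj) = 156 for N = 16384 at 0.01 s
        grid = camon.build_scales(camon.CwtConfig(), 16384)
        assert grid.n == 157

    def test_pseudo_frequency_of_9p55_seconds_is_0p1_hz(self):
        assert 6.0 / (2 * np.pi * 9.5493) == pytest.approx(0.100, abs=1e-4)
        cfg = camon.CwtConfig()
        grid = camon.build_scales(cfg, 16384)
        j = np.argmin(np.abs(grid.pseudo_freqs - 0.1))
        assert grid.pseudo_freqs[j] == pytest.approx(
            cfg.omega0 / (2 * np.pi * grid.scales[j])
        )

    def test_consecutive_pseudo_freq_ratio_is_one_voice(self):
        grid = camon.build_scales(camon.CwtConfig(), 4096)
        ratios = grid.pseudo_freqs[:-1] / grid.pseudo_freqs[1:]
        np.testing.assert_allclose(ratios, 2 ** (1 / 12), rtol=1e-12)

    def test_scale_frequency_mapping_invertible(self):
        cfg = camon.CwtConfig()
        grid = camon.build_scales(cfg, 4096)
        back = cfg.omega0 / (2 * np.pi * grid.pseudo_freqs)
        np.testing.assert_allclose(back, grid.scales, rtol=1e-12)

    def test_unrepresentable_band_rejected(self):
        # largest grid pseudo-frequency is omega0/(2 pi s0) = 47.7 Hz
        with pytest.raises(InvalidConfiguration):
            camon.build_scales(camon.CwtConfig(band=(48.0, 49.9)), 4096)


class TestMorletFourier:
    def test_zero_at_nonpositive_frequencies(self):
        assert camon.morlet_fourier(1.0, -1.0) == 0.0
        assert camon.morlet_fourier(1.0, 0.0) == 0.0
        assert camon.morlet_fourier(5.0, np.array([-3.0, 0.0, 1e-9]))[2] > 0

    def test_peak_value_is_pi_to_minus_quarter(self):
        for s in (0.1, 2.0, 9.5):
            assert camon.morlet_fourier(s, 6.0 / s) == pytest.approx(
                np.pi**-0.25, rel=1e-12
            )

    def test_gaussian_symmetry_about_center(self):
        s = 3.0
        hi = camon.morlet_fourier(s, (6.0 + 2.0) / s)
        lo = camon.morlet_fourier(s, (6.0 - 2.0) / s)
        assert hi == pytest.approx(lo, rel=1e-12)

    def test_normalization_factor(self):
        s, dt = 2.0, 0.01
        plain = camon.morlet_fourier(s, 6.0 / s)
        normed = camon.morlet_fourier(s, 6.0 / s, dt=dt)
        assert normed == pytest.approx(plain * np.sqrt(2 * np.pi * s / dt))


class TestCwtTransform:
    def test_linearity(self):
        cfg = camon.CwtConfig(dt=0.01, band=(1.0, 5.0))
        grid = camon.build_scales(cfg, 512)
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=512), rng.normal(size=512)
        fx = camon.cwt_fft(x, grid, cfg).coeffs
        fy = camon.cwt_fft(y, grid, cfg).coeffs
        fxy = camon.cwt_fft(x + y, grid, cfg).coeffs
        assert np.abs(fxy - fx - fy).max() < 1e-10 * np.abs(fxy).max()

    def test_zero_signal_gives_zero_field(self):
        cfg = camon.CwtConfig(dt=0.01, band=(1.0, 5.0))
        grid = camon.build_scales(cfg, 256)
        field = camon.cwt_fft(np.zeros(256), grid, cfg)
        assert np.all(field.coeffs == 0)

    def test_ridge_at_tone_frequency(self):
        cfg = camon.CwtConfig(dt=0.01)
        grid = camon.build_scales(cfg, 8192)
        t = np.arange(8192) * 0.01
        field = camon.cwt_fft(np.sin(2 * np.pi * 0.1 * t), grid, cfg)
        center = field.coeffs[:, 4096]
        jmax = np.argmax(np.abs(center))
        # ridge within one voice of 0.1 Hz
        assert abs(np.log2(grid.pseudo_freqs[jmax] / 0.1)) <= 1 / 12 + 1e-9

    def test_matches_time_domain_convolution_oracle(self):
        # quadrature-built analytic Morlet kernel, direct convolution,
        # compared on the central half of a 512-sample signal
        cfg = camon.CwtConfig(dt=0.01, band=(2.0, 8.0))
        rng = np.random.default_rng(2)
        x = rng.normal(size=512)
        scales = np.array([0.12, 0.2, 0.3])
        grid = camon.ScaleGrid(scales, 6.0 / (2 * np.pi * scales), 6.0)
        field = camon.cwt_fft(x, grid, cfg)
        oracle = direct_cwt(x, scales, 6.0, 0.01)
        mid = slice(128, 384)
        rel = np.abs(field.coeffs[:, mid] - oracle[:, mid]).max()
        assert rel / np.abs(oracle[:, mid]).max() < 1e-8

    def test_coi_grows_from_edges(self):
        cfg = camon.CwtConfig(dt=0.01, band=(1.0, 5.0))
        grid = camon.build_scales(cfg, 512)
        field = camon.cwt_fft(np.ones(512), grid, cfg)
        assert field.coi[0] == 0.0
        assert field.coi[200] == pytest.approx(200 * 0.01 / np.sqrt(2))
        d = np.diff(field.coi[:256])
        assert np.all(d > 0)


class TestSmoothing:
    def test_constant_field_preserved(self):
        cfg = camon.CwtConfig(dt=0.01, band=(1.0, 5.0))
        scales = np.array([0.1, 0.2, 0.4, 0.8])
        field = np.full((4, 300), 2.5)
        out = camon.smooth_field(field, scales, cfg)
        np.testing.assert_allclose(out, 2.5, rtol=1e-10)

    def test_time_impulse_becomes_gaussian(self):
        cfg = camon.CwtConfig(dt=0.01, scale_smooth_len=1)
        s = 0.5  # sigma = s/dt = 50 samples
        field = np.zeros((1, 1001))
        field[0, 500] = 1.0
        out = camon.smooth_field(field, np.array([s]), cfg)
        sigma = 50.0
        k = np.arange(1001) - 500
        expected = np.exp(-0.5 * (k / sigma) ** 2)
        expected /= expected.sum()  # interior: kernel normalized to unit sum
        np.testing.assert_allclose(out[0, 350:650], expected[350:650], atol=1e-6)

    def test_scale_impulse_becomes_plateau(self):
        arr = np.zeros((40, 5))
        arr[20, :] = 1.0
        out = _boxcar_scale_smooth(arr, 12)
        col = out[:, 0]
        hits = np.nonzero(col > 0)[0]
        assert len(hits) == 12
        np.testing.assert_allclose(col[hits], 1 / 12)

    def test_complex_smoothing_matches_parts(self):
        sm = _TimeSmoother(200, np.array([10.0, 25.0]))
        rng = np.random.default_rng(1)
        z = rng.normal(size=(2, 200)) + 1j * rng.normal(size=(2, 200))
        out = sm.apply(z)
        np.testing.assert_allclose(out.real, sm.apply(z.real.copy()), atol=1e-12)
        np.testing.assert_allclose(out.imag, sm.apply(z.imag.copy()), atol=1e-12)


class TestWaveletCoherence:
    def _fields(self, x, y, n, cfg):
        grid = camon.build_scales(cfg, n)
        return (camon.cwt_fft(x, grid, cfg), camon.cwt_fft(y, grid, cfg))

    def test_self_coherence_is_one(self, small_cwt_cfg):
        rng = np.random.default_rng(3)
        x = rng.normal(size=2048)
        fx, fy = self._fields(x, x, 2048, small_cwt_cfg)
        wc = camon.wavelet_coherence(fx, fy, small_cwt_cfg)
        power = np.abs(fx.coeffs) > 1e-9 * np.abs(fx.coeffs).max()
        assert np.all(np.abs(wc.coh_sq[power] - 1.0) < 1e-9)
        assert np.all(np.abs(wc.phase[power]) < 1e-9)

    def test_without_smoothing_coherence_degenerates_to_one(self, small_cwt_cfg):
        # |a b*|^2 = |a|^2 |b|^2 pointwise: smoothing is what makes the
        # coherence informative
        rng = np.random.default_rng(4)
        fx, fy = self._fields(
            rng.normal(size=1024), rng.normal(size=1024), 1024, small_cwt_cfg
        )
        wc = camon.wavelet_coherence(fx, fy, small_cwt_cfg, smooth=False)
        power = (np.abs(fx.coeffs) > 1e-12) & (np.abs(fy.coeffs) > 1e-12)
        assert np.all(np.abs(wc.coh_sq[power] - 1.0) < 1e-6)
        wc2 = camon.wavelet_coherence(fx, fy, small_cwt_cfg, smooth=True)
        assert wc2.coh_sq[power].mean() < 0.9

    def test_coherence_bounded(self, small_cwt_cfg):
        rng = np.random.default_rng(5)
        x = rng.normal(size=1024)
        y = 0.5 * x + rng.normal(size=1024)
        fx, fy = self._fields(x, y, 1024, small_cwt_cfg)
        wc = camon.wavelet_coherence(fx, fy, small_cwt_cfg)
        assert np.all(wc.coh_sq <= 1 + 1e-9)
        assert np.all(wc.coh_sq >= 0)

    def test_select_scale_on_tone_within_one_voice(self, coherent_pair):
        cfg = camon.CwtConfig(n_frame=8192)
        grid = camon.build_scales(cfg, 8192)
        x = coherent_pair.bp.values[:8192]
        y = coherent_pair.bfv_left.values[:8192]
        fx = camon.cwt_fft(x, grid, cfg)
        fy = camon.cwt_fft(y, grid, cfg)
        wc = camon.wavelet_coherence(fx, fy, cfg)
        j_max = camon.select_mayer_scale(wc, cfg.band, "max", cfg.threshold)
        j_frac = camon.select_mayer_scale(wc, cfg.band, "fraction", cfg.threshold)
        assert abs(np.log2(grid.pseudo_freqs[j_max] / 0.1)) <= 2 / 12 + 1e-9
        # both criteria agree on a stationary noise-free tone
        assert j_max == j_frac


class TestCwtPsSeries:
    def test_noise_free_pair_recovers_imposed_phase(self, coherent_pair):
        series = camon.cwt_ps_series(coherent_pair)
        assert not series.gated.any()
        assert np.mean(series.phase) == pytest.approx(1.0, abs=0.02)

    def test_backends_agree_on_stationary_pair(self, coherent_pair):
        s = camon.stft_ps_series(coherent_pair)
        c = camon.cwt_ps_series(coherent_pair)
        np.testing.assert_array_equal(s.times, c.times)
        assert abs(np.mean(s.phase) - np.mean(c.phase)) < 0.05

    def test_engine_matches_module_pipeline(self, small_cwt_cfg, noisy_pair):
        cfg = small_cwt_cfg
        x = noisy_pair.bp.values[: cfg.n_frame]
        y = noisy_pair.bfv_left.values[: cfg.n_frame]
        grid = camon.build_scales(cfg, cfg.n_frame)
        wc = camon.wavelet_coherence(
            camon.cwt_fft(x, grid, cfg), camon.cwt_fft(y, grid, cfg), cfg
        )
        j = camon.select_mayer_scale(wc, cfg.band, cfg.scale_criterion, cfg.threshold)
        samp = camon.CwtFrameEngine(cfg).frame_sample(x, y, 0.0)
        assert samp.f_mayer == pytest.approx(grid.pseudo_freqs[j], rel=1e-12)
        valid = wc.valid_mask()[j]
        coh_val = wc.coh_sq[j, valid].mean()
        assert samp.coh_sq == pytest.approx(coh_val, rel=1e-9)

    def test_channel_swap_negates_phase(self, small_cwt_cfg, coherent_pair):
        n = small_cwt_cfg.n_frame
        eng = camon.CwtFrameEngine(small_cwt_cfg)
        x = coherent_pair.bp.values[:n]
        y = coherent_pair.bfv_left.values[:n]
        a = eng.frame_sample(x, y, 0.0)
        b = eng.frame_sample(y, x, 0.0)
        assert a.phase == pytest.approx(-b.phase, abs=1e-9)

    def test_amplitude_scaling_invariance(self, small_cwt_cfg, coherent_pair):
        n = small_cwt_cfg.n_frame
        eng = camon.CwtFrameEngine(small_cwt_cfg)
        x = coherent_pair.bp.values[:n]
        y = coherent_pair.bfv_left.values[:n]
        a = eng.frame_sample(x, y, 0.0)
        b = eng.frame_sample(x, 37.5 * y, 0.0)
        assert a.phase == pytest.approx(b.phase, abs=1e-9)
        assert a.coh_sq == pytest.approx(b.coh_sq, abs=1e-9)

    def test_noise_frame_emits_gated_sample(self):
        cfg = camon.CwtConfig(n_frame=4096)
        rng = np.random.default_rng(6)
        samp = camon.CwtFrameEngine(cfg).frame_sample(
            rng.normal(size=4096), rng.normal(size=4096), 0.0
        )
        assert samp.gated and samp.phase is None
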