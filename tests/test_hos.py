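"""Bispectrum/bicoherence estimators, principal-domain geometry, Hinich tests."""

import numpy as np
import pytest

import hoseeg as h
from hoseeg.hos import _hinich_cells


def naive_direct_bispectrum(segs, nfft):
    """Independent oracle: literal triple-product definition, cell by cell."""
    segs = segs - segs.mean(axis=1, keepdims=True)
    X = np.fft.fft(segs, nfft, axis=1)
    M = nfft // 2 + 1
    B = np.zeros((M, M), complex)
    for i in range(M):
        for j in range(M):
            acc = 0.0
            for k in range(segs.shape[0]):
                acc += X[k, i] * X[k, j] * np.conj(X[k, (i + j) % nfft])
            B[i, j] = acc / segs.shape[0]
    return B


def principal_peak(est):
    domain = h.principal_domain(est.grid)
    mag = np.abs(est.values).copy()
    mag[~domain.mask] = 0.0
    return np.unravel_index(np.argmax(mag), mag.shape)


class TestBispectrumDirect:
    def test_zero_input_gives_zero_bispectrum(self):
        est = h.bispectrum_direct(np.zeros((8, 64)), nfft=64)
        assert np.allclose(est.values, 0)

    def test_matches_triple_product_oracle(self, coupled_segments):
        est = h.bispectrum_direct(coupled_segments[:8], nfft=64)
        oracle = naive_direct_bispectrum(coupled_segments[:8], 64)
        np.testing.assert_allclose(est.values, oracle, rtol=1e-10, atol=1e-8)

    def test_peak_at_coupled_cell(self, coupled_segments, qpc_cell):
        est = h.bispectrum_direct(coupled_segments, nfft=64)
        assert principal_peak(est) == qpc_cell

    def test_symmetry_in_f1_f2(self, coupled_segments):
        est = h.bispectrum_direct(coupled_segments, nfft=64)
        asym = np.max(np.abs(est.values - est.values.T))
        assert asym < 1e-9 * np.max(np.abs(est.values))

    def test_cubic_amplitude_scaling(self):
        spec = h.QPCSpec(f1=20.0, f2=30.0, noise_sd=0.0, n_samples=4096,
                         seed=1, phase_block=64)
        segs = h.gen_qpc_signal(spec).samples.reshape(64, 64)
        b1 = h.bispectrum_direct(segs, nfft=64)
        b2 = h.bispectrum_direct(2.0 * segs, nfft=64)
        peak = principal_peak(b1)
        ratio = np.abs(b2.values[peak]) / np.abs(b1.values[peak])
        assert ratio == pytest.approx(8.0, rel=0.01)

    def test_empty_window_list_rejected(self):
        with pytest.raises(ValueError):
            h.bispectrum_direct([])


class TestBispectrumIndirect:
    def test_zero_input_gives_zero(self):
        est = h.bispectrum_indirect(np.zeros((8, 64)), max_lag=16, nfft=64)
        assert np.allclose(est.values, 0)

    def test_peak_agrees_with_direct_method(self, coupled_segments, qpc_cell):
        direct = h.bispectrum_direct(coupled_segments, nfft=64)
        indirect = h.bispectrum_indirect(coupled_segments, max_lag=31, nfft=64)
        assert principal_peak(direct) == principal_peak(indirect) == qpc_cell

    def test_white_noise_floor_below_qpc_peak(self, coupled_segments):
        qpc_peak = np.abs(
            h.bispectrum_indirect(coupled_segments, max_lag=31, nfft=64).values
        ).max()
        domain = h.principal_domain(h.BiFrequencyGrid(nfft=64, fs=h.BONN_FS))
        floors = []
        for seed in range(5):
            noise = h.gen_gaussian_record(4096, seed=seed).samples.reshape(64, 64)
            # match the QPC signal's per-sample power (3 unit cosines)
            noise = noise * np.sqrt(1.5)
            est = h.bispectrum_indirect(noise, max_lag=31, nfft=64)
            floors.append(np.abs(est.values[domain.mask]).mean())
        assert np.mean(floors) < 0.1 * qpc_peak

    def test_max_lag_validation(self):
        with pytest.raises(ValueError, match="max_lag"):
            h.bispectrum_indirect(np.zeros((4, 64)), max_lag=64)


class TestBicoherence:
    def test_values_bounded_in_unit_interval(self, coupled_segments, uncoupled_segments):
        for segs in (coupled_segments, uncoupled_segments):
            est = h.bicoherence(segs, nfft=64)
            assert est.values.min() >= 0
            assert est.values.max() <= 1 + 1e-9

    def test_coupled_peak_high_uncoupled_low(self, qpc_cell):
        i, j = qpc_cell
        coupled, uncoupled = [], []
        for seed in range(10):
            for flag, acc in ((True, coupled), (False, uncoupled)):
                spec = h.QPCSpec(f1=20.0, f2=30.0, coupled=flag, noise_sd=0.05,
                                 n_samples=4096, seed=seed, phase_block=64)
                segs = h.gen_qpc_signal(spec).samples.reshape(64, 64)
                acc.append(h.bicoherence(segs, nfft=64).values[i, j])
        assert np.mean(coupled) > 0.9
        assert np.mean(uncoupled) < 0.2

    def test_invariant_under_amplitude_scaling(self, coupled_segments):
        a = h.bicoherence(coupled_segments, nfft=64).values
        b = h.bicoherence(137.0 * coupled_segments, nfft=64).values
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_background_decreases_with_averaging(self):
        """Doubling the averaged segments lowers the white-noise bicoherence
        floor: Monte-Carlo mean over the principal domain is monotone
        decreasing over 4 → 16 → 64 segments."""
        domain = h.principal_domain(h.BiFrequencyGrid(nfft=64, fs=h.BONN_FS))
        cells = domain.mask & (np.add.outer(np.arange(33), np.arange(33)) >= 1)
        means = []
        for n_seg in (8, 16, 64):  # ≥8 segments required by the estimator
            vals = []
            for seed in range(8):
                x = h.gen_gaussian_record(n_seg * 64, seed=100 + seed).samples
                est = h.bicoherence(x.reshape(n_seg, 64), nfft=64)
                vals.append(est.values[cells].mean())
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]

    def test_needs_eight_segments(self):
        with pytest.raises(ValueError, match="8 segments"):
            h.bicoherence(np.random.default_rng(0).normal(size=(4, 64)), nfft=64)

    def test_zero_denominator_cells_flagged_zero(self):
        segs = np.zeros((8, 64))
        est = h.bicoherence(segs, nfft=64)
        assert est.zero_denominator.all()
        assert np.all(est.values == 0)


class TestPrincipalDomain:
    def test_inner_triangle_definition_small_grid(self):
        grid = h.BiFrequencyGrid(nfft=8, fs=8.0)  # 1 Hz per cell
        domain = h.principal_domain(grid)
        ii, jj = np.nonzero(domain.mask)
        f = grid.freq_axis
        assert np.all(f[jj] <= f[ii])
        assert np.all(f[ii] + f[jj] <= grid.fs / 2 + 1e-12)

    def test_twelve_distinct_transforms(self):
        transforms = h.symmetry_transforms()
        assert len(transforms) == 12
        # distinct as maps: evaluate on a probe cell off every symmetry axis
        images = {t(5, 2, 32) for t in transforms}
        assert len(images) == 12

    def test_symmetry_images_tile_32x32_plane(self):
        domain = h.principal_domain(h.BiFrequencyGrid(nfft=32, fs=32.0))
        coverage = domain.symmetry_coverage()
        assert coverage.shape == (32, 32)
        assert (coverage >= 1).all()

    def test_overlaps_only_on_symmetry_boundaries(self):
        n = 32
        domain = h.principal_domain(h.BiFrequencyGrid(nfft=n, fs=float(n)))
        coverage = h.principal_domain(h.BiFrequencyGrid(nfft=n, fs=float(n))).symmetry_coverage()
        ii, jj = np.nonzero(coverage > 1)
        f1, f2 = ii.astype(int), jj.astype(int)
        f3 = (-f1 - f2) % n
        on_boundary = (
            (f1 == f2) | (f2 == f3) | (f1 == f3)
            | (f1 == 0) | (f2 == 0) | (f3 == 0)
            | (f1 == (-f1) % n) | (f2 == (-f2) % n) | (f3 == (-f3) % n)
        )
        assert on_boundary.all()

    def test_bispectrum_respects_symmetry_transforms(self, coupled_segments):
        """Values on the full FFT plane agree (up to conjugation) across the
        twelve transform images of an interior cell."""
        segs = coupled_segments - coupled_segments.mean(axis=1, keepdims=True)
        X = np.fft.fft(segs, 64, axis=1)
        i0, j0 = 11, 7
        base = np.mean(X[:, i0] * X[:, j0] * np.conj(X[:, (i0 + j0) % 64]))
        for t in h.symmetry_transforms():
            a, b = t(i0, j0, 64)
            val = np.mean(X[:, a] * X[:, b] * np.conj(X[:, (a + b) % 64]))
            assert min(abs(val - base), abs(val - np.conj(base))) < 1e-6 * abs(base)


class TestHinich:
    def test_pfa_is_probability(self, coupled_segments, uncoupled_segments):
        for segs in (coupled_segments, uncoupled_segments):
            res = h.hinich_test(segs, nfft=64)
            assert 0.0 <= res.pfa <= 1.0
            assert res.chi2_gauss >= 0
            assert res.lambda_lin >= 0

    def test_strong_qpc_detected_as_non_gaussian(self, coupled_segments):
        assert h.hinich_test(coupled_segments, nfft=64).pfa < 0.01

    def test_gaussian_type_one_error_near_nominal(self):
        # small-sample check; the 200-run calibration lives in the acceptance suite
        rejections = 0
        for seed in range(40):
            x = h.gen_gaussian_record(4096, seed=500 + seed).samples
            res = h.hinich_test(x.reshape(64, 64), nfft=64)
            rejections += res.pfa < 0.05
        assert rejections / 40 <= 0.2

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            h.hinich_test(np.ones((8, 64)), nfft=64)

    def test_dc_cells_excluded(self):
        cells = _hinich_cells(64)
        assert not cells[0, :].any()
        assert not cells[:, 0].any()

    def test_linearity_iqr_helper_returns_spreads(self, coupled_segments):
        sample_iqr, model_iqr = h.hos.hinich_linearity_iqr(coupled_segments, nfft=64)
        assert sample_iqr >= 0 and model_iqr > 0
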