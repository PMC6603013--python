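"""Generalized 2D correlation: Hilbert-Noda construction, map properties,
oracle agreement, autopeaks and the concentration-suitability screen.

The independent oracle computes Phi and Psi by direct double-loop summation
over the dynamic spectra (no matrix algebra)."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nirassign.spectra import Spectrum, SpectrumSet
from nirassign.synthetic import (make_magnolol_analog,
                                 simulate_concentration_series)
from nirassign.twodcos import (autopeaks, concentration_suitability,
                               correlate, dynamic_spectra,
                               hilbert_noda_matrix)

FOUR_LN2 = 4.0 * np.log(2.0)


def gaussian(x, center, fwhm, amp=1.0):
    return amp * np.exp(-FOUR_LN2 * (x - center) ** 2 / fwhm ** 2)


def oracle_maps(dyn):
    """Direct double-summation Phi and Psi (the independent oracle)."""
    m, n = dyn.shape
    noda = np.zeros((m, m))
    for j in range(m):
        for k in range(m):
            if j != k:
                noda[j, k] = 1.0 / (np.pi * (k - j))
    sync = np.zeros((n, n))
    async_ = np.zeros((n, n))
    for i1 in range(n):
        for i2 in range(n):
            s = a = 0.0
            for j in range(m):
                s += dyn[j, i1] * dyn[j, i2]
                for k in range(m):
                    a += dyn[j, i1] * noda[j, k] * dyn[k, i2]
            sync[i1, i2] = s / (m - 1)
            async_[i1, i2] = a / (m - 1)
    return sync, async_


def band_set(amplitudes1, amplitudes2, n=40):
    """Two separated bands whose amplitudes vary independently across rows."""
    g = np.linspace(1200.0, 1800.0, n)
    b1 = gaussian(g, 1350.0, 60.0)
    b2 = gaussian(g, 1650.0, 60.0)
    traces = (np.outer(amplitudes1, b1) + np.outer(amplitudes2, b2))
    return SpectrumSet(g, traces, np.arange(len(amplitudes1), dtype=float)), g, b1, b2


class TestHilbertNoda:
    def test_m1_and_m3_exact(self):
        assert np.array_equal(hilbert_noda_matrix(1), [[0.0]])
        expected = np.array([[0, 1 / np.pi, 1 / (2 * np.pi)],
                             [-1 / np.pi, 0, 1 / np.pi],
                             [-1 / (2 * np.pi), -1 / np.pi, 0]])
        assert np.allclose(hilbert_noda_matrix(3), expected)

    @given(st.integers(1, 30))
    def test_antisymmetric_zero_diagonal(self, m):
        n = hilbert_noda_matrix(m)
        assert np.allclose(n + n.T, 0.0)
        assert np.all(np.diag(n) == 0.0)

    def test_m0_rejected(self):
        with pytest.raises(ValueError):
            hilbert_noda_matrix(0)


class TestDynamicSpectra:
    def test_identical_spectra_mean_reference_zero(self):
        ss, *_ = band_set([1.0, 1.0], [1.0, 1.0])
        assert np.allclose(dynamic_spectra(ss), 0.0)

    def test_mean_removal_of_linear_series(self):
        ss, g, b1, b2 = band_set([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        dyn = dynamic_spectra(ss)
        assert np.allclose(dyn, np.outer([-1.0, 0.0, 1.0], b1 + b2))
        assert np.allclose(dyn.sum(axis=0), 0.0)

    def test_external_mean_reference_matches_mean_mode(self):
        ss, g, *_ = band_set([1.0, 2.0, 3.0], [0.5, 1.5, 2.0])
        ref = Spectrum(g, ss.traces.mean(axis=0))
        assert np.allclose(dynamic_spectra(ss, reference=ref),
                           dynamic_spectra(ss, reference="mean"))

    def test_m1_rejected(self):
        g = np.linspace(1200, 1300, 10)
        ss = SpectrumSet(g, np.ones((1, 10)), np.array([1.0]))
        with pytest.raises(ValueError, match="m >= 2"):
            dynamic_spectra(ss)


class TestCorrelationMaps:
    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(11)
        g = np.linspace(1200, 1500, 15)
        traces = rng.normal(size=(6, 15))
        ss = SpectrumSet(g, traces, np.arange(6.0))
        res = correlate(ss, window=None)
        sync_o, async_o = oracle_maps(traces - traces.mean(axis=0))
        scale = np.abs(sync_o).max()
        assert np.abs(res.sync - sync_o).max() <= 1e-12 * scale
        assert np.abs(res.async_ - async_o).max() <= 1e-12 * np.abs(async_o).max()

    def test_sync_rank1_closed_form(self):
        c = np.array([1.0, 2.0, 3.0, 5.0])
        ss, g, b1, b2 = band_set(c, c)
        res = correlate(ss, window=None)
        b = b1 + b2
        expected = np.var(c, ddof=1) * np.outer(b, b)
        assert np.allclose(res.sync, expected)
        assert np.all(res.sync >= -1e-12)  # all auto and cross peaks positive

    def test_constant_series_zero_map(self):
        ss, *_ = band_set([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        res = correlate(ss, window=None)
        assert np.allclose(res.sync, 0.0) and np.allclose(res.async_, 0.0)

    def test_sync_symmetric_psd_diagonal_is_variance(self):
        rng = np.random.default_rng(5)
        g = np.linspace(1200, 1500, 20)
        traces = rng.normal(size=(8, 20))
        ss = SpectrumSet(g, traces, np.arange(8.0))
        res = correlate(ss, window=None)
        assert np.allclose(res.sync, res.sync.T)
        assert np.linalg.eigvalsh(res.sync).min() >= -1e-10
        assert np.allclose(np.diag(res.sync), np.var(traces, axis=0, ddof=1))

    def test_async_antisymmetric_zero_diag_and_rank1_null(self):
        c = np.array([0.5, 1.0, 4.0, 9.0])
        ss, *_ = band_set(c, c)
        res = correlate(ss, window=None)
        assert np.abs(res.async_ + res.async_.T).max() <= 1e-12
        assert np.abs(np.diag(res.async_)).max() <= 1e-14
        assert np.abs(res.async_).max() <= 1e-12 * np.abs(res.sync).max()

    def test_quadrature_bands_produce_async_cross_peaks(self):
        theta = 2 * np.pi * np.arange(16) / 16
        ss_q, g, b1, b2 = band_set(1 + 0.5 * np.sin(theta), 1 + 0.5 * np.cos(theta))
        ss_p, *_ = band_set(1 + 0.5 * np.sin(theta), 1 + 0.5 * np.sin(theta))
        i1, i2 = int(np.argmax(b1)), int(np.argmax(b2))
        quad = correlate(ss_q, window=None)
        phase = correlate(ss_p, window=None)
        assert abs(quad.async_[i1, i2]) > 10 * abs(phase.async_[i1, i2])
        # sign flips across the diagonal
        assert quad.async_[i1, i2] == pytest.approx(-quad.async_[i2, i1])
        assert quad.async_[i1, i2] != 0.0
        # agreement with the direct-summation oracle
        _, async_o = oracle_maps(ss_q.traces - ss_q.traces.mean(axis=0))
        assert np.allclose(quad.async_, async_o, atol=1e-12 * np.abs(async_o).max())

    def test_scaling_spectra_scales_maps_quadratically(self):
        rng = np.random.default_rng(3)
        g = np.linspace(1200, 1500, 12)
        traces = rng.normal(size=(5, 12))
        base = correlate(SpectrumSet(g, traces, np.arange(5.0)), window=None)
        scaled = correlate(SpectrumSet(g, 3.0 * traces, np.arange(5.0)), window=None)
        assert np.allclose(scaled.sync, 9.0 * base.sync)
        assert np.allclose(scaled.async_, 9.0 * base.async_)

    def test_independent_bands_have_no_sync_cross_peak(self):
        # 200 seeded draws; cross peak within 3 standard errors of zero
        rng = np.random.default_rng(42)
        m = 200
        a = rng.normal(1.0, 0.1, size=m)
        c = rng.normal(1.0, 0.1, size=m)
        ss, g, b1, b2 = band_set(a, c)
        res = correlate(ss, window=None)
        i1, i2 = int(np.argmax(b1)), int(np.argmax(b2))
        se = np.sqrt(np.var(a, ddof=1) * np.var(c, ddof=1) / (m - 1))
        assert abs(res.sync[i1, i2]) <= 3 * se


class TestAutopeaks:
    def test_zero_map_empty(self):
        g = np.linspace(1200, 1500, 30)
        ss = SpectrumSet(g, np.ones((3, 30)), np.arange(3.0))
        assert autopeaks(correlate(ss, window=None)) == []

    def test_three_band_series_three_autopeaks(self):
        g = np.linspace(1150.0, 2450.0, 600)
        centers = (1300.0, 1800.0, 2300.0)
        b = sum(gaussian(g, c, 30.0) for c in centers)
        conc = np.array([1.0, 2.0, 3.0, 4.0])
        ss = SpectrumSet(g, np.outer(conc, b), conc)
        peaks = autopeaks(correlate(ss, window=None))
        assert len(peaks) == 3
        for p, c in zip(peaks, centers):
            assert abs(p.position_nm - c) <= 5.0

    def test_twelve_band_analog_counts_twelve(self):
        mag = make_magnolol_analog()
        ss = simulate_concentration_series(mag, (0.2, 0.4, 0.6, 9.6, 9.8, 10.0))
        peaks = autopeaks(correlate(ss, stride=4))
        assert len(peaks) == 12


class TestConcentrationSuitability:
    @staticmethod
    def builder(concs, noise_sd, seed):
        grid = np.arange(1100.0, 2500.5, 1.0)
        return simulate_concentration_series(make_magnolol_analog(), concs,
                                             grid, noise_sd, seed)

    def test_noiseless_reaches_expected_everywhere(self):
        base = np.array([0.2, 0.4, 0.6, 9.6, 9.8, 10.0])
        table = concentration_suitability(
            self.builder, [list(base * s) for s in (0.5, 1.0, 2.0)],
            noise_sd=0.0, seed=0, expected_bands=12, window=None, stride=4)
        assert table["reaches_expected"].all()
        assert (table["autopeak_count"] == 12).all()

    def test_dominant_noise_gives_zero_count(self):
        base = [0.2, 0.4, 0.6, 9.6, 9.8, 10.0]
        table = concentration_suitability(
            self.builder, [base], noise_sd=500.0, seed=1, expected_bands=12,
            window=None, stride=4)
        assert (table["autopeak_count"] == 0).all()

    def test_single_level_set_rejected(self):
        with pytest.raises(ValueError, match="m >= 2"):
            concentration_suitability(self.builder, [[1.0]], 0.0, 0, 1)
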