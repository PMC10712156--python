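"""Smoothing, baseline, picking, flatline, calibration and outlier removal."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from seedtyper import (
    BTS_MASSES,
    BTS_STANDARD,
    MassTolerance,
    Peak,
    PeakList,
    Spectrum,
    calibrate,
    detect_flatline,
    filter_outlier_replicates,
    normalize,
    pick_peaks,
    smooth,
    subtract_baseline,
)
from seedtyper.preprocessing import CalibrationStandard

from conftest import impulse_spectrum, make_peaklist


def flat_spectrum(values, start=2000.0, step=1.0):
    values = np.asarray(values, dtype=float)
    return Spectrum(start + step * np.arange(len(values)), values)


class TestSmooth:
    @pytest.mark.parametrize("method", ["savgol", "moving_average"])
    def test_constant_signal_unchanged(self, method):
        spec = flat_spectrum([5.0] * 50)
        out = smooth(spec, 7, method=method)
        np.testing.assert_allclose(out.intensity, 5.0)

    def test_impulse_moving_average_plateau(self):
        spec = flat_spectrum([0, 0, 9, 0, 0])
        out = smooth(spec, 3, method="moving_average")
        np.testing.assert_allclose(out.intensity, [0, 3, 3, 3, 0])

    def test_noise_reduction_on_gaussian_peak(self, rng):
        x = np.arange(2000.0, 3000.0)
        clean = 100.0 * np.exp(-0.5 * ((x - 2500.0) / 30.0) ** 2)
        noisy = clean + rng.normal(0, 2.0, size=len(x))
        out = smooth(Spectrum(x, np.clip(noisy, 0, None)), 7)
        assert np.std(out.intensity - clean) < np.std(np.clip(noisy, 0, None) - clean)

    def test_window_validation(self):
        spec = flat_spectrum([1.0] * 10)
        with pytest.raises(ValueError, match="odd"):
            smooth(spec, 4)
        with pytest.raises(ValueError):
            smooth(spec, 11)
        with pytest.raises(ValueError):
            smooth(spec, 1)


class TestSubtractBaseline:
    def test_all_zero_maps_to_all_zero(self):
        spec = flat_spectrum([0.0] * 200)
        for method in ("snip", "rolling_min"):
            out = subtract_baseline(spec, method=method)
            np.testing.assert_allclose(out.intensity, 0.0)

    def test_linear_ramp_rolling_min(self):
        # ramp 0..100 over 10000 points; per-window rise (half_window 5)
        # is 0.1, far below 1% of the ramp max
        n = 10000
        spec = flat_spectrum(np.linspace(0, 100, n), step=1.8)
        out = subtract_baseline(spec, method="rolling_min", half_window=5)
        assert out.intensity.max() < 1.0

    def test_gaussian_peak_on_constant_baseline(self):
        x = np.arange(2000.0, 4000.0)
        peak = 100.0 * np.exp(-0.5 * ((x - 3000.0) / 8.0) ** 2)
        spec = Spectrum(x, peak + 20.0)
        out = subtract_baseline(spec, method="snip", half_window=40)
        apex = out.intensity[np.argmin(np.abs(x - 3000.0))]
        assert abs(apex - 100.0) < 5.0

    def test_half_window_validated(self):
        with pytest.raises(ValueError):
            subtract_baseline(flat_spectrum([1.0] * 10), half_window=0)


class TestNormalize:
    def test_base_peak_and_tic(self):
        pl = make_peaklist([2500, 2600], [1.0, 4.0])
        np.testing.assert_allclose(normalize(pl, "base_peak").intensities, [25.0, 100.0])
        np.testing.assert_allclose(normalize(pl, "tic").intensities, [0.2, 0.8])

    def test_idempotent(self):
        spec = flat_spectrum([1.0, 4.0, 2.0])
        once = normalize(spec, "base_peak")
        twice = normalize(once, "base_peak")
        np.testing.assert_allclose(once.intensity, twice.intensity)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            normalize(flat_spectrum([0.0, 0.0]))


class TestPickPeaks:
    def test_all_zero_spectrum_is_flatline(self):
        pl = pick_peaks(flat_spectrum([0.0] * 100))
        assert len(pl) == 0 and pl.flatline

    def test_two_gaussians_high_snr(self, rng):
        x = np.arange(2000.0, 20000.0)
        y = 100.0 * np.exp(-0.5 * ((x - 5000.0) / 7.0) ** 2)
        y += 80.0 * np.exp(-0.5 * ((x - 9000.0) / 9.0) ** 2)
        y += np.abs(rng.normal(0, 0.3, size=len(x)))
        pl = pick_peaks(Spectrum(x, y))
        assert len(pl) == 2
        assert abs(pl.peaks[0].mz - 5000.0) <= 1.0
        assert abs(pl.peaks[1].mz - 9000.0) <= 1.0

    def test_min_separation_keeps_taller(self):
        spec = Spectrum(
            np.array([4999.0, 4999.5, 5000.0, 5000.5, 5001.0]),
            np.array([0.0, 8.0, 0.0, 9.0, 0.0]),
        )
        pl = pick_peaks(spec, min_separation=2.0)
        assert len(pl) == 1
        assert pl.peaks[0].mz == 5000.5


class TestDetectFlatline:
    def test_empty_is_flatline(self):
        assert detect_flatline(make_peaklist([]))

    @pytest.mark.parametrize("n,expected", [(5, False), (4, True)])
    def test_threshold_boundary(self, n, expected):
        pl = make_peaklist(range(2500, 2500 + 200 * n, 200), snrs=[10.0] * n)
        assert detect_flatline(pl) is expected

    @given(st.integers(min_value=0, max_value=12))
    def test_monotone_adding_peaks_never_creates_flatline(self, n):
        mzs = [2500.0 + 100 * i for i in range(n)]
        before = detect_flatline(make_peaklist(mzs, snrs=[10.0] * n))
        after = detect_flatline(
            make_peaklist(mzs + [19000.0], snrs=[10.0] * (n + 1))
        )
        assert not (before is False and after is True)


class TestCalibrate:
    def test_exact_bts_masses(self):
        spec = impulse_spectrum(BTS_MASSES)
        _, report = calibrate(spec)
        assert report.matched == 8
        assert abs(report.shift_ppm) < 1.0
        assert report.passed

    def test_recovers_injected_shift(self):
        spec = impulse_spectrum(BTS_MASSES, shift=200e-6)
        corrected, report = calibrate(spec)
        assert report.matched == 8
        assert abs(report.shift_ppm - 200.0) < 20.0
        picked = pick_peaks(corrected)
        for ref in BTS_MASSES:
            nearest = picked.mz[np.argmin(np.abs(picked.mz - ref))]
            assert abs(nearest - ref) / ref < 20e-6

    def test_empty_spectrum_fails(self):
        spec = flat_spectrum([0.0] * 100)
        same, report = calibrate(spec)
        assert report.matched == 0 and not report.passed
        assert same is spec

    def test_shift_recovery_over_random_shifts(self, rng):
        for shift_ppm in rng.uniform(-300, 300, size=25):
            spec = impulse_spectrum(BTS_MASSES, shift=shift_ppm * 1e-6)
            _, report = calibrate(spec)
            assert report.passed
            assert abs(report.shift_ppm - shift_ppm) < 20.0

    def test_bundled_standard_masses(self):
        assert BTS_STANDARD.reference_masses == BTS_MASSES
        assert len(BTS_MASSES) == 8
        assert BTS_MASSES[0] == 3637.8
        with pytest.raises(ValueError):
            CalibrationStandard(reference_masses=(5000.0, 3000.0))


class TestOutlierReplicates:
    def test_identical_lists_all_retained(self):
        lists = [make_peaklist([3000, 5000, 7000, 9000, 11000]) for _ in range(5)]
        retained, removed = filter_outlier_replicates(lists)
        assert len(retained) == 5 and not removed

    def test_disjoint_replicate_removed(self):
        base = [make_peaklist([3000, 5000, 7000, 9000]) for _ in range(4)]
        odd = make_peaklist([4000, 6000, 8000, 10000])
        retained, removed = filter_outlier_replicates(base + [odd])
        assert odd in removed
        assert len(retained) == 4

    def test_flatlines_always_removed(self):
        lists = [make_peaklist([], flatline=True) for _ in range(3)]
        retained, removed = filter_outlier_replicates(lists)
        assert retained == [] and len(removed) == 3


class TestChainRecovery:
    def test_noise_free_template_recovered_exactly(self):
        from seedtyper import simulate_spectrum

        template = make_peaklist(
            [3000, 5000, 8000, 12000, 16000, 19000], [80, 100, 60, 90, 50, 70]
        )
        spec = simulate_spectrum(template, baseline_amplitude=20.0, noise_sd=0.0)
        chain = pick_peaks(subtract_baseline(smooth(spec, 7), half_window=40))
        assert len(chain) == len(template)
        for found, true in zip(chain.peaks, template.peaks):
            assert abs(found.mz - true.mz) <= 1.0  # one grid step
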