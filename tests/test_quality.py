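"""Quality metrics: template SNR, drift amplitude, instantaneous frequency,
lag-searched cross-correlation."""

import numpy as np
import pytest

from cardiopatch import quality, synth, vitals

FS = 250.0


def truth_peaks(rec):
    return vitals.RPeakSet(indices=rec.rpeak_indices, fs=rec.fs)


class TestSNR:
    def test_noiseless_record_exceeds_40db(self, clean_record_60bpm):
        rec = clean_record_60bpm
        assert quality.snr(rec.samples, rec.fs, truth_peaks(rec)) >= 40.0

    def test_constructed_20db_mixture_estimated_within_1db(
            self, clean_record_60bpm):
        rec = clean_record_60bpm
        sd = synth.broadband_sd_for_snr(rec, 20.0)
        noisy = synth.add_noise(
            rec, synth.NoiseModel(wander_amp=0, powerline_amp=0,
                                  broadband_sd=sd, burst_rate=0), seed=2)
        est = quality.snr(noisy.samples, rec.fs, truth_peaks(rec))
        assert abs(est - 20.0) <= 1.0

    def test_scale_invariance(self, clean_record_60bpm):
        rec = clean_record_60bpm
        sd = synth.broadband_sd_for_snr(rec, 15.0)
        noisy = synth.add_noise(
            rec, synth.NoiseModel(wander_amp=0, powerline_amp=0,
                                  broadband_sd=sd, burst_rate=0), seed=3)
        a = quality.snr(noisy.samples, rec.fs, truth_peaks(rec))
        b = quality.snr(noisy.samples * 7.3, rec.fs, truth_peaks(rec))
        assert abs(a - b) <= 0.1

    def test_monotone_decreasing_in_noise_level(self, clean_record_60bpm):
        rec = clean_record_60bpm
        estimates = []
        for sd in (0.02, 0.1, 0.4):
            noisy = synth.add_noise(
                rec, synth.NoiseModel(wander_amp=0, powerline_amp=0,
                                      broadband_sd=sd, burst_rate=0), seed=5)
            estimates.append(quality.snr(noisy.samples, rec.fs,
                                         truth_peaks(rec)))
        assert estimates[0] > estimates[1] > estimates[2]

    def test_too_few_beats_rejected(self):
        with pytest.raises(ValueError):
            quality.snr(np.zeros(1000), FS,
                        vitals.RPeakSet(indices=np.array([100, 300]), fs=FS))


class TestDriftAmplitude:
    def test_drift_free_record_below_0p02(self, clean_record_60bpm):
        rec = clean_record_60bpm
        x = (rec.samples - rec.samples.min()) / np.ptp(rec.samples)
        assert quality.drift_amplitude(x, rec.fs) <= 0.02

    def test_known_wander_measured_as_peak_to_peak(self, clean_record_60bpm):
        rec = clean_record_60bpm
        x = (rec.samples - rec.samples.min()) / np.ptp(rec.samples)
        t = np.arange(x.size) / rec.fs
        x = x + 0.2 * np.sin(2 * np.pi * 0.25 * t)
        value = quality.drift_amplitude(x, rec.fs)
        assert abs(value - 0.4) <= 0.04

    def test_zero_signal_gives_zero(self):
        assert quality.drift_amplitude(np.zeros(int(20 * FS)), FS) == 0.0

    def test_scale_invariance_by_construction(self, clean_record_60bpm):
        rec = clean_record_60bpm
        t = np.arange(rec.n_samples) / rec.fs
        x = rec.samples + 0.3 * np.sin(2 * np.pi * 0.2 * t)
        assert np.isclose(quality.drift_amplitude(x, rec.fs),
                          quality.drift_amplitude(5.0 * x, rec.fs))

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            quality.drift_amplitude(np.zeros(int(5 * FS)), FS)


class TestInstantaneousFrequency:
    def test_pure_tone_ridge(self):
        t = np.arange(int(10 * FS)) / FS
        tf = quality.instantaneous_frequency(np.sin(2 * np.pi * 10 * t), FS)
        assert np.all(np.abs(tf.ridge - 10.0) <= 0.5)

    def test_chirp_ridge_at_midpoint(self):
        from scipy.signal import chirp
        t = np.arange(int(10 * FS)) / FS
        x = chirp(t, f0=5.0, f1=15.0, t1=10.0, method="linear")
        tf = quality.instantaneous_frequency(x, FS)
        mid = np.argmin(np.abs(tf.times - 5.0))
        assert abs(tf.ridge[mid] - 10.0) <= 1.0

    def test_arrhythmia_raises_ridge_variability(self):
        base = synth.generate_record(duration=30, seed=21)
        ar = synth.apply_pathology(
            base, synth.DEFAULT_PROFILES["AR"], seed=2)
        var_nr = np.var(quality.instantaneous_frequency(base.samples, FS).ridge)
        var_ar = np.var(quality.instantaneous_frequency(ar.samples, FS).ridge)
        assert var_ar > var_nr

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            quality.instantaneous_frequency(np.zeros(100), FS)


class TestXcorr:
    def test_self_correlation_is_one_at_zero_lag(self, default_record):
        rho, lag = quality.xcorr_coefficient(default_record.samples,
                                             default_record.samples, fs=FS)
        assert rho == pytest.approx(1.0) and lag == 0

    def test_inverted_copy_reports_minus_one(self, default_record):
        rho, lag = quality.xcorr_coefficient(default_record.samples,
                                             -default_record.samples, fs=FS)
        assert rho == pytest.approx(-1.0) and lag == 0

    def test_shift_recovered(self, default_record):
        a = default_record.samples
        b = np.roll(a, 25)
        rho, lag = quality.xcorr_coefficient(a[100:-100], b[100:-100], fs=FS)
        assert rho > 0.99 and abs(lag) == 25

    def test_symmetry_under_swap_negates_lag(self, default_record):
        a = default_record.samples[:-50]
        b = default_record.samples[50:]
        r1, l1 = quality.xcorr_coefficient(a, b, fs=FS)
        r2, l2 = quality.xcorr_coefficient(b, a, fs=FS)
        assert r1 == pytest.approx(r2, abs=1e-9) and l1 == -l2

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            quality.xcorr_coefficient(np.ones(100), np.arange(100.0), fs=FS)
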