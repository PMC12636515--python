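"""Generator ground truth, pathology structure, orientation group, noise."""

import numpy as np
import pytest

from cardiopatch import io as cio
from cardiopatch import quality, synth


def fixed_rhythm(hr, sd=0.0):
    return synth.RhythmModel(mean_hr=hr, hr_sd=sd, respiratory_mod_depth=0.0)


class TestGenerateRecord:
    @pytest.mark.parametrize("hr,expect_peaks,expect_spacing",
                             [(60, 10, 250), (120, 20, 125)])
    def test_zero_variance_rhythm_gives_exact_grid(self, hr, expect_peaks,
                                                   expect_spacing):
        rec = synth.generate_record(rhythm=fixed_rhythm(hr), fs=250,
                                    duration=10, seed=1)
        assert len(rec.rpeak_indices) == expect_peaks
        assert np.unique(np.diff(rec.rpeak_indices)).tolist() == [expect_spacing]

    def test_mean_rr_matches_rhythm_within_3se(self):
        rec = synth.generate_record(rhythm=fixed_rhythm(70, sd=3), fs=250,
                                    duration=60, seed=42)
        rr = rec.rr_seconds
        se = rr.std(ddof=1) / np.sqrt(rr.size)
        assert abs(rr.mean() - 60.0 / 70.0) < 3 * se

    def test_rpeaks_sit_on_clean_waveform_maxima(self, default_record):
        rec = default_record
        for i in rec.rpeak_indices:
            lo = max(0, i - 5)
            local = lo + np.argmax(rec.clean_samples[lo:i + 6])
            assert abs(local - i) <= 1

    def test_clean_equals_samples_before_noise(self, default_record):
        assert np.array_equal(default_record.samples,
                              default_record.clean_samples)

    def test_fiducial_spans_ordered_within_beat(self, default_record):
        for beat in default_record.fiducials:
            assert beat["P"][1] <= beat["QRS"][0]
            assert beat["QRS"][1] == beat["ST"][0]
            assert beat["ST"][1] == beat["T"][0]

    @pytest.mark.parametrize("kwargs", [
        {"duration": -1.0}, {"fs": 50.0}, {"duration": 1.0},
    ])
    def test_invalid_arguments_rejected(self, kwargs):
        with pytest.raises(ValueError):
            synth.generate_record(rhythm=fixed_rhythm(60), seed=0, **kwargs)

    def test_invalid_rhythm_rejected(self):
        with pytest.raises(ValueError):
            synth.RhythmModel(mean_hr=300)


class TestPathology:
    def test_nr_profile_is_identity(self, default_record):
        out = synth.apply_pathology(default_record,
                                    synth.PathologyProfile("NR"))
        assert np.array_equal(out.samples, default_record.samples)

    def test_mi_shifts_st_mean_by_exactly_the_configured_amount(
            self, default_record):
        out = synth.apply_pathology(
            default_record, synth.PathologyProfile("MI", st_shift=0.2))
        deltas = []
        for b_in, b_out in zip(default_record.fiducials, out.fiducials):
            on, off = b_in["ST"]
            deltas.append(out.samples[on:off].mean()
                          - default_record.samples[on:off].mean())
        assert np.allclose(deltas, 0.2, atol=1e-9)

    def test_ar_inflates_rr_sd_by_factor(self):
        base = synth.generate_record(rhythm=fixed_rhythm(70, sd=2),
                                     duration=60, seed=42)
        out = synth.apply_pathology(
            base, synth.PathologyProfile("AR", rr_irregularity_factor=4.0),
            seed=5)
        sd = out.hr_draws.std(ddof=1)
        se = sd / np.sqrt(2 * (out.hr_draws.size - 1))
        assert abs(sd - 8.0) < 3 * se

    def test_ah_scales_p_wave(self, default_record):
        out = synth.apply_pathology(
            default_record,
            synth.PathologyProfile("AH", p_amp_scale=2.0, p_width_scale=1.5))
        p_in = max(default_record.samples[b["P"][0]:b["P"][1]].max()
                   for b in default_record.fiducials)
        p_out = max(out.samples[b["P"][0]:b["P"][1]].max()
                    for b in out.fiducials)
        assert p_out > 1.5 * p_in

    def test_nonidentity_modifiers_on_nr_rejected(self):
        with pytest.raises(ValueError):
            synth.PathologyProfile("NR", st_shift=0.1)

    def test_pathology_after_noise_rejected(self, default_record):
        noisy = synth.add_noise(default_record, synth.NoiseModel(), seed=0)
        with pytest.raises(ValueError):
            synth.apply_pathology(noisy, synth.PathologyProfile("MI",
                                                                st_shift=0.1))

    def test_separability_of_default_profiles(self):
        """Per-class summary statistics sit >= 5 pooled SDs from normal."""
        n_rep, dur = 12, 30.0
        stats = {lab: [] for lab in synth.CLASS_LABELS}
        for k in range(n_rep):
            base = synth.generate_record(duration=dur, seed=100 + k)
            for lab in synth.CLASS_LABELS:
                rec = synth.apply_pathology(base, synth.DEFAULT_PROFILES[lab],
                                            seed=k)
                st = np.mean([rec.samples[b["ST"][0]:b["ST"][1]].mean()
                              for b in rec.fiducials])
                rr_sd = np.diff(rec.rpeak_indices).std() / rec.fs
                p_amp = np.mean([rec.samples[b["P"][0]:b["P"][1]].max()
                                 for b in rec.fiducials])
                r_amp = np.mean(rec.samples[rec.rpeak_indices])
                stats[lab].append({"MI": st, "AR": rr_sd, "AH": p_amp / r_amp})
        for lab, key in [("MI", "MI"), ("AR", "AR"), ("AH", "AH")]:
            x = np.array([s[key] for s in stats[lab]])
            y = np.array([s[key] for s in stats["NR"]])
            pooled = np.sqrt((x.var(ddof=1) + y.var(ddof=1)) / 2)
            assert abs(x.mean() - y.mean()) >= 5 * pooled, lab


class TestPosition:
    def test_o0_is_identity(self, default_record):
        out = synth.apply_position(default_record,
                                   synth.PositionModel.for_orientation("O0"))
        assert np.allclose(out.samples, default_record.samples)
        assert out.orientation_label == "O0"

    def test_o120_roundtrip_recovers_samples(self, default_record):
        pos = synth.PositionModel.for_orientation("O120")
        fwd = synth.apply_position(default_record, pos)
        back = synth.invert_position(fwd, pos)
        assert np.max(np.abs(back.samples - default_record.samples)) < 1e-9
        assert back.orientation_label == "O0"

    def test_orientation_labels_form_a_3_cycle(self, default_record):
        pos = synth.PositionModel.for_orientation("O120")
        rec = default_record
        labels = []
        for _ in range(3):
            rec = synth.apply_position(rec, pos)
            labels.append(rec.orientation_label)
        assert labels == ["O120", "O240", "O0"]

    def test_rpeak_time_indices_preserved(self, default_record):
        out = synth.apply_position(default_record,
                                   synth.PositionModel.for_orientation("O240"))
        assert np.array_equal(out.rpeak_indices, default_record.rpeak_indices)

    def test_misplacement_flips_polarity_and_shrinks_amplitude(
            self, default_record):
        out = synth.apply_position(default_record,
                                   synth.PositionModel.for_orientation("O120"))
        rho = np.corrcoef(out.samples, default_record.samples)[0, 1]
        assert rho < -0.9  # polarity flip
        assert np.ptp(out.samples) < 0.8 * np.ptp(default_record.samples)


class TestNoise:
    def test_zero_noise_leaves_samples_clean(self, default_record):
        out = synth.add_noise(default_record, synth.NO_NOISE, seed=0)
        assert np.array_equal(out.samples, out.clean_samples)

    def test_constructed_snr_matches_power_ratio(self, clean_record_60bpm):
        rec = clean_record_60bpm
        sd = synth.broadband_sd_for_snr(rec, 20.0)
        noisy = synth.add_noise(
            rec, synth.NoiseModel(wander_amp=0, powerline_amp=0,
                                  broadband_sd=sd, burst_rate=0), seed=2)
        noise = noisy.samples - noisy.clean_samples
        snr = 10 * np.log10(np.mean(rec.clean_samples ** 2)
                            / np.mean(noise ** 2))
        assert abs(snr - 20.0) < 1.0

    def test_powerline_component_peaks_at_mains_frequency(self, default_record):
        noisy = synth.add_noise(
            default_record,
            synth.NoiseModel(wander_amp=0, powerline_amp=0.1,
                             broadband_sd=0, burst_rate=0), seed=1)
        contamination = noisy.samples - noisy.clean_samples
        freqs = np.fft.rfftfreq(contamination.size, 1 / default_record.fs)
        spectrum = np.abs(np.fft.rfft(contamination))
        assert abs(freqs[np.argmax(spectrum)] - 50.0) < 0.2

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            synth.NoiseModel(wander_amp=-0.1)


class TestMakeDataset:
    def test_uniform_mix_gives_exact_counts_and_split(self):
        ds = synth.make_dataset(100, seed=0)
        counts = {lab: int(np.sum(ds.class_labels == lab))
                  for lab in synth.CLASS_LABELS}
        assert all(c == 25 for c in counts.values())
        assert len(ds.train_idx) == 80 and len(ds.test_idx) == 20

    def test_nonuniform_mix_respected(self):
        ds = synth.make_dataset(200, class_mix=(0.4, 0.2, 0.2, 0.2), seed=0)
        assert int(np.sum(ds.class_labels == "NR")) == 80
        assert all(int(np.sum(ds.class_labels == lab)) == 40
                   for lab in ("AR", "AH", "MI"))

    def test_same_seed_reproduces_dataset_bitwise(self):
        a = synth.make_dataset(40, seed=7, noise=synth.NoiseModel())
        b = synth.make_dataset(40, seed=7, noise=synth.NoiseModel())
        for ra, rb in zip(a.records, b.records):
            assert cio.record_fingerprint(ra) == cio.record_fingerprint(rb)
        assert np.array_equal(a.train_idx, b.train_idx)

    def test_split_is_stratified_by_class(self):
        ds = synth.make_dataset(100, seed=3)
        for lab in synth.CLASS_LABELS:
            in_test = np.sum(ds.class_labels[ds.test_idx] == lab)
            assert in_test == 5

    def test_too_small_dataset_rejected(self):
        with pytest.raises(ValueError):
            synth.make_dataset(5)
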