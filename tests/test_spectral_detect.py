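"""Spectrogram, noise profile and the band-limited energy detector."""

import numpy as np
import pytest

import batdialect as bd
from batdialect.calls import ARCHETYPES, ScheduledCall


def tone(freq_hz, dur_s, fs=256_000, amp=0.5):
    t = np.arange(int(dur_s * fs)) / fs
    return amp * np.sin(2 * np.pi * freq_hz * t)


class TestSpectrogram:
    def test_single_tone_localised_within_one_bin(self):
        audio = bd.AudioRecording(tone(40_000, 1.0), 256_000)
        spec = bd.compute_spectrogram(audio)
        peak_bin = np.unravel_index(np.argmax(spec.power), spec.power.shape)[1]
        assert abs(spec.bin_freqs_hz[peak_bin] - 40_000) <= 250.0
        assert spec.bin_width_hz == pytest.approx(250.0)
        assert spec.hop_s == pytest.approx(0.002)

    def test_all_zero_input_gives_all_zero_power(self):
        spec = bd.compute_spectrogram(bd.AudioRecording(np.zeros(4096), 256_000))
        assert np.all(spec.power == 0.0)

    def test_frame_count_formula(self):
        spec = bd.compute_spectrogram(bd.AudioRecording(np.zeros(4096), 256_000))
        assert spec.n_frames == 7  # floor((4096 - 1024)/512) + 1

    def test_too_short_audio_raises(self):
        with pytest.raises(ValueError, match="shorter than one window"):
            bd.compute_spectrogram(bd.AudioRecording(np.zeros(512), 256_000))


class TestNoiseProfile:
    def test_white_noise_profile_close_to_direct_percentile_oracle(self):
        rng = np.random.default_rng(0)
        audio = bd.AudioRecording(1e-2 * rng.standard_normal(256_000 * 10),
                                  256_000)
        spec = bd.compute_spectrogram(audio)
        prof = bd.estimate_noise_profile(spec)
        # oracle: same block/percentile computation written longhand
        fpb = int(round(2.0 / spec.hop_s))
        step = int(round(0.5 / spec.hop_s))
        blocks = [spec.power[s:s + fpb].mean(axis=0)
                  for s in range(0, spec.n_frames - fpb + 1, step)]
        oracle = np.percentile(np.stack(blocks), 20, axis=0)
        assert np.allclose(prof.noise_power, oracle)
        # and the profile is flat across interior bins (within sampling error)
        interior = prof.noise_power[5:-5]
        assert interior.max() / interior.min() < 2.0

    def test_constant_power_input_returns_that_power(self):
        spec = bd.compute_spectrogram(bd.AudioRecording(np.zeros(256_000 * 3),
                                                        256_000))
        spec.power[:] = 7.5
        prof = bd.estimate_noise_profile(spec)
        assert np.allclose(prof.noise_power, 7.5)

    def test_loud_transient_barely_moves_the_profile(self):
        """A 0.1 s transient occupies <20% of 2 s blocks in a 10 s
        recording, so the 20th-percentile profile stays near noise-only."""
        rng = np.random.default_rng(1)
        x = 1e-2 * rng.standard_normal(256_000 * 10)
        clean = bd.estimate_noise_profile(
            bd.compute_spectrogram(bd.AudioRecording(x.copy(), 256_000)))
        burst = tone(30_000, 0.1, amp=0.9)
        burst *= np.hanning(burst.size)  # no broadband edge clicks
        x[5 * 256_000:5 * 256_000 + 25_600] += burst
        dirty = bd.estimate_noise_profile(
            bd.compute_spectrogram(bd.AudioRecording(x, 256_000)))
        ratio = dirty.noise_power / clean.noise_power
        assert np.all(np.abs(ratio - 1.0) < 0.05)

    def test_recording_shorter_than_block_raises(self):
        spec = bd.compute_spectrogram(bd.AudioRecording(np.zeros(256_000),
                                                        256_000))
        with pytest.raises(ValueError, match="noise"):
            bd.estimate_noise_profile(spec, block_s=2.0)


def noisy_background(dur_s, fs=256_000, sigma=1e-3, seed=0):
    rng = np.random.default_rng(seed)
    return sigma * rng.standard_normal(int(dur_s * fs))


class TestDetector:
    def test_two_tones_with_short_gap_merge_into_one_detection(self):
        fs = 256_000
        x = noisy_background(6.0, fs)
        i0 = 3 * fs
        t1 = tone(30_000, 0.05, fs, amp=0.1)
        x[i0:i0 + t1.size] += t1
        gap = int(0.05 * fs)
        x[i0 + t1.size + gap:i0 + 2 * t1.size + gap] += t1
        spec = bd.compute_spectrogram(bd.AudioRecording(x, fs))
        dets = bd.detect_calls(spec, bd.estimate_noise_profile(spec))
        assert len(dets) == 1
        assert dets[0].duration_s == pytest.approx(0.15, abs=0.02)

    def test_tones_separated_by_more_than_min_sep_stay_apart(self):
        fs = 256_000
        x = noisy_background(6.0, fs)
        t1 = tone(30_000, 0.05, fs, amp=0.1)
        x[3 * fs:3 * fs + t1.size] += t1
        j = 3 * fs + t1.size + int(0.2 * fs)
        x[j:j + t1.size] += t1
        spec = bd.compute_spectrogram(bd.AudioRecording(x, fs))
        dets = bd.detect_calls(spec, bd.estimate_noise_profile(spec))
        assert len(dets) == 2

    def test_ten_millisecond_tone_is_below_minimum_duration(self):
        fs = 256_000
        x = noisy_background(6.0, fs)
        t1 = tone(30_000, 0.010, fs, amp=0.1)
        x[3 * fs:3 * fs + t1.size] += t1
        spec = bd.compute_spectrogram(bd.AudioRecording(x, fs))
        assert bd.detect_calls(spec, bd.estimate_noise_profile(spec)) == []

    def test_planted_calls_recovered_with_perfect_precision_recall(self, planted):
        scene, spec, noise, dets = planted
        assert len(dets) == len(scene.events) == 10
        for det in dets:
            overlapping = [ev for ev in scene.events
                           if det.begin_s < ev["offset_s"]
                           and det.end_s > ev["onset_s"]]
            assert len(overlapping) == 1

    def test_noise_only_audio_yields_zero_detections(self):
        audio = bd.AudioRecording(noisy_background(15.0, seed=42), 256_000)
        spec = bd.compute_spectrogram(audio)
        assert bd.detect_calls(spec, bd.estimate_noise_profile(spec)) == []

    def test_translation_by_whole_hops_shifts_detections_exactly(self):
        fs = 256_000
        x = noisy_background(8.0, fs, seed=2)
        call = bd.synthesize_call(ARCHETYPES["ultrasonic_social"], fs, seed=0)
        i0 = 3 * fs
        x[i0:i0 + call.samples.size] += 0.3 * call.samples

        def detect(sig):
            spec = bd.compute_spectrogram(bd.AudioRecording(sig, fs))
            return bd.detect_calls(spec, bd.estimate_noise_profile(spec))

        base = detect(x)
        k = 50  # shift by 50 hops = 25600 samples
        shifted = detect(np.roll(x, k * 512))
        assert len(base) == len(shifted) == 1
        assert shifted[0].begin_s - base[0].begin_s == pytest.approx(
            k * 512 / fs, abs=1e-12)
        assert shifted[0].end_s - base[0].end_s == pytest.approx(
            k * 512 / fs, abs=1e-12)

    def test_empty_band_raises(self, planted):
        _, spec, noise, _ = planted
        with pytest.raises(ValueError, match="empty"):
            bd.detect_calls(spec, noise, low_khz=50, high_khz=10)

    def test_detections_sorted_by_begin_time(self, planted):
        _, _, _, dets = planted
        begins = [d.begin_s for d in dets]
        assert begins == sorted(begins)
        for d in dets:
            assert 0.02 <= d.duration_s <= 5.0
            assert 0.0 <= d.occupancy_frac <= 1.0
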