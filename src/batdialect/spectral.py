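"""Short-time power spectrograms and percentile noise profiles.

The spectrogram follows the measurement chain's settings: Hann window of
1024 samples, 50% overlap (hop 512), one-sided power, no zero padding.
At 256 kHz that is a 250 Hz bin width and a 2 ms frame hop; the frame
count for N samples is floor((N - 1024) / 512) + 1.

The noise profile is the per-bin 20th percentile (by default) of block-mean
power over 2 s blocks hopped every 0.5 s, i.e. a robust floor that a sparse
transient cannot inflate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import get_window

from .audioio import AudioRecording

__all__ = ["Spectrogram", "NoiseProfile", "compute_spectrogram",
           "estimate_noise_profile", "DEFAULT_WINDOW", "DEFAULT_HOP"]

DEFAULT_WINDOW = 1024
DEFAULT_HOP = 512
DB_FLOOR = -120.0


@dataclass
class Spectrogram:
    power: np.ndarray          # frames x bins, linear power
    frame_times_s: np.ndarray  # centre time of each frame
    bin_freqs_hz: np.ndarray   # centre frequency of each bin
    window_samples: int
    hop_samples: int
    sample_rate_hz: int

    @property
    def n_frames(self) -> int:
        return self.power.shape[0]

    @property
    def n_bins(self) -> int:
        return self.power.shape[1]

    @property
    def hop_s(self) -> float:
        return self.hop_samples / self.sample_rate_hz

    @property
    def bin_width_hz(self) -> float:
        return self.sample_rate_hz / self.window_samples

    def power_db(self) -> np.ndarray:
        return 10.0 * np.log10(np.maximum(self.power, 10.0 ** (DB_FLOOR / 10.0)))


def compute_spectrogram(audio: AudioRecording,
                        window_samples: int = DEFAULT_WINDOW,
                        hop_samples: int = DEFAULT_HOP) -> Spectrogram:
    """Hann-windowed one-sided power spectrogram (no zero padding)."""
    x = audio.samples
    if x.size < window_samples:
        raise ValueError(
            f"audio ({x.size} samples) shorter than one window "
            f"({window_samples} samples)")
    frames = sliding_window_view(x, window_samples)[::hop_samples]
    win = get_window("hann", window_samples, fftbins=True)
    spec = np.fft.rfft(frames * win, axis=1)
    power = (spec.real ** 2 + spec.imag ** 2)
    fs = audio.sample_rate_hz
    n_frames = frames.shape[0]
    starts = np.arange(n_frames) * hop_samples
    return Spectrogram(
        power=power,
        frame_times_s=(starts + window_samples / 2.0) / fs,
        bin_freqs_hz=np.fft.rfftfreq(window_samples, d=1.0 / fs),
        window_samples=window_samples,
        hop_samples=hop_samples,
        sample_rate_hz=fs,
    )


@dataclass
class NoiseProfile:
    noise_power: np.ndarray  # per-bin linear power, same bin axis as source
    block_s: float
    hop_s: float
    percentile: float


def estimate_noise_profile(spec: Spectrogram, block_s: float = 2.0,
                           hop_s: float = 0.5,
                           percentile: float = 20.0) -> NoiseProfile:
    """Per-bin percentile of block-mean power across overlapping blocks."""
    frame_hop = spec.hop_s
    frames_per_block = int(round(block_s / frame_hop))
    if spec.n_frames < frames_per_block:
        raise ValueError(
            f"recording ({spec.n_frames} frames) shorter than one noise "
            f"block ({frames_per_block} frames)")
    step = max(1, int(round(hop_s / frame_hop)))
    starts = range(0, spec.n_frames - frames_per_block + 1, step)
    block_means = np.stack([
        spec.power[s:s + frames_per_block].mean(axis=0) for s in starts
    ])
    prof = np.percentile(block_means, percentile, axis=0)
    return NoiseProfile(prof, block_s, hop_s, percentile)
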