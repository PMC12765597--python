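"""The seven spectrographic call measurements.

Within a detection's time x band window:

* F_peak  - centre frequency of the global power maximum (kHz)
* PFC     - peak frequency contour: per-frame argmax frequency, traced over
            the detector's on-frames so silent gaps inside a multi-element
            call do not contribute noise argmaxes
* F_max / F_min - extrema of the contour (kHz)
* BW_90   - frequency span between the 5% and 95% points of the cumulative
            in-band energy spectrum (energy summed over frames), kHz
* BW_IQR  - as BW_90 but between the 25% and 75% points
* Length  - number of spectrogram frames in the detection
* Peak time - time from detection start to the frame holding the global
            power maximum (s)

All measurements are ratios of spectrogram quantities, hence invariant to
global amplitude scaling of the audio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detect import Detection
from .spectral import Spectrogram

__all__ = ["CallFeatures", "measure_call", "features_to_frame",
           "FEATURE_NAMES"]

FEATURE_NAMES = ["bw90_khz", "bw_iqr_khz", "f_peak_khz", "f_max_khz",
                 "f_min_khz", "length_frames", "peak_time_s"]


@dataclass
class CallFeatures:
    bw90_khz: float
    bw_iqr_khz: float
    f_peak_khz: float
    f_max_khz: float
    f_min_khz: float
    length_frames: int
    peak_time_s: float
    colony: str | None = None
    call_type: str | None = None

    def __post_init__(self) -> None:
        if not (self.f_min_khz <= self.f_peak_khz <= self.f_max_khz):
            raise ValueError("expected f_min <= f_peak <= f_max")
        if self.bw_iqr_khz > self.bw90_khz + 1e-9:
            raise ValueError("expected bw_iqr <= bw90")
        if self.length_frames < 1:
            raise ValueError("length_frames must be >= 1")

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in FEATURE_NAMES}
        d["colony"] = self.colony
        d["call_type"] = self.call_type
        return d


def _energy_quantile_freq(energy: np.ndarray, freqs: np.ndarray,
                          bin_width: float, q: float) -> float:
    """Frequency at cumulative-energy fraction q, linear within bins."""
    cum = np.cumsum(energy)
    total = cum[-1]
    target = q * total
    k = int(np.searchsorted(cum, target))
    k = min(k, len(energy) - 1)
    prev = cum[k - 1] if k > 0 else 0.0
    frac = (target - prev) / energy[k] if energy[k] > 0 else 0.5
    left_edge = freqs[k] - bin_width / 2.0
    return left_edge + frac * bin_width


def measure_call(spec: Spectrogram, det: Detection) -> CallFeatures:
    """Compute the seven measurements for one detection."""
    if det.frame_stop >= spec.n_frames:
        raise ValueError("detection extends past the spectrogram")
    band = ((spec.bin_freqs_hz >= det.low_freq_hz - 1e-9)
            & (spec.bin_freqs_hz <= det.high_freq_hz + 1e-9))
    if not band.any():
        raise ValueError("detection band contains no spectrogram bins")
    freqs = spec.bin_freqs_hz[band]
    frames = np.arange(det.frame_start, det.frame_stop + 1)
    window = spec.power[np.ix_(frames, np.flatnonzero(band))]
    if window.sum() <= 0:
        raise ValueError("zero-energy detection window")

    # peak frequency contour over on-frames (all frames if none recorded)
    on = det.on_frames if det.on_frames.size else frames
    contour_rows = np.asarray(on) - det.frame_start
    contour_rows = contour_rows[(contour_rows >= 0)
                                & (contour_rows < window.shape[0])]
    sub = window[contour_rows]
    contour = freqs[np.argmax(sub, axis=1)]
    f_max, f_min = float(contour.max()), float(contour.min())

    # global peak (searched over the same frames the contour traces, so
    # f_min <= f_peak <= f_max holds by construction)
    pk_row, pk_bin = np.unravel_index(np.argmax(sub), sub.shape)
    f_peak = freqs[pk_bin]
    peak_time = contour_rows[pk_row] * spec.hop_s

    energy = window.sum(axis=0)
    bw = spec.bin_width_hz
    f05 = _energy_quantile_freq(energy, freqs, bw, 0.05)
    f95 = _energy_quantile_freq(energy, freqs, bw, 0.95)
    f25 = _energy_quantile_freq(energy, freqs, bw, 0.25)
    f75 = _energy_quantile_freq(energy, freqs, bw, 0.75)

    return CallFeatures(
        bw90_khz=(f95 - f05) / 1000.0,
        bw_iqr_khz=(f75 - f25) / 1000.0,
        f_peak_khz=float(f_peak) / 1000.0,
        f_max_khz=f_max / 1000.0,
        f_min_khz=f_min / 1000.0,
        length_frames=len(frames),
        peak_time_s=float(peak_time),
    )


def features_to_frame(features: list[CallFeatures]) -> pd.DataFrame:
    """Stack measurements into a table (one row per detection)."""
    return pd.DataFrame([f.as_dict() for f in features])
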