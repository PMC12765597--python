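"""Audio containers and WAV / Raven-style selection table I/O."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.io import wavfile

__all__ = ["AudioRecording", "read_wav", "write_selection_table",
           "read_selection_table"]

SELECTION_COLUMNS = ["Selection", "Begin Time (s)", "End Time (s)",
                     "Low Freq (Hz)", "High Freq (Hz)", "Annotation"]


@dataclass
class AudioRecording:
    """A mono waveform: float samples (|x| <= 1) plus a sample rate."""

    samples: np.ndarray
    sample_rate_hz: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate_hz

    def scaled(self, gain: float) -> "AudioRecording":
        return AudioRecording(self.samples * gain, self.sample_rate_hz)

    def write_wav(self, path, dtype: str = "float32") -> None:
        """Write WAV as IEEE float32 (default) or PCM 16-bit."""
        if dtype == "float32":
            wavfile.write(path, self.sample_rate_hz,
                          self.samples.astype(np.float32))
        elif dtype == "int16":
            clipped = np.clip(self.samples, -1.0, 1.0)
            wavfile.write(path, self.sample_rate_hz,
                          (clipped * 32767).astype(np.int16))
        else:
            raise ValueError(f"unsupported dtype {dtype!r}")


def read_wav(path) -> AudioRecording:
    rate, data = wavfile.read(path)
    if data.ndim > 1:
        data = data[:, 0]
    if data.dtype == np.int16:
        data = data.astype(np.float64) / 32767.0
    elif data.dtype == np.int32:
        data = data.astype(np.float64) / 2147483647.0
    else:
        data = data.astype(np.float64)
    return AudioRecording(data, int(rate))


def write_selection_table(path, rows: list[dict]) -> None:
    """Write a Raven-style selection table (tab-separated).

    Each row dict must provide begin_s, end_s, low_freq_hz, high_freq_hz
    and may provide annotation.
    """
    records = []
    for i, r in enumerate(rows, start=1):
        records.append({
            "Selection": i,
            "Begin Time (s)": r["begin_s"],
            "End Time (s)": r["end_s"],
            "Low Freq (Hz)": r["low_freq_hz"],
            "High Freq (Hz)": r["high_freq_hz"],
            "Annotation": r.get("annotation", ""),
        })
    pd.DataFrame(records, columns=SELECTION_COLUMNS).to_csv(
        path, sep="\t", index=False)


def read_selection_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
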