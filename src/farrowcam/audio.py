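"""Multichannel WAV I/O (RIFF, 32-bit float) via scipy."""
from __future__ import annotations

from pathlib import Path

import numpy as np
from scipy.io import wavfile


def write_wav(path: str | Path, signals: np.ndarray, fs: float) -> None:
    """Write (n_channels, n_samples) float32 signals as a multichannel WAV."""
    sig = np.asarray(signals, dtype=np.float32)
    if sig.ndim != 2:
        raise ValueError("signals must be 2-D (n_channels, n_samples)")
    wavfile.write(str(path), int(round(fs)), np.ascontiguousarray(sig.T))


def read_wav(path: str | Path) -> tuple[float, np.ndarray]:
    """Read a WAV file; returns (fs, (n_channels, n_samples) float32)."""
    fs, data = wavfile.read(str(path))
    if data.ndim == 1:
        data = data[:, None]
    if data.dtype.kind == "i":  # normalise integer PCM
        data = data.astype(np.float32) / float(np.iinfo(data.dtype).max)
    return float(fs), np.ascontiguousarray(data.T.astype(np.float32))
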