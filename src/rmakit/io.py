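"""Small I/O helpers: array-spec YAML and mono WAV round-trips."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml
from scipy.io import wavfile

from .sensor import ArraySpec, ResonatorChannel

__all__ = ["load_array_spec", "save_array_spec", "read_wav", "write_wav"]


def save_array_spec(array: ArraySpec, path: str | Path) -> None:
    doc = {
        "sample_rate": float(array.sample_rate),
        "channels": [
            {"f0": ch.f0, "q": ch.q, "peak_sensitivity": ch.peak_sensitivity}
            for ch in array.channels
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_array_spec(path: str | Path) -> ArraySpec:
    doc = yaml.safe_load(Path(path).read_text())
    channels = tuple(
        ResonatorChannel(
            f0=float(ch["f0"]), q=float(ch["q"]),
            peak_sensitivity=float(ch["peak_sensitivity"]),
        )
        for ch in doc["channels"]
    )
    return ArraySpec(channels=channels, sample_rate=float(doc["sample_rate"]))


def write_wav(path: str | Path, waveform: np.ndarray, fs: float) -> None:
    """Write a [-1, 1] float waveform as 16-bit PCM mono WAV."""
    pcm = np.round(np.clip(waveform, -1.0, 1.0) * 32767).astype(np.int16)
    wavfile.write(Path(path), int(fs), pcm)


def read_wav(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a mono WAV as a float waveform in [-1, 1] plus its sample rate."""
    fs, data = wavfile.read(Path(path))
    if data.ndim != 1:
        raise ValueError(f"{path}: expected mono audio, got shape {data.shape}")
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return np.asarray(data, dtype=float), float(fs)
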