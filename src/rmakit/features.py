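"""Frame-level Mel-spectrum features, by two routes.

Route (a), the resonant-array path: the audio has already been filtered
acoustically by the resonator bank, so a feature frame is simply the
log-energy of each channel over a 40 ms frame -- no FFT anywhere.

Route (b), the conventional path: magnitude-squared FFT of each frame
followed by a bank of triangular filters with Mel-uniform centre
frequencies, then log compression.  With 8 filters spanning the array's
band the two routes measure the same spectral summary, one acoustically and
one digitally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cantilever import ValidationError, mel_forward, mel_inverse

__all__ = [
    "LOG_FLOOR",
    "FrameSet",
    "frame_signal",
    "rma_energy_features",
    "triangular_filterbank",
    "mel_filterbank_features",
]

#: Floor added inside the log to keep silent frames finite.
LOG_FLOOR = 1e-12


@dataclass(frozen=True)
class FrameSet:
    """Contiguous frames cut from one waveform."""

    frames: np.ndarray = field(repr=False)  # (n_frames, frame_length)
    frame_length: int
    hop: int
    fs: float
    recording_id: str = ""

    def __len__(self) -> int:
        return len(self.frames)


def frame_signal(
    waveform,
    fs: float,
    frame_ms: float = 40.0,
    hop_ms: float | None = None,
    recording_id: str = "",
) -> FrameSet:
    """Cut a waveform into fixed-length frames (non-overlapping by default).

    The trailing partial frame is dropped; a signal shorter than one frame
    yields an empty FrameSet.
    """
    x = np.asarray(waveform, dtype=float)
    if fs <= 0 or frame_ms <= 0:
        raise ValidationError("fs and frame_ms must be > 0")
    frame_len = int(round(frame_ms * fs / 1000.0))
    hop = frame_len if hop_ms is None else int(round(hop_ms * fs / 1000.0))
    if hop < 1 or frame_len < 1:
        raise ValidationError("frame and hop must be at least one sample")
    n_frames = max(0, (len(x) - frame_len) // hop + 1) if len(x) >= frame_len else 0
    idx = np.arange(frame_len)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = x[idx] if n_frames else np.empty((0, frame_len))
    return FrameSet(
        frames=frames, frame_length=frame_len, hop=hop, fs=fs, recording_id=recording_id
    )


def rma_energy_features(
    channel_waveforms, fs: float, frame_ms: float = 40.0, hop_ms: float | None = None
) -> np.ndarray:
    """Log frame energies of the array channels: feature[t, k] = log(E + eps).

    ``channel_waveforms`` is an ``(n_channels, n_samples)`` matrix, one row
    per resonant microphone.  E is the plain sum of squared samples per
    frame; no transform is involved on this path.
    """
    rows = [np.asarray(ch, dtype=float) for ch in channel_waveforms]
    if any(r.ndim != 1 for r in rows) or len({len(r) for r in rows}) > 1:
        raise ValidationError("channel lengths differ")
    chans = np.stack(rows)
    feats = []
    n_frames = None
    for ch in chans:
        fset = frame_signal(ch, fs, frame_ms, hop_ms)
        if n_frames is None:
            n_frames = len(fset)
        elif len(fset) != n_frames:
            raise ValidationError("channel lengths differ")
        feats.append(np.log(np.sum(fset.frames**2, axis=1) + LOG_FLOOR))
    return np.stack(feats, axis=1)


def triangular_filterbank(
    fs: float, n_fft: int, n_filters: int, band: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Unit-peak triangular filters with Mel-uniform centres spanning ``band``.

    Centres include the band endpoints; the outer triangle edges extend one
    Mel gap beyond them and are clipped at the band edges, so the first and
    last filters keep only their in-band half.

    Returns ``(weights, centers_hz)`` with weights of shape
    ``(n_filters, n_fft//2 + 1)``.
    """
    lo, hi = band
    if not 0 < lo < hi < fs / 2:
        raise ValidationError("band must lie within (0, Nyquist)")
    if n_filters < 1:
        raise ValidationError("need n_filters >= 1")
    mel_lo, mel_hi = mel_forward(lo), mel_forward(hi)
    if n_filters == 1:
        centers_mel = np.array([(mel_lo + mel_hi) / 2])
        gap = (mel_hi - mel_lo) / 2
    else:
        centers_mel = np.linspace(mel_lo, mel_hi, n_filters)
        gap = centers_mel[1] - centers_mel[0]
    edges_mel = np.concatenate([[centers_mel[0] - gap], centers_mel, [centers_mel[-1] + gap]])
    edges_hz = mel_inverse(np.maximum(edges_mel, 0.0))
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / fs)
    weights = np.zeros((n_filters, len(freqs)))
    for k in range(n_filters):
        f_l, f_c, f_r = edges_hz[k], edges_hz[k + 1], edges_hz[k + 2]
        rising = (freqs - f_l) / (f_c - f_l)
        falling = (f_r - freqs) / (f_r - f_c)
        tri = np.clip(np.minimum(rising, falling), 0.0, 1.0)
        tri[(freqs < lo) | (freqs > hi)] = 0.0  # clip at band edges
        weights[k] = tri
    centers_hz = mel_inverse(centers_mel)
    return weights, centers_hz


def mel_filterbank_features(
    waveform,
    fs: float,
    frame_ms: float = 40.0,
    n_filters: int = 8,
    band: tuple[float, float] = (200.0, 800.0),
    hop_ms: float | None = None,
    window: str | None = None,
) -> np.ndarray:
    """FFT + triangular Mel filterbank features: log filter energies per frame.

    Per frame: magnitude-squared FFT (zero-padded to the next power of two,
    rectangular window unless ``window='hann'``), triangular Mel filters
    over ``band``, then ``log(sum + eps)``.
    """
    fset = frame_signal(waveform, fs, frame_ms, hop_ms)
    n_fft = 1 << (fset.frame_length - 1).bit_length()
    weights, _ = triangular_filterbank(fs, n_fft, n_filters, band)
    frames = fset.frames
    if window == "hann":
        frames = frames * np.hanning(fset.frame_length)
    elif window is not None:
        raise ValidationError(f"unknown window {window!r}")
    power = np.abs(np.fft.rfft(frames, n=n_fft, axis=1)) ** 2
    return np.log(power @ weights.T + LOG_FLOOR)
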