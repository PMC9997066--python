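"""Second-order resonator model of the microphone array, noise and SNR.

Each microphone channel is a damped second-order resonance with peak
sensitivity ``S_peak`` (V/Pa) anchored at its resonance frequency ``f0``:

    |H(f)| = S_peak * (f0^2/Q) / sqrt((f0^2 - f^2)^2 + (f f0 / Q)^2)

so ``|H(f0)| = S_peak`` exactly and the DC sensitivity is ``S_peak/Q``.
The digital realisation bilinear-transforms this prototype with frequency
pre-warping at ``f0``, which preserves the peak gain exactly at ``f0``.

Noise arithmetic follows standard electro-acoustic practice: the noise
floor in pascals is the input-referred RMS noise voltage divided by the
sensitivity; in dB it is referred to 20 uPa; the SNR for a 1 Pa tone is
94 dB minus the noise floor in dB (94 dB being the SPL of 1 Pa).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import signal

from .cantilever import ValidationError, mel_spaced_frequencies

__all__ = [
    "ResonatorChannel",
    "ArraySpec",
    "NoiseSpec",
    "resonator_response",
    "extract_q",
    "biquad_coefficients",
    "apply_array_filter",
    "spl_db",
    "a_weighting_db",
    "noise_floor_and_snr",
    "default_array",
]


@dataclass(frozen=True)
class ResonatorChannel:
    """One microphone channel: resonance f0 (Hz), quality factor Q and
    peak (at-resonance) sensitivity (V/Pa)."""

    f0: float
    q: float
    peak_sensitivity: float

    def __post_init__(self) -> None:
        if self.f0 <= 0:
            raise ValidationError("f0 must be > 0")
        if self.q <= 0.5:
            raise ValidationError("Q must be > 0.5 (underdamped resonance)")
        if self.peak_sensitivity <= 0:
            raise ValidationError("peak sensitivity must be > 0")


@dataclass(frozen=True)
class ArraySpec:
    """Ordered bank of resonator channels plus the digital sample rate."""

    channels: tuple[ResonatorChannel, ...]
    sample_rate: float = 4000.0

    def __post_init__(self) -> None:
        f0s = [ch.f0 for ch in self.channels]
        if any(b <= a for a, b in zip(f0s, f0s[1:])):
            raise ValidationError("channel f0 must be strictly increasing")
        if any(f >= self.sample_rate / 2 for f in f0s):
            raise ValidationError("every f0 must be below Nyquist")

    def __len__(self) -> int:
        return len(self.channels)

    @property
    def f0s(self) -> np.ndarray:
        return np.array([ch.f0 for ch in self.channels])


@dataclass(frozen=True)
class NoiseSpec:
    """Input-referred RMS noise voltages over an observation band."""

    input_referred_rms: float
    a_weighted_rms: float
    band: tuple[float, float] = (20.0, 20000.0)

    def __post_init__(self) -> None:
        if self.input_referred_rms < 0 or self.a_weighted_rms < 0:
            raise ValidationError("RMS noise voltages must be >= 0")
        if self.a_weighted_rms > self.input_referred_rms:
            raise ValidationError("A-weighted RMS cannot exceed unweighted RMS")


def resonator_response(channel: ResonatorChannel, freqs) -> np.ndarray:
    """Magnitude sensitivity |H(f)| in V/Pa on the given frequency grid."""
    f = np.asarray(freqs, dtype=float)
    if np.any(f < 0):
        raise ValidationError("frequencies must be >= 0")
    f0, q = channel.f0, channel.q
    num = f0**2 / q
    den = np.sqrt((f0**2 - f**2) ** 2 + (f * f0 / q) ** 2)
    return channel.peak_sensitivity * num / den


def extract_q(freqs, magnitudes) -> tuple[float, float]:
    """Estimate (f0, Q) from a sampled magnitude curve.

    f0 is the argmax refined by three-point parabolic interpolation; Q is
    f0 divided by the -3 dB bandwidth, with the half-power (1/sqrt(2) of
    peak amplitude) crossings located by linear interpolation on each side
    of the peak.
    """
    f = np.asarray(freqs, dtype=float)
    mag = np.asarray(magnitudes, dtype=float)
    if f.shape != mag.shape or f.ndim != 1 or len(f) < 3:
        raise ValidationError("freqs and magnitudes must be matching 1-D arrays")
    i = int(np.argmax(mag))
    if 0 < i < len(f) - 1:
        y0, y1, y2 = mag[i - 1 : i + 2]
        denom = y0 - 2 * y1 + y2
        delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        f0 = f[i] + delta * (f[i + 1] - f[i])
        peak = y1 - 0.25 * (y0 - y2) * delta
    else:
        f0, peak = float(f[i]), float(mag[i])
    target = peak / np.sqrt(2.0)

    def _cross(lo_side: bool) -> float:
        idx = range(i, 0, -1) if lo_side else range(i, len(f) - 1)
        for j in idx:
            a, b = (j - 1, j) if lo_side else (j, j + 1)
            if (mag[a] - target) * (mag[b] - target) <= 0 and mag[a] != mag[b]:
                t = (target - mag[a]) / (mag[b] - mag[a])
                return float(f[a] + t * (f[b] - f[a]))
        raise ValidationError(
            "bandwidth unresolved: -3 dB crossing outside the sampled range"
        )

    f_lo, f_hi = _cross(True), _cross(False)
    return float(f0), float(f0 / (f_hi - f_lo))


def biquad_coefficients(
    channel: ResonatorChannel, fs: float
) -> tuple[np.ndarray, np.ndarray]:
    """Digital (b, a) for the resonator, bilinear transform pre-warped at f0.

    Pre-warping maps the analog resonance to exactly ``f0`` on the digital
    frequency axis, so the steady tone gain at f0 equals ``peak_sensitivity``
    up to rounding.
    """
    if channel.f0 >= fs / 2:
        raise ValidationError("f0 must be below Nyquist for the digital filter")
    w0 = 2 * fs * np.tan(np.pi * channel.f0 / fs)  # pre-warped analog resonance
    s_pk, q = channel.peak_sensitivity, channel.q
    b_analog = [s_pk * w0**2 / q]
    a_analog = [1.0, w0 / q, w0**2]
    b, a = signal.bilinear(b_analog, a_analog, fs)
    return b, a


def apply_array_filter(waveform, fs: float, array: ArraySpec) -> np.ndarray:
    """Filter a mono waveform through every channel of the array.

    Returns an ``(n_channels, n_samples)`` matrix; each row is the pressure
    signal as seen through that resonant microphone, in volts for a
    waveform in pascals.
    """
    x = np.asarray(waveform, dtype=float)
    if x.ndim != 1:
        raise ValidationError("waveform must be mono (1-D)")
    if not np.all(np.isfinite(x)):
        raise ValidationError("waveform contains non-finite samples")
    if fs != array.sample_rate:
        raise ValidationError(
            f"sample rate {fs} Hz does not match array spec {array.sample_rate} Hz"
        )
    out = np.empty((len(array), len(x)))
    for k, ch in enumerate(array.channels):
        b, a = biquad_coefficients(ch, fs)
        out[k] = signal.lfilter(b, a, x)
    return out


def spl_db(pressure: float) -> float:
    """Sound pressure level in dB re 20 uPa."""
    if np.any(np.asarray(pressure) <= 0):
        raise ValidationError("pressure must be > 0")
    return 20.0 * np.log10(pressure / 2e-5)


# IEC 61672 A-weighting pole frequencies (Hz).
_A_POLES = (20.598997, 107.65265, 737.86223, 12194.217)


def a_weighting_db(f) -> np.ndarray | float:
    """IEC 61672 A-weighting in dB, exactly 0 dB at 1 kHz."""
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValidationError("frequency must be > 0")

    def _ra(freq):
        f2 = freq**2
        p1, p2, p3, p4 = (p**2 for p in _A_POLES)
        return (p4 * f2**2) / (
            (f2 + p1) * np.sqrt((f2 + p2) * (f2 + p3)) * (f2 + p4)
        )

    out = 20.0 * np.log10(_ra(f) / _ra(np.asarray(1000.0)))
    return float(out) if out.ndim == 0 else out


class NoiseFloorResult(NamedTuple):
    noise_floor_pa: float
    noise_floor_db: float
    snr_db: float


def noise_floor_and_snr(
    noise: NoiseSpec, sensitivity: float, a_weighted: bool = True
) -> NoiseFloorResult:
    """Noise floor (Pa and dB SPL) and SNR at 1 Pa for a given sensitivity.

    The SNR for a 1 Pa input is 94 dB (the SPL of 1 Pa) minus the noise
    floor in dB; with ``a_weighted`` the A-weighted RMS noise voltage is
    used and the result is in dBA.
    """
    if sensitivity <= 0:
        raise ValidationError("sensitivity must be > 0")
    v_rms = noise.a_weighted_rms if a_weighted else noise.input_referred_rms
    if v_rms <= 0:
        raise ValidationError("selected RMS noise voltage must be > 0")
    floor_pa = v_rms / sensitivity
    floor_db = spl_db(floor_pa)
    return NoiseFloorResult(floor_pa, floor_db, 94.0 - floor_db)


def default_array(
    fs: float = 4000.0,
    f_lo: float = 253.0,
    f_hi: float = 717.0,
    n_channels: int = 8,
    q_range: tuple[float, float] = (13.5, 22.0),
    sensitivity_range: tuple[float, float] = (0.265, 0.086),
) -> ArraySpec:
    """Reference eight-channel array spec.

    Channel resonances sit on the Mel grid between ``f_lo`` and ``f_hi``
    (rounded to the nearest Hz).  Q rises linearly with f0 from 13.5 to 22
    (smaller cantilevers are less air-damped) and the peak sensitivity falls
    log-linearly with f0 from 265 down to 86 mV/Pa, matching the measured
    end-channel anchors of the reference device.
    """
    f0s = mel_spaced_frequencies(f_lo, f_hi, n_channels).hz_rounded
    t = (f0s - f0s[0]) / (f0s[-1] - f0s[0])
    qs = q_range[0] + t * (q_range[1] - q_range[0])
    log_s = np.log10(sensitivity_range[0]) + t * (
        np.log10(sensitivity_range[1]) - np.log10(sensitivity_range[0])
    )
    channels = tuple(
        ResonatorChannel(f0=float(f), q=float(q), peak_sensitivity=float(10**ls))
        for f, q, ls in zip(f0s, qs, log_s)
    )
    return ArraySpec(channels=channels, sample_rate=fs)
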