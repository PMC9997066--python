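"""Seeded synthetic lung-sound generator.

Emulates the one property of annotated respiratory-sound corpora that the
downstream pipeline depends on: wheeze recordings carry elevated narrowband
power, concentrated roughly in the 300--600 Hz band, on top of broadband
breath noise, while non-wheeze recordings are broadband only.

A breath is band-limited Gaussian noise shaped by a raised-cosine
inspiration/expiration envelope per cycle.  A wheeze is a slowly
frequency-drifting tone (with an optional weaker second harmonic) whose
amplitude follows the breath envelope, gated to the configured respiratory
phases and scaled to a configured wheeze-to-breath power ratio.  Everything
is deterministic under a fixed seed, at both recording and dataset
granularity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .cantilever import ValidationError

__all__ = [
    "BreathModel",
    "WheezeModel",
    "BreathEnvelope",
    "LungSoundRecording",
    "breath_envelope",
    "synth_breath",
    "add_wheeze",
    "generate_dataset",
    "write_dataset",
    "band_psd_summary",
]


@dataclass(frozen=True)
class BreathModel:
    """Breath-noise parameters.

    Defaults: 4 kHz sampling (covers the 200--800 Hz wheeze band with
    margin), 2.5 s respiratory cycle with a 0.4 inspiration fraction
    (typical adult breathing), noise band-limited to 100--1000 Hz,
    RMS level 0.15 full scale.  ``base_level`` is the continuous airflow
    floor of the envelope: chest-wall lung sounds do not fall silent
    between respiratory phases, so the raised-cosine bumps sit on a
    constant pedestal.
    """

    fs: float = 4000.0
    cycle_duration: float = 2.5
    inspiration_fraction: float = 0.4
    noise_band: tuple[float, float] = (100.0, 1000.0)
    breath_level: float = 0.15
    base_level: float = 0.6

    def __post_init__(self) -> None:
        if not 0 < self.inspiration_fraction < 1:
            raise ValidationError("inspiration_fraction must be in (0, 1)")
        if not 0 <= self.base_level < 1:
            raise ValidationError("base_level must be in [0, 1)")
        lo, hi = self.noise_band
        if not 0 < lo < hi < self.fs / 2:
            raise ValidationError("noise_band must lie within (0, fs/2)")
        if self.breath_level < 0:
            raise ValidationError("breath_level must be >= 0")


@dataclass(frozen=True)
class WheezeModel:
    """Wheeze-tone parameters.

    ``center_freq_range`` is the interval the per-recording tone frequency
    is drawn from; ``drift_bandwidth`` bounds the slow frequency drift
    within a breath phase; ``power_ratio_db`` is the wheeze-to-breath power
    ratio over the gated samples (``-inf`` disables the wheeze entirely);
    ``duty`` is the fraction of each gated phase carrying the tone;
    ``phases`` selects the respiratory phases that carry it (severe
    obstruction produces biphasic wheezes, the default here).
    """

    center_freq_range: tuple[float, float] = (300.0, 600.0)
    drift_bandwidth: float = 20.0
    power_ratio_db: float = 6.0
    duty: float = 1.0
    phases: tuple[str, ...] = ("inspiration", "expiration")
    harmonic_db: float | None = -10.0

    def __post_init__(self) -> None:
        lo, hi = self.center_freq_range
        if not 0 < lo <= hi:
            raise ValidationError("center_freq_range must satisfy 0 < lo <= hi")
        if not 0 < self.duty <= 1:
            raise ValidationError("duty must be in (0, 1]")
        if np.isnan(self.power_ratio_db):
            raise ValidationError("power_ratio_db must not be NaN")
        unknown = set(self.phases) - {"inspiration", "expiration"}
        if unknown:
            raise ValidationError(f"unknown respiratory phases: {sorted(unknown)}")


@dataclass(frozen=True)
class BreathEnvelope:
    """Amplitude envelope plus per-sample respiratory-phase masks."""

    envelope: np.ndarray
    inspiration_mask: np.ndarray
    expiration_mask: np.ndarray
    fs: float

    def phase_mask(self, phases: tuple[str, ...]) -> np.ndarray:
        mask = np.zeros_like(self.inspiration_mask)
        if "inspiration" in phases:
            mask |= self.inspiration_mask
        if "expiration" in phases:
            mask |= self.expiration_mask
        return mask


@dataclass(frozen=True)
class LungSoundRecording:
    """One synthetic mono recording with its label and provenance."""

    fs: float
    waveform: np.ndarray = field(repr=False)
    label: int
    seed: int
    recording_id: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValidationError("label must be 0 (normal) or 1 (wheeze)")
        if np.max(np.abs(self.waveform), initial=0.0) > 1.0 + 1e-12:
            raise ValidationError("waveform exceeds full scale [-1, 1]")


def breath_envelope(model: BreathModel, n_cycles: int) -> BreathEnvelope:
    """Raised-cosine (Hann bump) envelope per respiratory phase."""
    n_cycle = int(round(model.cycle_duration * model.fs))
    n_insp = int(round(n_cycle * model.inspiration_fraction))
    n_exp = n_cycle - n_insp
    cycle_env = np.concatenate([np.hanning(n_insp), np.hanning(n_exp)])
    cycle_env = model.base_level + (1.0 - model.base_level) * cycle_env
    env = np.tile(cycle_env, n_cycles)
    insp = np.tile(
        np.concatenate([np.ones(n_insp, bool), np.zeros(n_exp, bool)]), n_cycles
    )
    return BreathEnvelope(
        envelope=env, inspiration_mask=insp, expiration_mask=~insp, fs=model.fs
    )


def synth_breath(
    model: BreathModel, n_cycles: int, seed: int
) -> tuple[np.ndarray, BreathEnvelope]:
    """Band-limited Gaussian breath noise under the respiratory envelope.

    Returns the waveform (RMS ``breath_level``, peak clipped to full scale
    by renormalisation only if needed) and the envelope used to shape it.
    """
    env = breath_envelope(model, n_cycles)
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(len(env.envelope))
    sos = signal.butter(
        4, model.noise_band, btype="bandpass", fs=model.fs, output="sos"
    )
    x = signal.sosfilt(sos, x) * env.envelope
    rms = np.sqrt(np.mean(x**2))
    if rms > 0 and model.breath_level > 0:
        x *= model.breath_level / rms
    else:
        x = np.zeros_like(x)
    peak = np.max(np.abs(x), initial=0.0)
    if peak > 1.0:
        x /= peak
    return x, env


def add_wheeze(
    waveform: np.ndarray,
    model: WheezeModel,
    envelope: BreathEnvelope,
    seed: int,
    center_freq: float | None = None,
) -> np.ndarray:
    """Superimpose a drifting wheeze tone on a breath waveform.

    The tone's instantaneous frequency drifts sinusoidally within
    ``drift_bandwidth`` of the centre frequency over each breath cycle; its
    amplitude follows the breath envelope, gated to the configured phases
    and duty.  The tone power over the gated samples is set relative to the
    breath power there by ``power_ratio_db``; ``-inf`` returns the input
    unchanged.  The peak is renormalised to full scale only if it exceeds 1.
    """
    x = np.asarray(waveform, dtype=float)
    if x.shape != envelope.envelope.shape:
        raise ValidationError("waveform and envelope lengths differ")
    if np.isneginf(model.power_ratio_db):
        return x.copy()
    rng = np.random.default_rng(seed)
    lo, hi = model.center_freq_range
    fc = float(rng.uniform(lo, hi)) if center_freq is None else float(center_freq)

    fs = envelope.fs
    n = len(x)
    t = np.arange(n) / fs
    # slow sinusoidal drift, one wander per ~4 s, random phase per recording
    drift = model.drift_bandwidth * np.sin(
        2 * np.pi * 0.25 * t + rng.uniform(0, 2 * np.pi)
    )
    phase = 2 * np.pi * np.cumsum(fc + drift) / fs
    tone = np.sin(phase)
    if model.harmonic_db is not None:
        tone = tone + 10 ** (model.harmonic_db / 20.0) * np.sin(2 * phase)

    gate = envelope.phase_mask(model.phases).astype(float)
    if model.duty < 1.0:
        # tone occupies the leading `duty` fraction of each gated segment
        edges = np.flatnonzero(np.diff(np.concatenate([[0.0], gate, [0.0]])))
        for start, stop in zip(edges[::2], edges[1::2]):
            keep = start + int(round(model.duty * (stop - start)))
            gate[keep:stop] = 0.0
    tone = tone * gate * envelope.envelope

    p_breath = np.mean(x[gate > 0] ** 2) if np.any(gate > 0) else 0.0
    p_tone = np.mean(tone[gate > 0] ** 2) if np.any(gate > 0) else 0.0
    if p_tone > 0 and p_breath > 0:
        tone *= np.sqrt(10 ** (model.power_ratio_db / 10.0) * p_breath / p_tone)
    y = x + tone
    peak = np.max(np.abs(y), initial=0.0)
    if peak > 1.0:
        y /= peak
    return y


def generate_dataset(
    n_wheeze: int,
    n_normal: int,
    breath_model: BreathModel | None = None,
    wheeze_model: WheezeModel | None = None,
    seed: int = 0,
    n_cycles: int = 2,
) -> list[LungSoundRecording]:
    """Generate a labelled dataset of synthetic lung-sound recordings.

    Per-recording child seeds are drawn deterministically from the master
    seed; wheeze centre frequencies are randomised per recording within the
    configured range.  Wheeze recordings come first in the returned list.
    """
    if n_wheeze < 0 or n_normal < 0:
        raise ValidationError("recording counts must be >= 0")
    breath_model = breath_model or BreathModel()
    wheeze_model = wheeze_model or WheezeModel()
    master = np.random.default_rng(seed)
    child_seeds = master.integers(0, 2**31, size=2 * (n_wheeze + n_normal))
    recordings = []
    labels = [1] * n_wheeze + [0] * n_normal
    for i, label in enumerate(labels):
        breath_seed, wheeze_seed = int(child_seeds[2 * i]), int(child_seeds[2 * i + 1])
        x, env = synth_breath(breath_model, n_cycles, breath_seed)
        params: dict = {"n_cycles": n_cycles, "breath_seed": breath_seed}
        if label == 1:
            rng = np.random.default_rng(wheeze_seed)
            fc = float(rng.uniform(*wheeze_model.center_freq_range))
            x = add_wheeze(x, wheeze_model, env, wheeze_seed, center_freq=fc)
            params.update(
                {"wheeze_seed": wheeze_seed, "center_freq": fc,
                 "power_ratio_db": wheeze_model.power_ratio_db}
            )
        recordings.append(
            LungSoundRecording(
                fs=breath_model.fs,
                waveform=x,
                label=label,
                seed=breath_seed,
                recording_id=f"rec{i:03d}_{'wheeze' if label else 'normal'}",
                params=params,
            )
        )
    return recordings


def write_dataset(
    recordings: list[LungSoundRecording], out_dir: str | Path
) -> pd.DataFrame:
    """Write recordings as 16-bit PCM WAVs plus a manifest CSV.

    Returns the manifest (filename, label, seed, centre frequency).
    """
    from scipy.io import wavfile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recordings:
        fname = f"{rec.recording_id}.wav"
        try:
            pcm = np.round(rec.waveform * 32767).astype(np.int16)
            wavfile.write(out / fname, int(rec.fs), pcm)
        except OSError as exc:
            raise OSError(f"failed to write {out / fname}: {exc}") from exc
        rows.append(
            {
                "filename": fname,
                "label": rec.label,
                "seed": rec.seed,
                "center_freq": rec.params.get("center_freq", np.nan),
            }
        )
    manifest = pd.DataFrame(
        rows, columns=["filename", "label", "seed", "center_freq"]
    )
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def band_psd_summary(
    recordings: list[LungSoundRecording], nperseg: int = 1024
) -> pd.DataFrame:
    """Per-class mean and standard deviation of Welch PSDs.

    Each recording gets a Welch-averaged periodogram on a common frequency
    grid; the summary is the mean +- std across recordings within each
    class.  Columns: ``freq_hz``, then ``{wheeze,normal}_{mean,std}``.
    """
    by_class: dict[int, list[np.ndarray]] = {0: [], 1: []}
    freqs = None
    for rec in recordings:
        f, pxx = signal.welch(rec.waveform, fs=rec.fs, nperseg=nperseg)
        if freqs is None:
            freqs = f
        by_class[rec.label].append(pxx)
    for label, name in ((1, "wheeze"), (0, "normal")):
        if not by_class[label]:
            raise ValidationError(f"no recordings in class {name!r}")
    out = {"freq_hz": freqs}
    for label, name in ((1, "wheeze"), (0, "normal")):
        stack = np.vstack(by_class[label])
        out[f"{name}_mean"] = stack.mean(axis=0)
        out[f"{name}_std"] = stack.std(axis=0)
    return pd.DataFrame(out)
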