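"""Seeded synthetic ECG: Gaussian-bump PQRST beats plus four noise classes.

Every downstream stage (denoising, embedding, training) is exercised on
these signals, so the generator is deterministic: identical configuration
including the seed produces bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps

from .signal_io import ECGRecord

__all__ = ["SynthConfig", "NoiseSpec", "NOISE_KINDS", "generate_clean_ecg", "add_noise"]

NOISE_KINDS = ("baseline_drift", "powerline", "emg", "motion_artifact", "white")

# (fractional offset within the RR interval, fractional width) per wave.
_WAVE_OFFSETS = {"P": 0.22, "Q": 0.365, "R": 0.40, "S": 0.435, "T": 0.62}
_WAVE_WIDTHS = {"P": 0.030, "Q": 0.008, "R": 0.012, "S": 0.009, "T": 0.045}

# Declared spectral bands (Hz); the EMG upper edge is clipped at 0.45*rate.
_NOISE_BANDS = {
    "baseline_drift": (0.01, 1.0),
    "motion_artifact": (5.0, 10.0),
    "emg": (10.0, 500.0),
}


@dataclass(frozen=True)
class NoiseSpec:
    """One additive noise component: kind, amplitude (mV) and optional
    characteristic frequency (Hz, used by powerline and baseline drift)."""

    kind: str
    amplitude: float
    frequency: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in NOISE_KINDS:
            raise ValueError(
                f"unknown noise kind {self.kind!r}; expected one of {NOISE_KINDS}"
            )
        if self.amplitude < 0:
            raise ValueError("noise amplitude must be non-negative")


@dataclass(frozen=True)
class SynthConfig:
    sampling_rate: float = 250.0
    duration: float = 20.0
    heart_rate: float = 75.0
    beat_amplitudes: tuple[float, float, float, float, float] = (
        0.12,
        -0.10,
        1.00,
        -0.18,
        0.30,
    )
    noise_spec: tuple[NoiseSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not 20.0 < self.heart_rate < 300.0:
            raise ValueError("heart_rate must lie in (20, 300) bpm")
        if len(self.beat_amplitudes) != 5:
            raise ValueError("beat_amplitudes must have 5 entries (P,Q,R,S,T)")
        object.__setattr__(self, "noise_spec", tuple(self.noise_spec))

    @property
    def n_samples(self) -> int:
        return int(round(self.sampling_rate * self.duration))


def generate_clean_ecg(config: SynthConfig) -> ECGRecord:
    """Quasi-periodic PQRST-like signal: five Gaussian bumps per beat at
    fixed fractional phase offsets inside each RR interval. Noise-free."""
    n = config.n_samples
    t = np.arange(n) / config.sampling_rate
    rr = 60.0 / config.heart_rate
    x = np.zeros(n)
    amplitudes = dict(zip("PQRST", config.beat_amplitudes))
    n_beats = int(np.ceil(config.duration / rr)) + 2
    for b in range(-1, n_beats):
        onset = b * rr
        for wave in "PQRST":
            mu = onset + _WAVE_OFFSETS[wave] * rr
            sig = _WAVE_WIDTHS[wave] * rr
            x += amplitudes[wave] * np.exp(-0.5 * ((t - mu) / sig) ** 2)
    return ECGRecord(
        samples=x,
        sampling_rate=config.sampling_rate,
        record_id=f"synth-hr{config.heart_rate:g}-seed{config.seed}",
    )


def _band_limited_noise(
    rng: np.random.Generator, n: int, fs: float, low: float, high: float
) -> np.ndarray:
    """Unit-variance Gaussian noise band-passed to [low, high] Hz."""
    high = min(high, 0.45 * fs)
    if high <= low:
        raise ValueError(
            f"band [{low}, {high}] Hz is empty at sampling rate {fs} Hz"
        )
    white = rng.standard_normal(n)
    sos = sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    shaped = sps.sosfiltfilt(sos, white)
    sd = shaped.std()
    return shaped / sd if sd > 0 else shaped


def _render_component(
    spec: NoiseSpec, rng: np.random.Generator, n: int, fs: float
) -> np.ndarray:
    t = np.arange(n) / fs
    if spec.kind == "powerline":
        freq = spec.frequency if spec.frequency is not None else 50.0
        if freq >= fs / 2:
            raise ValueError(
                f"powerline frequency {freq} Hz is at or above Nyquist ({fs / 2} Hz)"
            )
        phase = rng.uniform(0, 2 * np.pi)
        return spec.amplitude * np.sin(2 * np.pi * freq * t + phase)
    if spec.kind == "baseline_drift":
        # A few slow sinusoids keeps the energy inside 0.01-1 Hz exactly.
        base = spec.frequency if spec.frequency is not None else 0.25
        drift = np.zeros(n)
        for mult in (1.0, 1.7, 2.6):
            f = min(base * mult, 1.0)
            drift += rng.uniform(0.5, 1.0) * np.sin(
                2 * np.pi * f * t + rng.uniform(0, 2 * np.pi)
            )
        sd = drift.std()
        return spec.amplitude * (drift / sd if sd > 0 else drift)
    if spec.kind == "white":
        return spec.amplitude * rng.standard_normal(n)
    low, high = _NOISE_BANDS[spec.kind]
    return spec.amplitude * _band_limited_noise(rng, n, fs, low, high)


def add_noise(
    record: ECGRecord,
    noise_spec: Sequence[NoiseSpec],
    seed: int,
) -> ECGRecord:
    """Return ``record`` plus the summed noise components.

    The clean input is left untouched, so callers keep the ground truth
    needed for SNR bookkeeping. An empty spec returns an identical copy.
    """
    if len(record) == 0:
        raise ValueError("cannot add noise to an empty record")
    specs = [s if isinstance(s, NoiseSpec) else NoiseSpec(*s) for s in noise_spec]
    rng = np.random.default_rng(seed)
    noisy = record.samples.copy()
    for spec in specs:
        noisy += _render_component(spec, rng, len(record), record.sampling_rate)
    return record.with_samples(noisy, record_id=record.record_id + "+noise")


def make_noisy_pair(config: SynthConfig) -> tuple[ECGRecord, ECGRecord]:
    """Convenience: (clean, noisy) records from one config, one seed."""
    clean = generate_clean_ecg(config)
    noisy = add_noise(clean, config.noise_spec, config.seed)
    return clean, noisy
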