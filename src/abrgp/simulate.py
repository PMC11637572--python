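"""Synthetic chirp-evoked ABR epoch generation.

This module produces stimulus-locked EEG epoch ensembles with a known
ground-truth wave-V amplitude growth surface, so that every downstream stage
(preprocessing, peak-to-trough amplitude estimation, the Gaussian-process
regression and the closed-loop policy) can be exercised and validated against
a subject whose hearing thresholds are known exactly.

The model is deliberately simple but captures the features that matter for
threshold estimation from the wave-V peak-to-trough amplitude (PTTa):

* PTTa grows piecewise-linearly with stimulus level above a per-frequency
  hearing threshold and saturates (0 to ~1.25 µV range overall);
* wave-V peak latency increases as the stimulus level decreases;
* the background EEG is zero-mean band-limited (30–1500 Hz) noise with a
  configurable per-epoch RMS;
* occasional artifact epochs contain deflections exceeding ±20 µV, which the
  preprocessing stage must reject.

Epochs are generated directly at 5 kHz on the closed 0–20 ms post-stimulus
window (101 samples); the 48 kHz acquisition chain is not simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import signal

#: Sampling rate of simulated (and preprocessed) epochs, samples/s.
FS_HZ = 5000.0
#: Length of the retained post-stimulus window, ms (closed interval [0, 20]).
WINDOW_MS = 20.0
#: Samples per epoch: sample 0 sits at stimulus onset, the window is closed.
N_SAMPLES = int(round(FS_HZ * WINDOW_MS / 1000.0)) + 1
#: The four narrow-band chirp test frequencies, Hz.
FREQUENCIES_HZ = (500.0, 1000.0, 2000.0, 4000.0)
#: Band limits of the background-noise shaping filter, Hz.
NOISE_BAND_HZ = (30.0, 1500.0)
#: Reference level at which the latency law is anchored, dB HL.
LATENCY_REFERENCE_DB = 70.0
#: Artifact half-sine amplitude range, µV (only the ±20 µV exceedance matters).
ARTIFACT_AMP_RANGE_UV = (25.0, 40.0)
#: Artifact half-sine duration, ms.
ARTIFACT_DURATION_MS = 5.0


@dataclass(frozen=True)
class StimulusSpec:
    """A single test stimulus: level in dB HL, frequency in Hz.

    The frequency must belong to the four-chirp test set."""

    level: float
    frequency: float

    def __post_init__(self) -> None:
        if float(self.frequency) not in FREQUENCIES_HZ:
            raise ValueError(
                f"frequency {self.frequency} Hz not in test set {FREQUENCIES_HZ}"
            )
        if not np.isfinite(self.level):
            raise ValueError("stimulus level must be finite")


@dataclass(frozen=True)
class SubjectProfile:
    """Ground truth for one simulated subject.

    Parameters
    ----------
    thresholds
        Map frequency (Hz) -> true hearing threshold (dB HL).  Values may
        exceed the maximum test level to model profound loss.
    slope
        Suprathreshold PTTa growth, µV per dB.
    amp_max
        Saturation PTTa, µV (must lie in (0, 1.25]).
    latency0
        Wave-V peak latency at 70 dB HL, ms.
    latency_shift
        Latency increase per 10 dB of level decrease, ms.
    trough_lag
        Peak-to-trough interval, ms (must be < 8 ms so the search
        constraint of the amplitude estimator can see the full deflection).
    noise_rms
        Per-epoch background RMS, µV.  Zero is accepted and means exactly
        noiseless epochs (useful for validation).
    artifact_rate
        Probability that an epoch additionally contains a >20 µV artifact.
    """

    thresholds: Mapping[float, float]
    slope: float = 0.01
    amp_max: float = 0.6
    latency0: float = 8.0
    latency_shift: float = 0.4
    trough_lag: float = 2.0
    noise_rms: float = 5.0
    artifact_rate: float = 0.0

    def __post_init__(self) -> None:
        thr = {float(f): float(t) for f, t in self.thresholds.items()}
        for f, t in thr.items():
            if f not in FREQUENCIES_HZ:
                raise ValueError(f"threshold frequency {f} Hz not in {FREQUENCIES_HZ}")
            if not np.isfinite(t):
                raise ValueError("thresholds must be finite")
        object.__setattr__(self, "thresholds", thr)
        if self.slope < 0:
            raise ValueError("slope must be >= 0")
        if not (0 < self.amp_max <= 1.25):
            raise ValueError("amp_max must lie in (0, 1.25] µV")
        if not (0 < self.trough_lag < 8):
            raise ValueError("trough_lag must lie in (0, 8) ms")
        if self.noise_rms < 0:
            raise ValueError("noise_rms must be >= 0")
        if not (0 <= self.artifact_rate < 1):
            raise ValueError("artifact_rate must lie in [0, 1)")


@dataclass
class EpochBlock:
    """A block of stimulus-locked epochs for one stimulus.

    ``samples`` is an (n_epochs, N_SAMPLES) array in µV at ``fs`` = 5 kHz over
    the closed [0, 20] ms window; ``seed_state`` records RNG provenance."""

    samples: np.ndarray
    stimulus: StimulusSpec
    fs: float = FS_HZ
    seed_state: str | None = None

    @property
    def n_epochs(self) -> int:
        return int(self.samples.shape[0])

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != int(
            round(self.fs * WINDOW_MS / 1000.0)
        ) + 1:
            raise ValueError("samples must be (n_epochs, n_samples) for the 0-20 ms window")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("epoch samples must be finite")


def true_growth(profile: SubjectProfile, stim: StimulusSpec) -> float:
    """Ground-truth PTTa (µV) of the growth surface at one stimulus.

    Exactly zero at and below the per-frequency threshold, then linear in
    level with slope ``profile.slope`` up to saturation at ``amp_max``."""
    freq = float(stim.frequency)
    if freq not in profile.thresholds:
        raise ValueError(f"profile has no threshold for {freq} Hz")
    excess = float(stim.level) - profile.thresholds[freq]
    if excess <= 0:
        return 0.0
    return float(min(profile.amp_max, profile.slope * excess))


def peak_latency_ms(profile: SubjectProfile, level: float) -> float:
    """Wave-V peak latency law: latency grows as the level decreases."""
    return profile.latency0 + profile.latency_shift * (LATENCY_REFERENCE_DB - level) / 10.0


def wave_v_template(
    amplitude: float,
    peak_latency: float,
    trough_lag: float,
    fs: float = FS_HZ,
    n_samples: int = N_SAMPLES,
    lobe_width_ms: float = 1.0,
) -> np.ndarray:
    """Noiseless biphasic wave-V surrogate.

    A positive Gaussian lobe at ``peak_latency`` ms followed by a negative
    lobe at ``peak_latency + trough_lag`` ms (each of width ``lobe_width_ms``),
    rescaled so the exact peak-to-trough difference of the returned vector
    equals ``amplitude``.  All-zero when ``amplitude`` is 0.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if trough_lag <= 0:
        raise ValueError("trough_lag must be > 0")
    window_ms = (n_samples - 1) / fs * 1000.0
    if peak_latency - 2 * lobe_width_ms < 0 or peak_latency + trough_lag + 2 * lobe_width_ms > window_ms:
        raise ValueError(
            f"waveform geometry (peak {peak_latency} ms, lag {trough_lag} ms, "
            f"lobe width {lobe_width_ms} ms) exceeds the 0-{window_ms:g} ms window"
        )
    if amplitude == 0:
        return np.zeros(n_samples)
    t = np.arange(n_samples) / fs * 1000.0
    shape = np.exp(-0.5 * ((t - peak_latency) / lobe_width_ms) ** 2) - np.exp(
        -0.5 * ((t - peak_latency - trough_lag) / lobe_width_ms) ** 2
    )
    return amplitude / (shape.max() - shape.min()) * shape


def _noise_sos(fs: float):
    # 6th-order Butterworth band-pass (3 pole pairs), mirroring the recording chain.
    return signal.butter(3, NOISE_BAND_HZ, btype="bandpass", fs=fs, output="sos")


def band_limited_noise(
    n_epochs: int, n_samples: int, rms: float, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Zero-mean Gaussian noise filtered to 30-1500 Hz, pooled-RMS rescaled.

    The noise is generated as one continuous stream, filtered forward-backward
    and then sliced into epochs, as if consecutive sweeps were cut from an
    ongoing EEG recording; the pooled sample RMS is rescaled to ``rms``
    exactly, so per-epoch RMS fluctuates around it.
    """
    if rms == 0:
        return np.zeros((n_epochs, n_samples))
    pad = 512  # discard filter edge transients
    stream = rng.standard_normal(n_epochs * n_samples + 2 * pad)
    filtered = signal.sosfiltfilt(_noise_sos(fs), stream)[pad:-pad]
    filtered = filtered * (rms / np.sqrt(np.mean(filtered**2)))
    return filtered.reshape(n_epochs, n_samples)


def _inject_artifacts(
    samples: np.ndarray, rate: float, fs: float, rng: np.random.Generator
) -> None:
    """Add >20 µV half-sine deflections to a random subset of epochs in place."""
    if rate <= 0:
        return
    n_epochs, n_samples = samples.shape
    width = int(round(ARTIFACT_DURATION_MS / 1000.0 * fs))
    hits = np.flatnonzero(rng.random(n_epochs) < rate)
    for i in hits:
        amp = rng.uniform(*ARTIFACT_AMP_RANGE_UV) * (1.0 if rng.random() < 0.5 else -1.0)
        start = int(rng.integers(0, n_samples - width))
        samples[i, start : start + width] += amp * np.sin(np.linspace(0, np.pi, width))


def generate_block(
    profile: SubjectProfile,
    stim: StimulusSpec,
    n_epochs: int,
    rng: np.random.Generator,
) -> EpochBlock:
    """Simulate one block of stimulus-locked epochs for a stimulus.

    Each epoch is the noiseless wave-V template (amplitude from the true
    growth surface, latency from the latency law) plus band-limited background
    noise; with probability ``profile.artifact_rate`` an epoch additionally
    contains a >20 µV artifact.  Fully reproducible from ``rng``.
    """
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1")
    amp = true_growth(profile, stim)
    template = wave_v_template(
        amp, peak_latency_ms(profile, stim.level), profile.trough_lag
    )
    samples = np.broadcast_to(template, (n_epochs, N_SAMPLES)).copy()
    if profile.noise_rms > 0:
        samples += band_limited_noise(n_epochs, N_SAMPLES, profile.noise_rms, FS_HZ, rng)
    _inject_artifacts(samples, profile.artifact_rate, FS_HZ, rng)
    return EpochBlock(samples=samples, stimulus=stim, fs=FS_HZ)
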