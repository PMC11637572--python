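"""Epoch conditioning: band-pass filtering, downsampling, artifact rejection.

Reproduces the recording chain applied before amplitude estimation: 30-1500 Hz
sixth-order Butterworth band-pass (applied zero-phase so peak/trough latencies
are preserved), 48 kHz -> 5 kHz rate conversion with anti-alias filtering, and
rejection of epochs whose absolute amplitude exceeds the ±20 µV level.
Accepted epochs accumulate per test location in an :class:`EpochEnsemble`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .simulate import EpochBlock, StimulusSpec

#: Band-pass corners, Hz.
BAND_HZ = (30.0, 1500.0)
#: Artifact rejection level, µV; epochs with max |x| strictly above are removed.
REJECTION_UV = 20.0


def bandpass(x: np.ndarray, fs: float) -> np.ndarray:
    """30-1500 Hz sixth-order Butterworth band-pass, zero-phase.

    Applied along the last axis (time).  The zero-phase (forward-backward)
    application removes DC and preserves latencies; it requires the sampling
    rate to put 1500 Hz below Nyquist, hence ``fs`` must exceed 3000 Hz.
    """
    if fs <= 3000:
        raise ValueError("fs must exceed 3000 Hz (Nyquist above the 1500 Hz corner)")
    sos = signal.butter(3, BAND_HZ, btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


def downsample_48k_to_5k(x: np.ndarray) -> np.ndarray:
    """Convert a 48 kHz signal to 5 kHz with anti-alias filtering.

    Polyphase resampling by 5/48 (the anti-alias low-pass is part of the
    polyphase design); output length is round(n * 5 / 48).
    """
    x = np.asarray(x, dtype=float)
    n_out = int(round(x.shape[-1] * 5 / 48))
    y = signal.resample_poly(x, 5, 48, axis=-1)
    return y[..., :n_out]


def reject_artifacts(
    samples: np.ndarray, limit: float = REJECTION_UV
) -> tuple[np.ndarray, int]:
    """Split epochs into (accepted, n_rejected) by the ±limit µV rule.

    An epoch is kept iff max |x| <= limit (boundary inclusive, so the
    documented rejection level itself is attainable); row order is preserved.
    Idempotent: re-applying to the accepted epochs rejects nothing.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    keep = np.max(np.abs(samples), axis=1) <= limit
    return samples[keep], int(np.count_nonzero(~keep))


@dataclass
class EpochEnsemble:
    """Cumulative artifact-free epochs for one (level, frequency) location."""

    stimulus: StimulusSpec
    _blocks: list = field(default_factory=list, repr=False)
    n_rejected: int = 0

    @property
    def n_accepted(self) -> int:
        return sum(b.shape[0] for b in self._blocks)

    @property
    def n_presented(self) -> int:
        return self.n_accepted + self.n_rejected

    @property
    def accepted(self) -> np.ndarray:
        """All accepted epochs, oldest first, as an (n, n_samples) array."""
        if not self._blocks:
            return np.empty((0, 0))
        return np.concatenate(self._blocks, axis=0)


def accumulate(
    ensemble: EpochEnsemble,
    accepted_epochs: np.ndarray,
    n_rejected: int = 0,
    stimulus: StimulusSpec | None = None,
) -> EpochEnsemble:
    """Append already-accepted epochs (plus a rejection count) to an ensemble.

    ``stimulus``, if given, must match the ensemble's stimulus; mixing test
    locations in one ensemble is a usage error.
    """
    if stimulus is not None and stimulus != ensemble.stimulus:
        raise ValueError(
            f"stimulus mismatch: ensemble is {ensemble.stimulus}, got {stimulus}"
        )
    accepted_epochs = np.atleast_2d(np.asarray(accepted_epochs, dtype=float))
    if accepted_epochs.shape[0]:
        ensemble._blocks.append(accepted_epochs)
    ensemble.n_rejected += int(n_rejected)
    return ensemble


def ingest_block(
    ensemble: EpochEnsemble, block: EpochBlock, limit: float = REJECTION_UV
) -> int:
    """Artifact-reject a raw block and accumulate the survivors.

    Returns the number of accepted epochs added."""
    accepted, n_rej = reject_artifacts(block.samples, limit)
    accumulate(ensemble, accepted, n_rej, stimulus=block.stimulus)
    return accepted.shape[0]
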