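"""Simulate chirp-evoked ABR epochs for one subject and inspect them.

Builds a normal-hearing subject profile, generates a 500-epoch block at
70 dB HL / 1 kHz, and prints the ground-truth wave-V amplitude, the noise
level, and what survives artifact rejection.
"""

import numpy as np

from abrgp import StimulusSpec, SubjectProfile, generate_block, true_growth
from abrgp.preprocess import reject_artifacts

profile = SubjectProfile(
    thresholds={500.0: 10.0, 1000.0: 5.0, 2000.0: 10.0, 4000.0: 15.0},
    noise_rms=5.0,      # per-epoch background RMS, µV
    artifact_rate=0.05,  # 5% of epochs carry a >20 µV artifact
)
stim = StimulusSpec(level=70.0, frequency=1000.0)

block = generate_block(profile, stim, n_epochs=500, rng=np.random.default_rng(1))
accepted, n_rejected = reject_artifacts(block.samples)

print(f"stimulus: {stim.level:.0f} dB HL @ {stim.frequency:.0f} Hz")
print(f"true wave-V amplitude at this stimulus: {true_growth(profile, stim):.3f} µV")
print(f"epochs: {block.n_epochs} presented, {n_rejected} rejected (> ±20 µV), "
      f"{accepted.shape[0]} accepted")
print(f"per-epoch RMS: {np.sqrt(np.mean(accepted**2)):.2f} µV "
      f"(single epochs are ~10x the response: averaging is essential)")
avg = accepted.mean(axis=0)
print(f"coherent average peak-to-peak: {avg.max() - avg.min():.3f} µV after "
      f"{accepted.shape[0]} epochs")
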