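"""Condition the level x frequency Gaussian process on a few observations.

Starts from the zero-mean prior (the belief that the subject is deaf),
adds three debiased amplitude observations at 1 kHz, refits the length
scales by maximum likelihood, and prints the posterior along the level axis.
"""

from abrgp.gp import (
    Hyperparameters,
    ObservationSet,
    PredictionGrid,
    fit_hyperparameters,
    posterior,
)

grid = PredictionGrid()
obs = ObservationSet()
obs.upsert(70.0, 1000.0, 0.55, 0.004)  # (level, freq, o µV, sigma2 µV²)
obs.upsert(45.0, 1000.0, 0.20, 0.006)
obs.upsert(25.0, 1000.0, 0.00, 0.003)

hyper = fit_hyperparameters(obs)
post = posterior(obs, grid, hyper)

print(f"prior scale s = {hyper.s:.4f} µV²  (SD {hyper.s**0.5:.3f} µV)")
print(f"ML length scales: theta_db = {hyper.theta_db:.0f}, theta_hz = {hyper.theta_hz:.2f}")
print("posterior at 1 kHz (µV):")
for level in range(-10, 71, 10):
    mu, var = post.marginal(float(level), 1000.0)
    print(f"  {level:+3d} dB HL: mean {mu:+.3f}  sd {var**0.5:.3f}")
print("at 2 kHz (information smeared across the octave):")
for level in (70, 40):
    mu, var = post.marginal(float(level), 2000.0)
    print(f"  {level:+3d} dB HL: mean {mu:+.3f}  sd {var**0.5:.3f}")
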