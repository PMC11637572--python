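# Methods

This note documents the model, the estimator internals, the synthetic-data
generator, the numerical choices, and the limitations of `abrgp`.  Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The regression model

The wave-V peak-to-trough amplitude (PTTa) growth surface f(x_L, x_F) is a
zero-mean Gaussian process over stimulus level (dB HL) and frequency (Hz)
with exponential covariance

    k(x1, x2) = s · exp(−|L1−L2| / θ_dB − |log F1 − log F2| / θ_Hz).

* **s = (1.25/3.09)² ≈ 0.1636 µV²**, fixed, never refit.  It encodes the
  prior that 99.9% of wave-V amplitudes lie below 1.25 µV (±3.09 SD of a
  zero-mean normal).  Stored as a variance (µV²).
* **Zero prior mean** encodes the clinically conservative starting belief
  that the subject is deaf, and pulls the posterior mean toward zero away
  from data, giving the stimulus policy directional guidance.
* **θ_dB ∈ (1000, 2000)** and **θ_Hz ∈ (0.05, 1)** are refit after every
  block by maximizing the Gaussian log marginal likelihood on a
  deterministic 12 × 12 log-spaced grid (endpoints included).  A grid search
  is used instead of a gradient optimizer so refits are exactly reproducible;
  exact likelihood ties resolve toward larger (smoother) length scales, so
  with zero or one observation — where the likelihood is θ-independent —
  the upper bounds are returned.
* The log base in the frequency distance is natural log (configurable via
  `Hyperparameters.log_base`).

Note that θ_dB ∈ (1000, 2000) dB is an order of magnitude larger than the
80 dB test range, so the prior correlation between *any* two levels at the
same frequency exceeds 0.92: the model is near-degenerately smooth in level,
and the posterior mean behaves like piecewise-linear interpolation between
observations (the exponential kernel approaches a Brownian-like linear
covariance at long length scales).  This is implemented as specified, not
"corrected"; its consequences are discussed under Limitations.

The prediction grid is fixed: 81 integer levels (−10…70 dB HL) at each of
500/1000/2000/4000 Hz, 324 locations, frequency-major ordering (all levels
at 500 Hz first, level ascending).  Posteriors are computed by standard
multivariate-normal conditioning; every matrix that is inverted receives a
diagonal jitter of 1e−9·s, because observation variances can sit at the
σ²-floor while clustered test locations make Σ_T nearly singular.
Observation sets hold at most one entry per unique (level, frequency):
re-testing a location recomputes (o, σ²) from the cumulative ensemble and
replaces the entry.

## Amplitude extraction and debiasing

The **coherent average** is the arithmetic mean of accepted epochs; odd/even
replicate sub-averages (1-based epoch parity) are retained for inspection.
The raw PTTa maximizes avg[i] − avg[j] over sample pairs with the peak
preceding the trough by at most 8 ms, both inside a 4–16 ms search window
(configurable; inside the 0–20 ms epoch).  Exact ties resolve to the
earliest peak, then the earliest trough; the amplitude is clamped at 0.

This maximum is positively biased by residual noise.  The **bootstrap
maximum-likelihood debiaser** inverts the bias:

1. B = 200 noise-only surrogate averages are built by resampling the
   accepted epochs with replacement and multiplying each draw by a random
   ±1.  Sign-flipping destroys the time-locked response while preserving
   the second-order noise statistics of the average.
2. For each candidate amplitude a on a 0–1.25 µV grid (step 0.005 µV), a
   biphasic wave-V template of amplitude a is injected at the *observed*
   peak/trough latencies into every surrogate, and the constrained search
   is re-run, giving the sampling distribution of the biased statistic
   under that a.  All candidates share the same surrogates (common random
   numbers), which makes the likelihood curve smooth in a.
3. The likelihood of the observed biased value under each candidate is a
   Gaussian kernel density over the B surrogate values (Silverman
   bandwidth, floored at 1e−4 µV).  The debiased estimate o is the
   maximum-likelihood candidate; σ² is the variance of the
   likelihood-normalized distribution over the grid, floored at (0.005 µV)²
   so GP noise terms stay positive.

**Boundary gate.**  Because the amplitude lives on a boundary (a ≥ 0), the
raw ML argmax is positively biased under pure noise: any observation in the
upper half of the noise-only distribution maps to a positive amplitude, and
a nonnegative estimator can only be mean-accurate at a = 0 if it returns
exactly 0 for the vast majority of noise draws.  The nonzero ML candidate is
therefore kept only when the boundary likelihood-ratio statistic
2·(log L_max − log L(0)) exceeds 2.706, the 95th percentile of the standard
½χ²₀ + ½χ²₁ mixture for a parameter on its boundary.  This constant is a
textbook critical value, not a fitted number.  The cost is attenuation of
amplitudes near the detection limit of the max-pair statistic (detection
power at 0.3 µV with 4000 epochs of 5 µV RMS noise is well below 1), which
the closed loop compensates for by accumulating more epochs — mirroring how
testing is prolonged when data are noisy.

Degenerate ensembles (residual RMS < 1e−9, e.g. noiseless simulations)
short-circuit: o equals the raw value, σ² the floor, and a warning flag is
set.

The inner pair-scan over (candidate × surrogate) is accelerated with numba
when available (identical pure-numpy fallback, exercised in tests): for each
surrogate only the Pareto front of (template-difference, noise-difference)
pairs needs evaluating, since for a ≥ 0 a pair dominated in both coordinates
can never be the maximum.

## Active learning and threshold inference

Targets T₁…T₅ = 0.5, 0.3, 0.25, 0.2, 0.15 µV are located per frequency in
descending order with confidence thresholds δ₁…δ₅ = 0.2, 0.15, 0.1, 0.075,
0.05 µV (posterior SD at the target's most-likely level, strict
comparison).  The most-likely level for a target maximizes the normal
density N(T; μ̄(L), σ²(L)) over the 81 grid levels, ties toward the highest
level (conservative approach-from-above).  If the most likely amplitude at
the 70 dB HL maximum level (argmax of the posterior density over the 0–1.25
µV grid — the grid point nearest the mean, clamped) is below the current
target, testing redirects to the maximum level, and the target is abandoned
once the max-level SD falls below its δ; a frequency whose five targets are
all abandoned is censored (profound-loss surrogate).  The next stimulus is
the active-frequency candidate with the largest posterior SD, ties toward
the lower frequency — which at session start (constant prior SD √s) yields
(70 dB HL, 500 Hz).  Thresholds are inferred from the final posterior as
the most likely level where f = 0, per frequency.

The controller alternates 500-accepted-epoch blocks (rejected epochs do not
count, matching the artifact-free test-time definition) with posterior
updates and θ refits; one refit per block.  A hard cap of 20 000 accepted
epochs per frequency guarantees termination; a capped frequency keeps its
audiogram entry but is flagged censored.  Test time converts epochs to
minutes at 47.17 stimuli/s.

## The synthetic-ABR generator

The generator emulates what matters to the estimator, not cochlear
physiology:

* **Growth law**: piecewise linear with saturation — exactly 0 at and below
  the per-frequency threshold, then slope 0.01 µV/dB up to amp_max 0.6 µV.
  Invertible, so ground-truth thresholds are exact; amplitudes stay inside
  the 0–1.25 µV prior range.
* **Waveform**: a biphasic template (two Gaussian lobes of width 1 ms,
  trough 2 ms after the peak) whose exact peak-to-trough difference equals
  the growth-law amplitude.  Peak latency 8 ms at 70 dB HL, +0.4 ms per
  10 dB of level decrease.
* **Noise**: Gaussian white noise filtered to 30–1500 Hz (6th-order
  Butterworth, forward–backward), generated as one continuous stream and
  sliced into consecutive epochs (as consecutive sweeps would be), then
  rescaled so the pooled sample RMS equals noise_rms exactly.
* **Artifacts**: with probability artifact_rate an epoch receives a
  half-sine deflection of 25–40 µV (random sign, 5 ms, random latency);
  only its ±20 µV exceedance matters downstream.
* Epochs are generated directly at 5 kHz on the closed 0–20 ms window
  (101 samples); the 48 kHz acquisition chain is not simulated, though the
  preprocessing operations for it exist.

The default evaluation cohort has 30 subjects (22 normal-hearing with
integer thresholds uniform on [0, 15] dB HL per frequency; 8 with
mild-to-moderate loss, uniform on [20, 50]), per-epoch noise RMS uniform on
[3, 8] µV, and 2% artifact epochs — a plausible adult cohort at the stated
amplitude range.  What passing tests show is that the pipeline recovers the
thresholds of *this* growth/noise model without bias in the median; real
ABR data differ (non-linear growth, non-stationary and non-Gaussian EEG,
latency jitter across epochs, electrode artifacts with structure), so
simulation results bound optimism, they do not replace subject validation.

## Numerical choices

* Rejection boundary inclusive: epochs with max |x| exactly 20 µV are kept.
* Filtering is zero-phase (forward–backward `sosfiltfilt`); "6th order"
  means the overall band-pass order (3 pole pairs).
* Downsampling uses polyphase resampling by 5/48 with its built-in
  anti-alias filter; output length is round(n·5/48).
* Amplitude-candidate ties in the debiaser resolve to the smallest
  amplitude; level ties in the policy to the highest level; frequency ties
  to the lowest frequency (all documented tie-breaks, all deterministic).
* All randomness flows through explicit `numpy.random.Generator` objects;
  cohort evaluation spawns one child seed per subject from a
  `SeedSequence`, so runs are reproducible and subjects independent.

## Known limitations

* **Near-degenerate level smoothness.**  With θ_dB ∈ (1000, 2000) the
  target-location rule's density argmax can be drawn toward the far
  extrapolation edge early in a session (the posterior SD grows with
  distance from the data while the mean barely moves), so the policy
  occasionally samples deep in the no-response region and can leave a
  tightly-constrained zero there.  The final threshold rule (density argmax
  at T = 0) then prefers that tight zero over the true zero-crossing
  region.  With realistic noise this inflates the spread of threshold
  errors while the median stays near zero; in near-noiseless simulations it
  can dominate, so low-noise single-subject recovery is *not* a reliable
  property of the procedure as specified.  Monotonicity-constrained GPs or
  a shorter level length scale would remove the pathology but would be a
  different model.
* **Length-scale identifiability.**  A single dense surface draw carries
  limited Fisher information about θ_dB (the Cramér–Rao SE over the 80 dB
  span is ~12%, larger than one step of the 12-point search grid), so
  refitted length scales scatter widely; the procedure is robust to this
  because the posterior changes little across the allowed θ range.
* **Attenuation near the detection limit.**  The boundary gate trades a
  small downward bias at marginal SNR for mean-accuracy under noise; both
  cannot be avoided simultaneously with a scalar max-pair statistic.
* The examiner/visual-inspection comparison arm and behavioral audiometry
  are out of scope; no real-EEG ingest (EDF/BDF) is provided.
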