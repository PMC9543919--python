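# Methods

## The question and the statistic

Covert visual attention may sample the environment rhythmically rather than
continuously.  If it does, the strength of a stimulus representation in
neural population activity should wax and wane with the phase of ongoing
theta/alpha oscillations.  This package operationalizes that question as a
*phase-binned decoding* analysis:

1. From epoched multichannel recordings (trials x channels x samples,
   200 Hz, epochs spanning −1.0 to +1.0 s around stimulus onset), every
   sample in the post-onset analysis window (default 0.4–1.0 s, skipping
   the evoked transient) becomes one observation.
2. A designated phase-providing channel (a virtual channel or parcel time
   course in source space; any channel tagged `modulator` here) yields an
   instantaneous phase per observation: the four-quadrant arctangent of the
   imaginary over the real part of the Fourier coefficient of a
   Hanning-tapered window of two cycles of the frequency of interest,
   zero-padded to 4 s (0.25 Hz grid), sliding in 5 ms steps and centered on
   the output time point.  Positions whose window does not fit inside the
   epoch are flagged invalid, never zero-filled.
3. Observations are assigned to 18 equidistant phase bins partitioning
   [−π, π); bin k covers [−π + k·2π/18, −π + (k+1)·2π/18).
4. Within each bin, the binary stimulus class (clockwise vs
   counterclockwise grating) is decoded: disjoint groups of five same-class
   observations are averaged into pseudo-observations (leftovers
   discarded); the pseudo-observations are demeaned, reduced by SVD to the
   components explaining ≥99% of variance, each scaled to unit variance;
   classes are equalized by random subsampling; a linear SVM (C = 1) is
   evaluated with stratified 5-fold cross-validation.  The per-bin accuracy
   is averaged over repetitions of this procedure (20 per bin at full
   scale) with fresh random groupings.
5. A one-cycle cosine y_k ≈ c + a·cos(θ_k − φ*) is fitted to the 18 bin
   accuracies with c fixed at their mean.  For complete equidistant bins
   the least-squares solution is closed-form:
   a = (2/N)·|Σ_k y_k e^(−iθ_k)|, φ* = arg(Σ_k y_k e^(+iθ_k)).
   With missing (flagged) bins the fit falls back to explicit least squares
   with the intercept estimated jointly, and is marked as such.
   The amplitude *a* is the **modulation depth**, φ* the optimal phase.
6. The null distribution adds an independent uniform offset in (−2π, 2π) to
   every trial's phase time course (wrapped), re-bins, and recomputes
   steps 4–5.  This destroys phase-outcome coupling while exactly
   preserving each trial's temporal autocorrelation.  A temporal-rotation
   variant (`mode="roll"`) is provided for sensitivity analysis.
7. Steps 2–6 repeat per frequency (1 Hz grids, 4–30 or 4–20 Hz at full
   scale), giving a modulation spectrum with per-frequency null draws.

Group inference uses a second-level cluster permutation over frequencies:
per null draw and frequency, one first-level null sample per subject is
averaged over subjects; the per-frequency threshold is the (1−α) quantile
of those draws; contiguous supra-threshold frequencies are clustered, their
group statistics summed, and each observed cluster sum compared to the
distribution of maximum null-cluster sums (inclusive p = (b+1)/(n+1)).
When many phase-providing parcels are tested, a max-statistic correction
pools the maximum cluster sum across parcels per draw; clusters are still
formed only over frequencies.  Simple contrasts use an exhaustive sign-flip
permutation test (all 2^n flips for n ≤ 10 subjects).  Post-hoc evidence
for null results uses the JZS one-sample Bayes factor on paired differences
(Cauchy prior on effect size, scale √2/2 by default) computed by
quadrature; it is a deliberate, documented operationalization of an
otherwise non-operational "flat prior".

Behavioral coupling is assessed analogously: one phase per trial from a
two-cycle window centered one cycle before target onset (so the window
ends exactly at target onset and is uncontaminated by the stimulus
change), mean reaction time in a 90° window centered on each of the 18 bin
centers (half-open membership: lower edge in), the same cosine fit, and a
null built by shuffling reaction times over trials.  Averaging a cosine
over a 90° boxcar attenuates its amplitude by sin(π/4)/(π/4) ≈ 0.900;
recovery analyses must divide by this factor before comparing against a
generative coupling.

## The eye-movement control

Systematic gaze differences between stimulus classes can masquerade as
neural decoding.  The control decodes the class from the gaze channels
alone (same pseudo-observation pipeline, 10-fold CV); each iteration tests
the fold accuracies against scrambled-label fold accuracies with a paired
one-sided t test (α = 0.05).  While significant, the pseudo-observation
per class per fold with the largest correct-side margin is marked and its
constituent trials removed; the loop stops after five consecutive
non-significant iterations (the counter resets on any significant one),
with an iteration cap as a non-termination guard.  The marked trials are
then removed from the neural data before re-decoding.

Two properties of this procedure at desk scale deserve mention.  First,
because pseudo-observations mix observations from different trials,
removing one marks up to five trials; a single (possibly false-positive)
iteration can remove up to `n_folds × 2 × group_size` trials, so the noise
behavior of the loop should be judged relative to the trial count.
Second, because fold assignment operates on observations (trial-time
points), observations from one trial can land in different folds; with few
trials, a classifier can exploit within-trial noise autocorrelation
("trial fingerprints") and sit above 50% with zero class information.
This is a property of the method, negligible at full scale (on the order of a thousand trials) but
visible at hundreds.  The correct chance reference is therefore
the trial-level label permutation (`empirical_chance(..., unit="trial")`),
which preserves the fingerprint advantage under the null; the
observation-level shuffle (`unit="observation"`) estimates nominal chance.

## The synthetic-data generator

`simulate_subject` produces epochs with exactly the structure the
inference assumes, plus the ground truth used to make them:

* **Modulator channel**: cos(2π·f_mod·t + θ_trial), θ_trial ~ U[−π, π),
  embedded in background noise (sd `modulator_noise_sd`, default 0.4;
  spectral slope `modulator_noise_exponent`, default 0 = white, emulating
  the whitened background of a beamformed virtual-channel time course).
* **Sensor channels**: unit-variance 1/f^`noise_exponent` noise (default
  slope 1), the modulator waveform leaked in with fixed N(0, 0.2²)
  weights (so sensor phase is realistically correlated with the
  modulator), and — from stimulus onset — a class-specific spatial
  pattern.  The two class patterns are random orthonormal channel
  vectors, so linear separability is controlled solely by `pattern_snr`
  and the envelope A(t) = 1 + m·cos(φ_mod(t) − φ*), with modulation depth
  m ∈ [0, 1] and optimal phase φ*.
* **Behavior**: RT = rt_base − b·cos(φ_mod(t_target) − φ*) + N(0, σ_RT²)
  with defaults 630 ms, b = 10 ms, σ_RT = 96 ms, typical of speeded
  discrimination responses; correctness is Bernoulli with base 0.87 and
  optional phasic coupling.  Target onset is at 1.0 s (epoch end).
* **Gaze channels**: white noise, with a class-dependent offset
  (`eye_bias`) on a random `eye_bias_fraction` of trials from stimulus
  onset, optionally leaked into the sensors (`gaze_leak`) to emulate a
  purely oculomotor origin of "neural" decodability.
* **Lateralized-power fixture** (`simulate_lateralized_power`): 10 Hz
  amplitude raised by `alpha_lateralization` on the hemisphere
  ipsilateral to the attended side; the default 0.08 was calibrated once
  so that the downstream lateralization index lands near the ~10%
  typical of covert spatial attention.

Each subject's stream derives from (seed, subject index); identical seeds
give bit-identical output.

**What the generator does not emulate**: sensor geometry and field
spread, non-stationary rhythm bursts, saccade dynamics, evoked
transients, or any biophysics.  Passing recovery tests therefore shows
the *pipeline* is correct and calibrated under the assumed generative
structure, not that real recordings satisfy that structure.

**A note on spectral leakage.**  With two-cycle estimation windows, a
spectrally dominant oscillation imprints its phase on the Fourier
coefficient of *every* nearby analyzed frequency (the shorter the window
— i.e. the higher the analyzed frequency — the wider its mainlobe, so
the coupling is strongest above the rhythm's frequency).  If the
modulator were a clean tone, the modulation spectrum would be nearly
flat and the peak uninformative.  Frequency-resolved analysis is
meaningful in the regime where the in-band background dominates
off-frequency coefficients; the frequency-recovery experiments therefore
use a low-SNR rhythm (`modulator_noise_sd = 2.0`, chosen once), while
the default 0.4 keeps single-trial phase readout faithful (mean absolute
circular error < 0.15 rad) for tests that need the true phase.

## Problem sizes and numerical choices

Full-scale defaults describe the experimental regime the pipeline
targets (18 bins, groups of 5, 100
overall / 20 per-bin repetitions, 100 circular-shift permutations, 1,024
sign-flip and 1,000 cluster permutations, 0.4–1.0 s window).  The test
suite and the demo analyses run reduced problem sizes — 12–40 trials per
condition, 8 sensor channels, 3–9 frequencies, 5–10 repetitions per bin,
50 first-level permutations — chosen as the package's reduced-cost
experiment design; resampling counts and thresholds are never adapted to
data.

The inner decoding loop is solved by dual coordinate descent on the
C-SVM objective (hinge loss, bias as an augmented constant feature,
tolerance 1e-3 on the projected gradient, 300-pass cap), compiled with
numba; scikit-learn's `SVC(kernel="linear")` is the equivalence reference
in the tests and available as `backend="sklearn"`.  Whitening of the tiny
per-repetition matrices uses the eigendecomposition of the feature Gram
matrix (identical to SVD up to component sign).  Whitening is fit on the
full pseudo-observation set by default, mirroring the stated order of
operations; a leakage-free per-training-fold variant is available
(`whiten="per_fold"`).  Ties in the eye-control margin ranking break
toward the lowest trial index; fold assignment is a seeded round robin
within class; phase-bin membership at π wraps to −π.  Flagged
(underfilled) bins propagate as NaN and are excluded explicitly by the
fallback cosine fit.

## Known limitations

* Observation-level fold assignment (as specified) permits within-trial
  leakage at small trial counts; see the eye-control section.  Use
  trial-level chance for calibrated comparisons.
* The paired fold-wise t test in the removal loop treats folds as
  independent; they are not, so its effective false-positive rate
  exceeds its nominal α.  The five-in-a-row stopping rule absorbs most
  of this in practice.
* The cosine fit assigns all non-uniformity to the first circular
  harmonic; higher-harmonic phase dependence would be underestimated.
* Modulation depths at neighboring frequencies are correlated by
  construction (leakage), so cluster extent over frequencies should not
  be read as bandwidth of the underlying rhythm.
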