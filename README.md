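# phasedecode

Does the brain's representation of a visual stimulus wax and wane with the
phase of ongoing theta/alpha oscillations?  `phasedecode` implements the
full analysis pipeline for asking that question of epoched multichannel
recordings (MEG/EEG sensor data or source time courses), together with a
synthetic-data generator that makes every stage testable without any
recording.  It is aimed at cognitive/systems neuroscientists analyzing
phase-dependent stimulus decodability and at methodologists who want a
calibrated, seeded reference implementation of the procedure.

## The statistic

Each post-stimulus sample (0.4–1.0 s after onset) is an observation.  A
designated *phase-providing channel* yields instantaneous phase at a
frequency f via the angle of the Hanning-tapered Fourier coefficient of a
two-cycle sliding window, φ = atan2(Im X, Re X).  Observations are sorted
into 18 equidistant phase bins; within each bin the binary stimulus class
is decoded (pseudo-observation averaging in groups of 5 → SVD whitening to
99% variance → class equalization → linear SVM, stratified 5-fold CV,
repeated with fresh groupings).  A one-cycle cosine fitted to the 18 bin
accuracies,

    y_k ≈ c + a·cos(θ_k − φ*),   a = (2/N)·|Σ_k y_k·e^(−iθ_k)|,

gives the **modulation depth** a (in accuracy percentage points) and the
optimal phase φ*.  Significance comes from a circular-shift null — each
trial's phase time course rotated by an independent uniform offset,
preserving within-trial autocorrelation — repeated per frequency, with
second-level cluster permutation over frequencies (and max-statistic
correction over parcels) at the group level.  Companion analyses: the
attentional modulation index AMI = 100·(P_left − P_right)/(P_left +
P_right) and its lateralization index, phasic modulation of reaction
times by pre-target phase, and a gaze-leakage control that iteratively
removes eye-discriminative trials before re-decoding the neural data.

## Worked example

```python
import numpy as np
from phasedecode.simulate import SimConfig, simulate_subject
from phasedecode.phase_binned import modulation_spectrum

cfg = SimConfig(n_trials_per_condition=32, n_channels=8,
                f_mod=10.0, mod_depth=0.6, phi_star=0.8,
                pattern_snr=0.7, modulator_noise_sd=2.0, seed=0)
epochs, truth = simulate_subject(cfg, (300, 0))
sp = modulation_spectrum(epochs, "mod", freqs=range(6, 15),
                         n_repetitions=10, n_perm=0, seed=0)
print("peak:", sp.peak_frequency(), "Hz")
print("depth at peak: %.1f%%" % sp.amplitudes.max())
print("optimal phase: %.2f rad" % sp.preferred_phases[np.argmax(sp.amplitudes)])
```

prints

```
peak: 9.0 Hz
depth at peak: 9.6%
optimal phase: 0.78 rad
```

— the spectrum peaks within 1 Hz of the generative modulator frequency
(10 Hz; two-cycle estimation windows blur phase across neighboring
frequencies), the fitted modulation depth reflects the envelope gating of
the class pattern (accuracy swinging ≈10 percentage points over the cycle
at m = 0.6 under single-trial phase noise), and the recovered optimal
phase matches the ground-truth φ* = 0.8 rad.

The numbered scripts under `analysis/` run the full study flow on a
simulated cohort — `01_simulate_cohort.py` (writes HDF5 epochs + ground
truth), `02_power_lateralization.py` (AMI/LI), `03_decode_overall.py`
(overall accuracy vs empirical chance), `04_phase_modulation.py`
(modulation spectra + group cluster test), `05_rt_modulation.py`,
`06_eye_control.py` — each printing what it found and writing tables
under `results/`.

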