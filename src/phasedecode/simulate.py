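"""Synthetic epoched recordings with oscillation-gated class information.

The generator is an assumption-matching stand-in for task recordings, not a
biophysical model.  It produces exactly the statistical structure the
downstream inference assumes:

* a designated *modulator* channel carrying an ongoing oscillation at
  ``f_mod`` with a uniformly random phase per trial, embedded in background
  noise of configurable spectral slope (flat by default, emulating the
  whitened background of a beamformed virtual-channel time course);
* *neural* sensor channels = 1/f background noise, plus the modulator
  oscillation leaked in with fixed random weights (so sensor phase is
  realistically correlated with the modulator), plus a class-specific
  spatial pattern whose amplitude envelope is gated by the modulator phase:

  ``A(t) = 1 + m * cos(phi_mod(t) - phi_star)``,

  switched on at stimulus onset (t = 0);
* reaction times coupled to the modulator phase at target onset,
  ``RT = rt_base - b * cos(phi_mod(t_target) - phi_star) + noise``;
* two *gaze* channels with a class-dependent offset on a configurable
  fraction of trials (the eye-leakage confound), optionally leaked into the
  neural channels.

Identical seeds give bit-identical output; each subject draws from an
independent stream derived from ``(seed, subject_index)``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import EpochSet


def _wrap(phi: np.ndarray) -> np.ndarray:
    """Wrap angles to [-pi, pi)."""
    return np.mod(np.asarray(phi) + np.pi, 2.0 * np.pi) - np.pi


@dataclass
class SimConfig:
    """Ground-truth generator parameters.

    Defaults emulate a realistic full-scale experiment: 10 subjects,
    200 Hz sampling,
    epochs spanning [-1, 1) s around stimulus onset, ~600 trials per
    attention condition, an alpha-band (10 Hz) modulator, reaction times
    around 630 +/- 96 ms with a ~10 ms phasic swing, and ~87% correct
    behavior.  Effect sizes without a published generative counterpart
    (mod_depth, pattern_snr, eye bias) are fixed, documented choices.
    """

    n_subjects: int = 10
    n_trials_per_condition: int = 600
    n_channels: int = 16             # neural sensor channels
    fs: float = 200.0
    epoch_window: tuple[float, float] = (-1.0, 1.0)
    f_mod: float = 10.0              # modulator frequency, Hz
    mod_depth: float = 0.6           # m, in [0, 1]
    phi_star: float = 0.0            # preferred (optimal) phase, rad
    pattern_snr: float = 0.5         # class-pattern amplitude / noise sd
    noise_exponent: float = 1.0      # 1/f^exponent background
    rt_base: float = 0.63            # s
    rt_coupling: float = 0.010       # b, s
    rt_noise_sd: float = 0.096       # s
    accuracy_base: float = 0.87      # P(correct) at neutral phase
    accuracy_coupling: float = 0.0   # phasic swing of P(correct)
    eye_bias: float = 0.3            # gaze offset per class, a.u.
    eye_bias_fraction: float = 0.05  # fraction of trials carrying the bias
    gaze_leak: float = 0.0           # leakage of gaze signal into sensors
    alpha_lateralization: float = 0.08   # amplitude asymmetry for AMI fixture
                                         # (calibrated to a lateralization
                                         # index of ~10%)
    modulator_noise_sd: float = 0.4  # background noise on the modulator channel
    modulator_noise_exponent: float = 0.0   # spectral slope of that noise
    leak_sd: float = 0.2             # sd of modulator->sensor leak weights
    seed: int = 0

    def validate(self) -> None:
        numeric = {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if f.name != "epoch_window"
        }
        for name, value in numeric.items():
            if not np.isfinite(value):
                raise ValueError(f"SimConfig.{name} must be finite, got {value!r}")
        if not np.all(np.isfinite(self.epoch_window)):
            raise ValueError("epoch_window must be finite")
        if not 0.0 <= self.mod_depth <= 1.0:
            raise ValueError("mod_depth must lie in [0, 1]")
        if not 0.0 <= self.eye_bias_fraction <= 1.0:
            raise ValueError("eye_bias_fraction must lie in [0, 1]")
        if self.fs <= 2.0 * self.f_mod:
            raise ValueError("fs must exceed 2 * f_mod (Nyquist)")
        start, end = self.epoch_window
        if end - start < 2.0 / self.f_mod:
            raise ValueError("epoch_window must span at least 2 cycles of f_mod")
        if self.n_trials_per_condition < 1:
            raise ValueError("n_trials_per_condition must be >= 1")
        if self.n_channels < 2:
            raise ValueError("need at least 2 neural channels")
        if self.alpha_lateralization < 0:
            raise ValueError("alpha_lateralization must be >= 0")


@dataclass
class SimTruth:
    """Generation-time ground truth, for recovery tests."""

    f_mod: float
    mod_depth: float
    phi_star: float
    rt_coupling: float
    theta: np.ndarray            # per-trial initial modulator phase, rad
    phase: np.ndarray            # (n_trials, n_samples) modulator phase, rad
    pattern_cw: np.ndarray       # class spatial patterns (unit norm)
    pattern_ccw: np.ndarray
    eye_biased: np.ndarray       # bool per trial

    def to_json(self, path) -> None:
        """Serialize (phase stored implicitly via theta and f_mod)."""
        payload = {
            "f_mod": self.f_mod,
            "mod_depth": self.mod_depth,
            "phi_star": self.phi_star,
            "rt_coupling": self.rt_coupling,
            "theta": self.theta.tolist(),
            "pattern_cw": self.pattern_cw.tolist(),
            "pattern_ccw": self.pattern_ccw.tolist(),
            "eye_biased": self.eye_biased.astype(int).tolist(),
        }
        with open(path, "w") as f:
            json.dump(payload, f)


def powerlaw_noise(
    rng: np.random.Generator, shape: tuple[int, ...], fs: float, exponent: float
) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent power spectrum, unit variance.

    The last axis is time.  exponent=0 reduces to white noise.
    """
    white = rng.standard_normal(shape)
    if exponent == 0:
        return white
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = np.fft.rfft(white, axis=-1) * scale
    x = np.fft.irfft(spec, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _orthonormal_patterns(rng: np.random.Generator, n_channels: int):
    p0 = rng.standard_normal(n_channels)
    p0 /= np.linalg.norm(p0)
    p1 = rng.standard_normal(n_channels)
    p1 -= p0 * (p0 @ p1)
    p1 /= np.linalg.norm(p1)
    return p0, p1


def simulate_subject(config: SimConfig, subject_seed) -> tuple[EpochSet, SimTruth]:
    """Generate one subject's epochs plus the ground truth used to make them.

    ``subject_seed`` may be an int or a sequence (e.g. ``(seed, subject)``);
    it fully determines the output.
    """
    config.validate()
    rng = np.random.default_rng(subject_seed)

    start, end = config.epoch_window
    n_samples = int(round((end - start) * config.fs))
    times = start + np.arange(n_samples) / config.fs
    n_trials = 2 * config.n_trials_per_condition
    n_neural = config.n_channels

    # trial metadata ------------------------------------------------------
    attend = np.array(["left", "right"]).repeat(config.n_trials_per_condition)
    # orientation balanced within each attention condition
    orientation = np.empty(n_trials, dtype=object)
    for side in ("left", "right"):
        rows = np.flatnonzero(attend == side)
        half = len(rows) // 2
        labels = np.array(["CW"] * half + ["CCW"] * (len(rows) - half), dtype=object)
        orientation[rows] = rng.permutation(labels)
    order = rng.permutation(n_trials)
    attend, orientation = attend[order], orientation[order]
    is_cw = orientation == "CW"

    # modulator phase -----------------------------------------------------
    theta = rng.uniform(-np.pi, np.pi, size=n_trials)
    phase = _wrap(2.0 * np.pi * config.f_mod * times[None, :] + theta[:, None])

    # class patterns ------------------------------------------------------
    p_cw, p_ccw = _orthonormal_patterns(rng, n_neural)
    envelope = 1.0 + config.mod_depth * np.cos(phase - config.phi_star)
    stim_on = times >= 0.0
    gate = envelope * stim_on[None, :]          # pattern present from t=0
    pattern = np.where(is_cw[:, None], p_cw[None, :], p_ccw[None, :])
    signal = (
        config.pattern_snr * pattern[:, :, None] * gate[:, None, :]
    )  # (trials, channels, samples)

    # background noise + leaked modulator ---------------------------------
    noise = powerlaw_noise(
        rng, (n_trials, n_neural, n_samples), config.fs, config.noise_exponent
    )
    leak = rng.normal(0.0, config.leak_sd, size=n_neural)
    osc = np.cos(phase)                          # clean modulator waveform
    neural = noise + signal + leak[None, :, None] * osc[:, None, :]

    # modulator channel ---------------------------------------------------
    mod_channel = osc + config.modulator_noise_sd * powerlaw_noise(
        rng, (n_trials, n_samples), config.fs, config.modulator_noise_exponent
    )

    # gaze channels -------------------------------------------------------
    gaze = rng.standard_normal((n_trials, 2, n_samples))
    n_biased = int(round(config.eye_bias_fraction * n_trials))
    biased_rows = rng.choice(n_trials, size=n_biased, replace=False)
    eye_biased = np.zeros(n_trials, dtype=bool)
    eye_biased[biased_rows] = True
    class_sign = np.where(is_cw, 1.0, -1.0)
    offset = 0.5 * config.eye_bias * class_sign * eye_biased   # per trial
    gaze[:, 0, :] += offset[:, None] * stim_on[None, :]

    if config.gaze_leak != 0.0:
        g_w = rng.standard_normal(n_neural) / np.sqrt(n_neural)
        neural += config.gaze_leak * g_w[None, :, None] * gaze[:, 0:1, :]

    # behavior ------------------------------------------------------------
    t_target = end if end > 0 else 0.0          # stimulus change at epoch end
    phase_at_target = _wrap(2.0 * np.pi * config.f_mod * t_target + theta)
    rt = (
        config.rt_base
        - config.rt_coupling * np.cos(phase_at_target - config.phi_star)
        + rng.normal(0.0, config.rt_noise_sd, size=n_trials)
    )
    rt = np.clip(rt, 0.05, None)
    p_correct = np.clip(
        config.accuracy_base
        + config.accuracy_coupling * np.cos(phase_at_target - config.phi_star),
        0.0,
        1.0,
    )
    correct = rng.random(n_trials) < p_correct

    # assemble ------------------------------------------------------------
    data = np.concatenate(
        [mod_channel[:, None, :], neural, gaze], axis=1
    )
    names = (
        ["mod"]
        + [f"meg{i:03d}" for i in range(n_neural)]
        + ["gaze_x", "gaze_y"]
    )
    roles = ["modulator"] + ["neural"] * n_neural + ["gaze"] * 2
    table = pd.DataFrame(
        {
            "orientation": orientation.astype(str),
            "attend": attend.astype(str),
            "cue_valid": np.ones(n_trials, dtype=bool),
            "stim_duration": np.full(n_trials, 1.0),
            "rt": rt,
            "correct": correct,
            "target_onset": np.full(n_trials, t_target),
        }
    )
    epochs = EpochSet(
        data=data, times=times, fs=config.fs,
        channel_names=names, channel_roles=roles, trial_table=table,
    )
    truth = SimTruth(
        f_mod=config.f_mod,
        mod_depth=config.mod_depth,
        phi_star=config.phi_star,
        rt_coupling=config.rt_coupling,
        theta=theta,
        phase=phase,
        pattern_cw=p_cw,
        pattern_ccw=p_ccw,
        eye_biased=eye_biased,
    )
    return epochs, truth


def simulate_cohort(config: SimConfig):
    """Yield ``(subject_index, EpochSet, SimTruth)`` for every subject,
    each from an independent stream derived from ``(config.seed, subject)``."""
    for s in range(config.n_subjects):
        epochs, truth = simulate_subject(config, (config.seed, s))
        yield s, epochs, truth


def simulate_lateralized_power(config: SimConfig, subject_seed=None) -> EpochSet:
    """Fixture for the attentional power-lateralization indices.

    Attend-left trials carry stronger 10 Hz power on the designated
    left-hemisphere channels (and vice versa), with amplitude asymmetry
    ``1 + alpha_lateralization`` on the ipsilateral side.  Only used to
    exercise the AMI / LI stage; no class pattern, no phasic gating.
    """
    config.validate()
    rng = np.random.default_rng(
        subject_seed if subject_seed is not None else config.seed
    )
    start, end = config.epoch_window
    n_samples = int(round((end - start) * config.fs))
    times = start + np.arange(n_samples) / config.fs
    n_trials = 2 * config.n_trials_per_condition
    n_half = config.n_channels // 2
    if n_half < 1:
        raise ValueError("need at least 2 channels for the lateralized fixture")
    n_ch = 2 * n_half

    attend = np.array(["left", "right"]).repeat(config.n_trials_per_condition)
    attend = attend[rng.permutation(n_trials)]
    is_left = attend == "left"

    f_alpha = 10.0
    theta = rng.uniform(-np.pi, np.pi, size=n_trials)
    osc = np.cos(2.0 * np.pi * f_alpha * times[None, :] + theta[:, None])

    a = config.alpha_lateralization
    # ipsilateral-to-attention channels get the stronger alpha amplitude
    gain_lh = np.where(is_left, 1.0 + a, 1.0)     # left-hemisphere channels
    gain_rh = np.where(is_left, 1.0, 1.0 + a)     # right-hemisphere channels
    noise = powerlaw_noise(
        rng, (n_trials, n_ch, n_samples), config.fs, config.noise_exponent
    )
    data = noise.copy()
    data[:, :n_half, :] += gain_lh[:, None, None] * osc[:, None, :]
    data[:, n_half:, :] += gain_rh[:, None, None] * osc[:, None, :]

    names = [f"lh{i:02d}" for i in range(n_half)] + [
        f"rh{i:02d}" for i in range(n_half)
    ]
    table = pd.DataFrame(
        {
            "orientation": np.where(rng.random(n_trials) < 0.5, "CW", "CCW"),
            "attend": attend.astype(str),
            "cue_valid": np.ones(n_trials, dtype=bool),
            "stim_duration": np.full(n_trials, 1.0),
            "rt": np.full(n_trials, config.rt_base),
            "correct": np.ones(n_trials, dtype=bool),
            "target_onset": np.full(n_trials, max(end, 0.0)),
        }
    )
    return EpochSet(
        data=data, times=times, fs=config.fs,
        channel_names=names, channel_roles=["neural"] * n_ch, trial_table=table,
    )
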