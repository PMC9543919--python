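"""End-to-end drivers shared by the analysis scripts, the acceptance
script and the integration tests.

Each function runs one stage of the study on simulated data at a stated
(desk-scale) problem size and returns plain dictionaries/arrays that the
callers serialize.  All randomness is derived from explicit integer seeds.
"""

from __future__ import annotations

import numpy as np

from . import behavior, decoding, phase_binned, spectral, stats
from .containers import EpochSet, select_trials
from .simulate import SimConfig, simulate_lateralized_power, simulate_subject


def desk_scale_config(seed: int = 0, **overrides) -> SimConfig:
    """The reduced problem size used by the demo pipeline: 5 subjects,
    40 trials per condition, 8 sensor channels; all rates, couplings and
    effect sizes at their full-scale defaults."""
    base = dict(
        n_subjects=5,
        n_trials_per_condition=40,
        n_channels=8,
        pattern_snr=0.7,
        # low-SNR rhythm regime: off-frequency phase estimates are noise-
        # dominated, so the modulation spectrum is frequency-specific
        modulator_noise_sd=2.0,
        seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)


def subject_modulation_spectrum(
    epochs: EpochSet,
    freqs,
    n_perm: int,
    seed: int,
    n_repetitions: int = 5,
    phase_channel: str = "mod",
) -> phase_binned.ModulationSpectrum:
    """Modulation spectrum of one subject on the standard trial selection."""
    selected = select_trials(epochs)
    return phase_binned.modulation_spectrum(
        selected,
        phase_channel=phase_channel,
        freqs=freqs,
        n_repetitions=n_repetitions,
        n_perm=n_perm,
        seed=seed,
    )


def group_modulation(
    spectra: list[phase_binned.ModulationSpectrum],
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> stats.ClusterResult:
    """Cluster-based group inference over the spectra's frequency grid."""
    samples = [
        stats.GroupSample(
            observed=np.array([sp.fits[f].amplitude for sp in spectra]),
            first_level_null=np.stack([sp.null_amplitudes[f] for sp in spectra]),
        )
        for f in range(len(spectra[0].freqs))
    ]
    return stats.cluster_test_over_freqs(
        samples, n_perm=n_perm, alpha=alpha, rng=np.random.default_rng((seed, 3))
    )


def overall_decoding(
    epochs: EpochSet,
    n_repetitions: int = 20,
    n_chance: int = 20,
    seed: int = 0,
) -> decoding.DecodingResult:
    """Single-bin decoding of the stimulus class with its empirical chance
    distribution (all observations in one bin)."""
    selected = select_trials(epochs)
    obs = phase_binned.select_analysis_window(selected)
    rng = np.random.default_rng((seed, 4))
    result = decoding.decode(obs, n_repetitions=n_repetitions, rng=rng)
    result.chance_distribution = decoding.empirical_chance(
        obs, n_shuffles=n_chance, rng=np.random.default_rng((seed, 5))
    )
    return result


def lateralization_demo(seed: int = 0, n_trials: int = 120, n_channels: int = 8):
    """AMI / LI on the lateralized-power fixture; returns (LI, AMIMap)."""
    config = SimConfig(
        n_trials_per_condition=n_trials, n_channels=n_channels, seed=seed
    )
    epochs = simulate_lateralized_power(config, subject_seed=(seed, 90))
    left = epochs.subset_trials(epochs.trial_table["attend"].to_numpy() == "left")
    right = epochs.subset_trials(epochs.trial_table["attend"].to_numpy() == "right")
    freqs = np.arange(4.0, 21.0, 1.0)
    tfr_l = spectral.tfr_hanning(left, freqs)
    tfr_r = spectral.tfr_hanning(right, freqs)
    ami_map = spectral.ami(tfr_l, tfr_r)
    n_half = n_channels // 2
    li = spectral.lateralization_index(
        ami_map,
        left_set=epochs.channel_names[:n_half],
        right_set=epochs.channel_names[n_half : 2 * n_half],
    )
    return li, ami_map


def rt_modulation_demo(epochs: EpochSet, f_mod: float, seed: int = 0):
    """Pre-target phase -> RT modulation on the standard trial selection."""
    selected = select_trials(epochs)
    phases, valid = behavior.phase_at_pretarget(selected, "mod", f_mod)
    rts = selected.trial_table["rt"].to_numpy(dtype=float)
    return behavior.rt_phase_modulation(
        phases[valid], rts[valid], rng=np.random.default_rng((seed, 6))
    )


def run_demo(seed: int = 0, freqs=None, n_perm: int = 20, n_subjects: int = 3):
    """Small end-to-end pass over every stage; returns a flat dict of the
    headline numbers.  Deterministic given ``seed``."""
    if freqs is None:
        freqs = [8.0, 10.0, 12.0]
    config = desk_scale_config(seed=seed, n_subjects=n_subjects)
    spectra = []
    rt_amp = []
    for s in range(n_subjects):
        epochs, truth = simulate_subject(config, (seed, s))
        spectra.append(
            subject_modulation_spectrum(epochs, freqs, n_perm=n_perm, seed=seed + s)
        )
        rt_amp.append(rt_modulation_demo(epochs, config.f_mod, seed=seed + s).fit.amplitude)
    cluster = group_modulation(spectra, n_perm=200, seed=seed)
    epochs0, _ = simulate_subject(config, (seed, 0))
    dec = overall_decoding(epochs0, n_repetitions=10, n_chance=10, seed=seed)
    li, _ = lateralization_demo(seed=seed)
    amps = np.mean([sp.amplitudes for sp in spectra], axis=0)
    peak = int(np.argmax(amps))
    return {
        "freqs": list(map(float, freqs)),
        "group_mean_amplitude": amps.tolist(),
        "peak_freq_hz": float(freqs[peak]),
        "peak_amplitude_pct": float(amps[peak]),
        "cluster_min_p": cluster.min_p(),
        "decoding_accuracy_pct": dec.accuracy,
        "chance_mean_pct": float(np.mean(dec.chance_distribution)),
        "lateralization_index_pct": float(li),
        "rt_modulation_amplitude_ms": float(np.mean(rt_amp) * 1000.0),
    }
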