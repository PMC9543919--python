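"""Phasic modulation of behavioral performance (reaction times, accuracy).

One phase per trial is estimated from a two-cycle window that ends exactly
at target onset (centered one cycle before it), so the estimate cannot be
contaminated by the stimulus change.  Mean reaction time is then computed
in a 90-degree window centered on each of 18 phase-bin centers (overlapping
boxcar smoothing, 20-degree spacing), a one-cycle cosine is fitted, and a
null distribution of fit amplitudes is built by shuffling reaction times
over trials.

Note the boxcar: averaging a cosine over a window of width W attenuates
its amplitude by sin(W/2)/(W/2) (~0.900 for W = 90 deg); recovery tests
must divide by this factor when comparing against a generative coupling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import EpochSet
from .phase_binned import ModulationFit, fit_cosine
from .spectral import window_phase, wrap_phase

__all__ = [
    "BehaviorModulation",
    "phase_at_pretarget",
    "rt_phase_modulation",
    "accuracy_phase_modulation",
    "boxcar_attenuation",
]


def boxcar_attenuation(window_width_deg: float) -> float:
    """Amplitude attenuation of a cosine averaged over a boxcar window."""
    half = np.deg2rad(window_width_deg) / 2.0
    return float(np.sin(half) / half)


@dataclass
class BehaviorModulation:
    """Binned behavioral scores with cosine fit and shuffle null."""

    bin_values: np.ndarray           # seconds (RT) or percent (accuracy)
    bin_centers: np.ndarray
    fit: ModulationFit
    null_amplitudes: np.ndarray
    flagged: np.ndarray              # bins with an empty window


def phase_at_pretarget(
    epochs: EpochSet,
    phase_channel: str,
    freq: float,
    pad_to: float = 4.0,
    window_cycles: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """One pre-target phase per trial.

    The two-cycle estimation window is centered one cycle before each
    trial's target onset so that it ends exactly at target onset.  Returns
    ``(phases, valid)``; trials whose window is truncated are flagged
    invalid.  If every trial is invalid an error is raised."""
    data = epochs.get_channel(phase_channel)
    onsets = epochs.trial_table["target_onset"].to_numpy(dtype=float)
    cycle = 1.0 / freq
    phases = np.full(epochs.n_trials, np.nan)
    valid = np.zeros(epochs.n_trials, dtype=bool)
    for onset in np.unique(onsets):
        rows = np.flatnonzero(onsets == onset)
        center = np.array([onset - cycle])
        ph, ok, _ = window_phase(
            data[rows], epochs.times, epochs.fs, freq, center,
            pad_to=pad_to, window_cycles=window_cycles,
        )
        if ok[0]:
            phases[rows] = ph[:, 0]
            valid[rows] = True
    if not valid.any():
        raise ValueError(
            "pre-target phase window does not fit in the epoch for any trial"
        )
    return phases, valid


def _windowed_means(
    phases: np.ndarray,
    values: np.ndarray,
    n_bins: int,
    window_width_deg: float,
):
    """Mean of ``values`` within a half-open circular window centered on
    each bin center."""
    centers = wrap_phase(
        -np.pi + (np.arange(n_bins) + 0.5) * 2.0 * np.pi / n_bins
    )
    half = np.deg2rad(window_width_deg) / 2.0
    means = np.full(n_bins, np.nan)
    flagged = np.zeros(n_bins, dtype=bool)
    for k, c in enumerate(centers):
        d = wrap_phase(phases - c)
        rows = (d >= -half) & (d < half)       # lower edge in, upper out
        if rows.any():
            means[k] = values[rows].mean()
        else:
            flagged[k] = True
    return means, centers, flagged


def _phase_modulation(
    phases, values, n_bins, window_width_deg, n_shuffles, rng
) -> BehaviorModulation:
    if n_bins < 3:
        raise ValueError("need at least 3 bins for the cosine fit")
    phases = np.asarray(phases, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(phases) & np.isfinite(values)
    if not ok.any():
        raise ValueError("no valid trials")
    phases, values = phases[ok], values[ok]
    means, centers, flagged = _windowed_means(
        phases, values, n_bins, window_width_deg
    )
    fit = fit_cosine(means, centers)
    rng = np.random.default_rng() if rng is None else rng
    nulls = np.empty(n_shuffles)
    for s in range(n_shuffles):
        shuffled = rng.permutation(values)
        m, _, _ = _windowed_means(phases, shuffled, n_bins, window_width_deg)
        nulls[s] = fit_cosine(m, centers).amplitude
    return BehaviorModulation(
        bin_values=means, bin_centers=centers, fit=fit,
        null_amplitudes=nulls, flagged=flagged,
    )


def rt_phase_modulation(
    phases: np.ndarray,
    rts: np.ndarray,
    n_bins: int = 18,
    window_width_deg: float = 90.0,
    n_shuffles: int = 100,
    rng: np.random.Generator | None = None,
    rt_range: tuple[float, float] | None = None,
) -> BehaviorModulation:
    """Phasic modulation of reaction time.

    ``rt_range`` optionally trims RTs to a closed interval (e.g. the
    response window) before binning; default keeps all trials."""
    rts = np.asarray(rts, dtype=float)
    if rt_range is not None:
        keep = (rts >= rt_range[0]) & (rts <= rt_range[1])
        phases = np.asarray(phases, dtype=float)[keep]
        rts = rts[keep]
    return _phase_modulation(phases, rts, n_bins, window_width_deg, n_shuffles, rng)


def accuracy_phase_modulation(
    phases: np.ndarray,
    correct: np.ndarray,
    n_bins: int = 18,
    window_width_deg: float = 90.0,
    n_shuffles: int = 100,
    rng: np.random.Generator | None = None,
) -> BehaviorModulation:
    """Phasic modulation of percent-correct behavior."""
    values = 100.0 * np.asarray(correct, dtype=float)
    return _phase_modulation(phases, values, n_bins, window_width_deg, n_shuffles, rng)
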