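"""Phase-binned decoding, cosine-fit modulation depth, and the
circular-shift permutation null.

The core statistic: assign every observation (trial-timepoint inside the
analysis window) to one of ``n_bins`` equidistant phase bins using the
phase-providing channel's instantaneous phase at that time, decode the
stimulus class independently within every bin, and fit a one-cycle cosine
``y_k ~ c + a*cos(theta_k - phi_pref)`` to the bin accuracies.  The
amplitude ``a`` is the modulation depth; ``phi_pref`` the optimal phase.

The null preserves within-trial temporal structure: each trial's phase
time course is shifted by an independent constant offset drawn uniformly
from (-2*pi, 2*pi) and re-wrapped before re-binning; the whole per-bin
decoding and cosine fit is then recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .containers import EpochSet
from .decoding import ObservationSet, _decode_once
from .spectral import PhaseTimecourse, estimate_phase, wrap_phase

__all__ = [
    "PhaseBinning",
    "ModulationFit",
    "ModulationSpectrum",
    "select_analysis_window",
    "bin_by_phase",
    "observation_bins",
    "decode_per_bin",
    "fit_cosine",
    "circular_shift_null",
    "modulation_spectrum",
]


# ---------------------------------------------------------------------------
# observations & binning
# ---------------------------------------------------------------------------

def select_analysis_window(
    epochs: EpochSet,
    window: tuple[float, float] = (0.4, 1.0),
    channels: Sequence[str] | None = None,
) -> ObservationSet:
    """Turn every retained sample into one observation row.

    ``window`` is closed-open in seconds; ``channels`` defaults to all
    channels with the ``neural`` role.  The binary label is the stimulus
    orientation (CW=1, CCW=0)."""
    t0, t1 = window
    eps = 0.5 / epochs.fs
    if t0 < epochs.times[0] - eps or t1 > epochs.times[-1] + 1.0 / epochs.fs + eps:
        raise ValueError("analysis window extends outside the epoch")
    mask = (epochs.times >= t0 - eps) & (epochs.times < t1 - eps)
    sample_idx = np.flatnonzero(mask)
    if sample_idx.size == 0:
        raise ValueError("analysis window contains no samples")
    if channels is None:
        ch_idx = epochs.channels_with_role("neural")
    else:
        ch_idx = np.array([epochs.channel_index(c) for c in channels])
    if ch_idx.size == 0:
        raise ValueError("no channels selected")
    orientation = epochs.trial_table["orientation"].to_numpy()
    y_trial = (orientation == "CW").astype(np.int8)

    n_trials, n_t = epochs.n_trials, sample_idx.size
    block = epochs.data[:, ch_idx][:, :, sample_idx]          # (tr, ch, t)
    X = block.transpose(0, 2, 1).reshape(n_trials * n_t, ch_idx.size)
    trial = np.repeat(np.arange(n_trials), n_t)
    timepoint = np.tile(sample_idx, n_trials)
    time_s = np.tile(epochs.times[sample_idx], n_trials)
    y = np.repeat(y_trial, n_t)
    return ObservationSet(X=X, y=y, trial=trial, timepoint=timepoint, time_s=time_s)


@dataclass
class PhaseBinning:
    """Equidistant partition of [-pi, pi) with per-(trial, timepoint)
    assignment on the phase grid; -1 marks invalid phase samples."""

    n_bins: int
    edges: np.ndarray                  # (n_bins + 1,)
    assignment: np.ndarray             # (trials, grid timepoints), int
    times: np.ndarray                  # phase grid times (s)
    step: float

    @property
    def centers(self) -> np.ndarray:
        return (self.edges[:-1] + self.edges[1:]) / 2.0


def bin_by_phase(phase_tc: PhaseTimecourse, n_bins: int = 18) -> PhaseBinning:
    """Bin k covers [-pi + k*2pi/n, -pi + (k+1)*2pi/n); invalid -> -1."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    width = 2.0 * np.pi / n_bins
    edges = -np.pi + width * np.arange(n_bins + 1)
    phi = phase_tc.phase
    with np.errstate(invalid="ignore"):
        idx = np.floor((phi + np.pi) / width)
    idx = np.where(np.isnan(phi), -1, np.clip(idx, 0, n_bins - 1)).astype(np.int16)
    idx[:, ~phase_tc.valid] = -1
    return PhaseBinning(
        n_bins=n_bins, edges=edges, assignment=idx,
        times=phase_tc.times, step=phase_tc.step,
    )


def observation_bins(obs: ObservationSet, binning: PhaseBinning) -> np.ndarray:
    """Bin index per observation (nearest phase-grid timepoint; -1 invalid)."""
    if obs.time_s is None:
        raise ValueError("observations carry no time stamps")
    gi = np.clip(
        np.round((obs.time_s - binning.times[0]) / binning.step).astype(int),
        0,
        binning.times.size - 1,
    )
    return binning.assignment[obs.trial, gi]


# ---------------------------------------------------------------------------
# per-bin decoding
# ---------------------------------------------------------------------------

@dataclass
class BinDecoding:
    """Per-bin cross-validated accuracies; NaN where a bin was flagged."""

    accuracies: np.ndarray             # (n_bins,) percent
    flagged: np.ndarray                # (n_bins,) bool, too few observations
    counts: np.ndarray                 # (n_bins, 2) obs per class


def decode_per_bin(
    obs: ObservationSet,
    binning: PhaseBinning,
    n_repetitions: int = 20,
    group_size: int = 5,
    variance_kept: float = 0.99,
    n_folds: int = 5,
    rng: np.random.Generator | None = None,
    C: float = 1.0,
    min_per_class: int | None = None,
) -> BinDecoding:
    """Run the full decoding pipeline independently inside every phase bin.

    Bins with fewer than ``min_per_class`` (default ``n_folds*group_size``)
    observations in either class are flagged and reported as NaN, never
    silently dropped."""
    rng = np.random.default_rng() if rng is None else rng
    if min_per_class is None:
        min_per_class = max(2 * group_size, n_folds * group_size)
    bins = observation_bins(obs, binning)
    n_bins = binning.n_bins
    acc = np.full(n_bins, np.nan)
    flagged = np.zeros(n_bins, dtype=bool)
    counts = np.zeros((n_bins, 2), dtype=int)
    for b in range(n_bins):
        rows = np.flatnonzero(bins == b)
        yb = obs.y[rows]
        counts[b] = [np.sum(yb == 0), np.sum(yb == 1)]
        if counts[b].min() < min_per_class:
            flagged[b] = True
            continue
        Xb = obs.X[rows]
        tb = obs.trial[rows]
        reps = np.empty(n_repetitions)
        for r in range(n_repetitions):
            fold_accs, _ = _decode_once(
                Xb, yb, tb, group_size, variance_kept, n_folds, rng, C=C
            )
            reps[r] = fold_accs.mean()
        acc[b] = reps.mean()
    return BinDecoding(accuracies=acc, flagged=flagged, counts=counts)


# ---------------------------------------------------------------------------
# cosine fit
# ---------------------------------------------------------------------------

@dataclass
class ModulationFit:
    """One-cycle cosine fit to scores over phase bins."""

    amplitude: float                   # a >= 0, units of the scores
    preferred_phase: float             # [-pi, pi)
    offset: float                      # c, the mean score
    bin_scores: np.ndarray
    bin_centers: np.ndarray
    fallback_lstsq: bool = False       # explicit LS path was used


def _is_equidistant_full_circle(centers: np.ndarray) -> bool:
    if centers.size < 3:
        return False
    d = np.diff(centers)
    return np.allclose(d, d[0], atol=1e-9) and np.isclose(
        d[0] * centers.size, 2.0 * np.pi, atol=1e-6
    )


def fit_cosine(
    bin_scores: Sequence[float], bin_centers: Sequence[float]
) -> ModulationFit:
    """Least-squares fit of ``y_k ~ c + a*cos(theta_k - phi_pref)`` with
    ``c`` fixed at the mean of the available scores.

    For complete equidistant bins this is the closed form
    ``a = (2/N)|sum y_k exp(-i theta_k)|``,
    ``phi_pref = arg(sum y_k exp(+i theta_k))``; with missing bins or
    non-equidistant centers it falls back to explicit least squares on the
    available bins (flagged in the result)."""
    y = np.asarray(bin_scores, dtype=float)
    theta = np.asarray(bin_centers, dtype=float)
    if y.shape != theta.shape:
        raise ValueError("scores and centers must have matching shape")
    ok = np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("need at least 3 finite bins for the cosine fit")
    complete = ok.all() and _is_equidistant_full_circle(theta)
    if complete:
        z = np.sum(y * np.exp(1j * theta)) * (2.0 / y.size)
        amplitude = float(np.abs(z))
        phi = float(wrap_phase(np.angle(z)))
        offset = float(y.mean())
        fallback = False
    else:
        # with missing or non-equidistant bins the mean is no longer the
        # least-squares intercept, so c is fitted jointly
        yv, tv = y[ok], theta[ok]
        A = np.column_stack([np.ones_like(tv), np.cos(tv), np.sin(tv)])
        coef, *_ = np.linalg.lstsq(A, yv, rcond=None)
        offset = float(coef[0])
        amplitude = float(np.hypot(coef[1], coef[2]))
        phi = float(wrap_phase(np.arctan2(coef[2], coef[1])))
        fallback = True
    return ModulationFit(
        amplitude=amplitude, preferred_phase=phi, offset=offset,
        bin_scores=y, bin_centers=theta, fallback_lstsq=fallback,
    )


# ---------------------------------------------------------------------------
# circular-shift null and the spectrum over frequencies
# ---------------------------------------------------------------------------

def circular_shift_null(
    phase_tc: PhaseTimecourse,
    obs: ObservationSet,
    n_perm: int = 100,
    rng: np.random.Generator | None = None,
    n_bins: int = 18,
    offsets: np.ndarray | None = None,
    mode: str = "offset",
    decode_seed: int | None = None,
    **decode_kwargs,
) -> np.ndarray:
    """Null modulation amplitudes from randomized phase binning.

    Per permutation every trial's phase time course receives an independent
    uniform offset in (-2*pi, 2*pi) (wrapped back to [-pi, pi)), the data
    are re-binned, and the per-bin decoding plus cosine fit is recomputed.
    ``mode="roll"`` instead rotates each trial's phase samples in time
    (sensitivity variant).  The per-bin decoder inside every permutation is
    seeded with ``decode_seed`` so that a zero offset reproduces the
    observed amplitude exactly."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    n_trials = phase_tc.n_trials
    out = np.empty(n_perm)
    for p in range(n_perm):
        if mode == "offset":
            delta = (
                offsets if offsets is not None
                else rng.uniform(-2.0 * np.pi, 2.0 * np.pi, size=n_trials)
            )
            shifted = phase_tc.shifted(delta)
        elif mode == "roll":
            n_valid = int(phase_tc.valid.sum())
            shifts = rng.integers(0, max(n_valid, 1), size=n_trials)
            shifted = phase_tc.rolled(shifts)
        else:
            raise ValueError(f"unknown null mode {mode!r}")
        binning = bin_by_phase(shifted, n_bins)
        dec_rng = (
            np.random.default_rng(decode_seed) if decode_seed is not None else rng
        )
        bd = decode_per_bin(obs, binning, rng=dec_rng, **decode_kwargs)
        out[p] = fit_cosine(bd.accuracies, binning.centers).amplitude
    return out


@dataclass
class ModulationSpectrum:
    """Cosine-fit modulation per frequency plus first-level null draws."""

    freqs: np.ndarray
    fits: list[ModulationFit]
    null_amplitudes: np.ndarray          # (n_freqs, n_perm)
    bin_accuracies: np.ndarray           # (n_freqs, n_bins)

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([f.amplitude for f in self.fits])

    @property
    def preferred_phases(self) -> np.ndarray:
        return np.array([f.preferred_phase for f in self.fits])

    def peak_frequency(self) -> float:
        return float(self.freqs[int(np.argmax(self.amplitudes))])


def modulation_spectrum(
    epochs: EpochSet,
    phase_channel: str,
    freqs: Sequence[float],
    window: tuple[float, float] = (0.4, 1.0),
    n_bins: int = 18,
    n_repetitions: int = 20,
    n_perm: int = 100,
    group_size: int = 5,
    variance_kept: float = 0.99,
    n_folds: int = 5,
    seed: int = 0,
    C: float = 1.0,
    pad_to: float = 4.0,
    phase_step: float = 0.005,
    window_cycles: float = 2.0,
    channels: Sequence[str] | None = None,
) -> ModulationSpectrum:
    """Phase-binned decoding repeated for every frequency of interest.

    Per frequency: estimate the phase time course of ``phase_channel``,
    bin, decode per bin, fit the cosine; then build the circular-shift
    null (``n_perm`` draws, 0 to skip)."""
    if len(freqs) == 0:
        raise ValueError("empty frequency list")
    obs = select_analysis_window(epochs, window, channels=channels)
    fits: list[ModulationFit] = []
    n_perm_eff = int(n_perm)
    nulls = np.empty((len(freqs), n_perm_eff))
    bin_acc = np.empty((len(freqs), n_bins))
    decode_kwargs = dict(
        n_repetitions=n_repetitions, group_size=group_size,
        variance_kept=variance_kept, n_folds=n_folds, C=C,
    )
    for i, f in enumerate(freqs):
        phase_tc = estimate_phase(
            epochs, phase_channel, f, pad_to=pad_to, step=phase_step,
            window_cycles=window_cycles,
        )
        binning = bin_by_phase(phase_tc, n_bins)
        khz = int(round(float(f) * 1000))
        dec_seed = (seed, 1, khz)        # decode stream, shared with the null
        bd = decode_per_bin(
            obs, binning, rng=np.random.default_rng(dec_seed), **decode_kwargs
        )
        fits.append(fit_cosine(bd.accuracies, binning.centers))
        bin_acc[i] = bd.accuracies
        if n_perm_eff:
            shift_rng = np.random.default_rng((seed, 2, khz))
            nulls[i] = circular_shift_null(
                phase_tc, obs, n_perm=n_perm_eff, rng=shift_rng, n_bins=n_bins,
                decode_seed=dec_seed, **decode_kwargs,
            )
    return ModulationSpectrum(
        freqs=np.asarray(list(freqs), dtype=float), fits=fits,
        null_amplitudes=nulls, bin_accuracies=bin_acc,
    )
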