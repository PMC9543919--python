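"""Time-frequency power, attentional modulation indices, and instantaneous
phase via tapered sliding-window Fourier transforms.

Phase is defined as the four-quadrant arctangent of the imaginary over the
real part of the Fourier coefficient of a Hanning-tapered window of
``window_cycles`` cycles, centered on the output time point, on a frequency
grid set by zero-padding the window to ``pad_to`` seconds.  Output is
produced only where the full window fits inside the epoch; truncated
positions are flagged invalid, never silently zeroed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.signal import windows

from .containers import EpochSet


def wrap_phase(phi):
    """Wrap angles to [-pi, pi)."""
    return np.mod(np.asarray(phi) + np.pi, 2.0 * np.pi) - np.pi


class ChannelSet(NamedTuple):
    """A named selection of channels (e.g. left-posterior sensors)."""

    name: str
    channels: tuple[str, ...]


# ---------------------------------------------------------------------------
# sliding-window bookkeeping
# ---------------------------------------------------------------------------

def _step_grid(times: np.ndarray, step: float) -> np.ndarray:
    """Centers on multiples of ``step`` (seconds) inside the time axis."""
    k0 = int(math.ceil(round(times[0] / step, 9)))
    k1 = int(math.floor(round(times[-1] / step, 9)))
    return np.arange(k0, k1 + 1) * step


def _window_slices(times, fs, centers, win_n):
    """Start index of each window and a validity mask (full fit inside)."""
    n = times.size
    ic = np.round((centers - times[0]) * fs).astype(int)
    start = ic - win_n // 2
    valid = (start >= 0) & (start + win_n <= n)
    return start, valid


def snap_frequency(freq: float, pad_to: float) -> float:
    """Nearest representable frequency on the 1/pad_to grid."""
    return round(freq * pad_to) / pad_to


# ---------------------------------------------------------------------------
# TFR
# ---------------------------------------------------------------------------

@dataclass
class TFR:
    """Per-trial (or trial-averaged) time-frequency power.

    ``power`` has shape (trials, channels, freqs, times); entries at
    positions whose window does not fit inside the epoch are NaN and
    flagged False in ``valid`` (freqs x times).
    """

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    valid: np.ndarray
    method: str
    channel_names: list[str]

    def trial_average(self) -> np.ndarray:
        return self.power.mean(axis=0)


def _sliding_power(data, times, fs, freqs, win_n, taper_set, centers, pad_n):
    """|X|^2 at the requested (snapped) frequencies for one window length.

    ``taper_set`` is (n_tapers, win_n); power is averaged over tapers.
    Normalization: a unit-amplitude sinusoid at a grid frequency gives
    power ~1 with a single Hanning taper.
    """
    start, valid = _window_slices(times, fs, centers, win_n)
    n_trials, n_ch = data.shape[0], data.shape[1]
    out = np.full((n_trials, n_ch, len(freqs), len(centers)), np.nan)
    if not valid.any():
        return out, valid
    sw = np.lib.stride_tricks.sliding_window_view(data, win_n, axis=-1)
    segs = sw[:, :, start[valid], :]                  # (tr, ch, nv, win)
    tau = (np.arange(win_n) - (win_n - 1) / 2.0) / fs
    acc = None
    for taper in taper_set:
        basis = taper[None, :] * np.exp(
            -2j * np.pi * np.asarray(freqs)[:, None] * tau[None, :]
        )  # (nf, win)
        norm = 2.0 / taper.sum()
        coef = np.einsum("tcvw,fw->tcfv", segs, basis) * norm
        p = np.abs(coef) ** 2
        acc = p if acc is None else acc + p
    out[:, :, :, valid] = acc / len(taper_set)
    return out, valid


def tfr_hanning(
    epochs: EpochSet,
    freqs: Sequence[float],
    win_len: float = 0.5,
    step: float = 0.1,
    pad_to: float = 4.0,
) -> TFR:
    """Hanning-tapered sliding-window power (low-frequency analysis).

    ``pad_to`` fixes the frequency grid (1/pad_to spacing); requested
    frequencies are snapped to the nearest grid point.
    """
    epoch_len = epochs.n_samples / epochs.fs
    if win_len > epoch_len:
        raise ValueError("window longer than epoch")
    if pad_to < epoch_len:
        raise ValueError("pad_to must be at least the epoch length")
    nyq = epochs.fs / 2.0
    if np.max(freqs) > nyq:
        raise ValueError("requested frequency above Nyquist")
    win_n = int(round(win_len * epochs.fs))
    taper = windows.hann(win_n, sym=False)
    centers = _step_grid(epochs.times, step)
    pad_n = int(round(pad_to * epochs.fs))
    snapped = np.array([snap_frequency(f, pad_to) for f in freqs])
    power, valid = _sliding_power(
        epochs.data, epochs.times, epochs.fs, snapped, win_n, [taper], centers, pad_n
    )
    valid2d = np.broadcast_to(valid, (len(snapped), len(centers))).copy()
    return TFR(
        power=power, freqs=snapped, times=centers, valid=valid2d,
        method="hanning", channel_names=list(epochs.channel_names),
    )


def tfr_multitaper(
    epochs: EpochSet,
    freqs: Sequence[float],
    cycles_per_window: float = 5.0,
    step: float = 0.05,
    smoothing_fraction: float = 0.2,
    pad_to: float = 4.0,
) -> TFR:
    """DPSS multitaper power with frequency-proportional smoothing.

    The window holds ``cycles_per_window`` cycles of each frequency and the
    spectral (half-)smoothing is ``smoothing_fraction * f`` Hz.
    """
    if smoothing_fraction <= 0:
        raise ValueError("smoothing_fraction must be > 0")
    epoch_len = epochs.n_samples / epochs.fs
    nyq = epochs.fs / 2.0
    if np.max(freqs) > nyq:
        raise ValueError("requested frequency above Nyquist")
    centers = _step_grid(epochs.times, step)
    pad_n = int(round(pad_to * epochs.fs))
    n_trials, n_ch = epochs.n_trials, epochs.n_channels
    power = np.full((n_trials, n_ch, len(freqs), len(centers)), np.nan)
    valid2d = np.zeros((len(freqs), len(centers)), dtype=bool)
    snapped = []
    for i, f in enumerate(freqs):
        f_used = snap_frequency(f, pad_to)
        snapped.append(f_used)
        win_len = cycles_per_window / f
        if win_len > epoch_len:
            raise ValueError(f"{cycles_per_window} cycles of {f} Hz exceed the epoch")
        win_n = int(round(win_len * epochs.fs))
        nw = win_len * smoothing_fraction * f
        k = max(1, int(math.floor(2 * nw - 1)))
        if k == 1:
            tapers = [windows.hann(win_n, sym=False)]
        else:
            tapers = list(windows.dpss(win_n, nw, Kmax=k))
        p, valid = _sliding_power(
            epochs.data, epochs.times, epochs.fs, [f_used], win_n, tapers,
            centers, pad_n,
        )
        power[:, :, i, :] = p[:, :, 0, :]
        valid2d[i] = valid
    return TFR(
        power=power, freqs=np.array(snapped), times=centers, valid=valid2d,
        method="multitaper", channel_names=list(epochs.channel_names),
    )


# ---------------------------------------------------------------------------
# Attentional modulation / lateralization
# ---------------------------------------------------------------------------

@dataclass
class AMIMap:
    """Attentional modulation index in percent, channels x freqs x times."""

    values: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    channel_names: list[str]
    defined: np.ndarray      # False where P_left + P_right == 0


def ami(tfr_left: TFR, tfr_right: TFR) -> AMIMap:
    """Percent power increase of attend-left over attend-right trials:
    ``100 * (P_left - P_right) / (P_left + P_right)``, trial-averaged.

    Elements with zero total power are flagged undefined (NaN + mask),
    with a warning rather than silent propagation.
    """
    if not np.array_equal(tfr_left.freqs, tfr_right.freqs) or not np.array_equal(
        tfr_left.times, tfr_right.times
    ):
        raise ValueError("TFR frequency/time axes do not match")
    if tfr_left.channel_names != tfr_right.channel_names:
        raise ValueError("TFR channels do not match")
    p_l = tfr_left.trial_average()
    p_r = tfr_right.trial_average()
    total = p_l + p_r
    with np.errstate(invalid="ignore", divide="ignore"):
        values = 100.0 * (p_l - p_r) / total
    defined = ~np.isnan(values)
    zero_total = np.isfinite(total) & (total == 0)
    if zero_total.any():
        warnings.warn(
            f"AMI undefined at {int(zero_total.sum())} zero-power elements",
            RuntimeWarning,
            stacklevel=2,
        )
        defined &= ~zero_total
        values = np.where(zero_total, np.nan, values)
    return AMIMap(
        values=values, freqs=tfr_left.freqs, times=tfr_left.times,
        channel_names=list(tfr_left.channel_names), defined=defined,
    )


def lateralization_index(
    ami_map: AMIMap,
    left_set: ChannelSet | Sequence[str],
    right_set: ChannelSet | Sequence[str],
    time_window: tuple[float, float] = (-0.6, -0.2),
    freq_window: tuple[float, float] = (8.0, 13.0),
) -> float:
    """Mean AMI over the left channel set minus the right channel set,
    inside a closed time-frequency window (defaults: pre-stimulus alpha)."""
    left = left_set.channels if isinstance(left_set, ChannelSet) else tuple(left_set)
    right = right_set.channels if isinstance(right_set, ChannelSet) else tuple(right_set)
    if not left or not right:
        raise ValueError("channel sets must be nonempty")
    li = [ami_map.channel_names.index(c) for c in left]
    ri = [ami_map.channel_names.index(c) for c in right]
    fmask = (ami_map.freqs >= freq_window[0]) & (ami_map.freqs <= freq_window[1])
    tmask = (ami_map.times >= time_window[0]) & (ami_map.times <= time_window[1])
    if not fmask.any() or not tmask.any():
        raise ValueError("time-frequency window does not intersect the map")
    sub = ami_map.values[:, fmask][:, :, tmask]
    left_vals = sub[li]
    right_vals = sub[ri]
    if np.all(np.isnan(left_vals)) or np.all(np.isnan(right_vals)):
        raise ValueError("window is empty after masking invalid samples")
    return float(np.nanmean(left_vals) - np.nanmean(right_vals))


# ---------------------------------------------------------------------------
# Instantaneous phase
# ---------------------------------------------------------------------------

@dataclass
class PhaseTimecourse:
    """Instantaneous phase at one frequency on a fixed step grid.

    ``phase`` is (trials x timepoints) in [-pi, pi), NaN at invalid
    positions (window truncated by the epoch edge); ``valid`` flags the
    timepoints whose estimation window fits inside the epoch.
    """

    phase: np.ndarray
    valid: np.ndarray
    times: np.ndarray
    freq: float                 # requested frequency, Hz
    freq_used: float            # snapped to the padding grid
    step: float
    window_cycles: float
    channel: str

    @property
    def n_trials(self) -> int:
        return self.phase.shape[0]

    def nearest_index(self, t: np.ndarray) -> np.ndarray:
        """Index of the nearest grid timepoint for each time in ``t``."""
        return np.clip(
            np.round((np.asarray(t) - self.times[0]) / self.step).astype(int),
            0,
            self.times.size - 1,
        )

    def shifted(self, offsets: np.ndarray) -> "PhaseTimecourse":
        """Per-trial constant phase offsets, wrapped (circular-shift null)."""
        offsets = np.asarray(offsets, dtype=float)
        shifted = wrap_phase(self.phase + offsets[:, None])
        shifted[:, ~self.valid] = np.nan
        return PhaseTimecourse(
            phase=shifted, valid=self.valid.copy(), times=self.times,
            freq=self.freq, freq_used=self.freq_used, step=self.step,
            window_cycles=self.window_cycles, channel=self.channel,
        )

    def rolled(self, shifts: np.ndarray) -> "PhaseTimecourse":
        """Temporal rotation of each trial's valid phase samples
        (sensitivity-analysis variant of the circular-shift null)."""
        shifts = np.asarray(shifts, dtype=int)
        out = self.phase.copy()
        vi = np.flatnonzero(self.valid)
        for t in range(self.phase.shape[0]):
            out[t, vi] = np.roll(self.phase[t, vi], shifts[t])
        return PhaseTimecourse(
            phase=out, valid=self.valid.copy(), times=self.times,
            freq=self.freq, freq_used=self.freq_used, step=self.step,
            window_cycles=self.window_cycles, channel=self.channel,
        )


def window_phase(
    data: np.ndarray,
    times: np.ndarray,
    fs: float,
    freq: float,
    centers: np.ndarray,
    pad_to: float = 4.0,
    window_cycles: float = 2.0,
):
    """Phase of the Hanning-tapered Fourier coefficient at ``freq`` for
    windows centered on ``centers``; returns (phase, valid, freq_used).

    The window covers ``window_cycles / freq`` seconds; the coefficient's
    time origin is the window center, so the angle is the instantaneous
    phase there.  ``data`` is (trials, samples).
    """
    freq_used = snap_frequency(freq, pad_to)
    if freq_used <= 0:
        raise ValueError("frequency too low to represent after padding")
    if freq_used > fs / 2:
        raise ValueError("frequency above Nyquist")
    win_len = window_cycles / freq
    if win_len > times[-1] - times[0] + 1.0 / fs:
        raise ValueError("phase window does not fit in the epoch")
    win_n = int(round(win_len * fs))
    start, valid = _window_slices(times, fs, centers, win_n)
    taper = windows.hann(win_n, sym=False)
    tau = (np.arange(win_n) - (win_n - 1) / 2.0) / fs
    basis = taper * np.exp(-2j * np.pi * freq_used * tau)
    phase = np.full((data.shape[0], centers.size), np.nan)
    if valid.any():
        sw = np.lib.stride_tricks.sliding_window_view(data, win_n, axis=-1)
        segs = sw[:, start[valid], :]              # (trials, nv, win)
        coef = segs @ basis
        # correct for the sub-sample offset between the nominal center and
        # the actual center of the sampled window
        t_mid = times[start[valid]] + (win_n - 1) / (2.0 * fs)
        coef = coef * np.exp(-2j * np.pi * freq_used * (t_mid - centers[valid]))
        phase[:, valid] = wrap_phase(np.angle(coef))
    return phase, valid, freq_used


def estimate_phase(
    epochs: EpochSet,
    channel: str,
    freq: float,
    pad_to: float = 4.0,
    step: float = 0.005,
    window_cycles: float = 2.0,
) -> PhaseTimecourse:
    """Instantaneous phase time course of one channel at one frequency.

    Windows slide in steps of ``step`` seconds (default 5 ms); output
    positions whose window is truncated by the epoch edges are flagged
    invalid.  If ``freq`` is not representable on the 1/pad_to grid it is
    snapped to the nearest grid frequency, recorded in ``freq_used``.
    """
    data = epochs.get_channel(channel)
    centers = _step_grid(epochs.times, step)
    phase, valid, freq_used = window_phase(
        data, epochs.times, epochs.fs, freq, centers,
        pad_to=pad_to, window_cycles=window_cycles,
    )
    return PhaseTimecourse(
        phase=phase, valid=valid, times=centers,
        freq=freq, freq_used=freq_used, step=step,
        window_cycles=window_cycles, channel=channel,
    )
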