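"""Time-frequency power, AMI/LI, and instantaneous phase estimation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from phasedecode.containers import EpochSet
from phasedecode.spectral import (
    AMIMap,
    ami,
    estimate_phase,
    lateralization_index,
    snap_frequency,
    tfr_hanning,
    tfr_multitaper,
    wrap_phase,
)


def make_epochs(data, fs=200.0, t0=-1.0):
    n_trials, n_ch, n_samples = data.shape
    times = t0 + np.arange(n_samples) / fs
    table = pd.DataFrame(
        {
            "orientation": ["CW"] * n_trials,
            "attend": ["left"] * n_trials,
            "cue_valid": [True] * n_trials,
            "stim_duration": [1.0] * n_trials,
            "rt": [0.6] * n_trials,
            "correct": [True] * n_trials,
            "target_onset": [1.0] * n_trials,
        }
    )
    return EpochSet(
        data=data, times=times, fs=fs,
        channel_names=[f"ch{i}" for i in range(n_ch)],
        channel_roles=["neural"] * n_ch,
        trial_table=table,
    )


class TestTfrHanning:
    def test_zero_signal_gives_zero_power(self):
        ep = make_epochs(np.zeros((2, 1, 400)))
        tfr = tfr_hanning(ep, [10.0])
        assert np.nanmax(tfr.power) == 0.0

    def test_stationary_sinusoid_power_is_constant_inside(self):
        times = -1.0 + np.arange(400) / 200.0
        data = np.cos(2 * np.pi * 10.0 * times)[None, None, :].repeat(2, axis=0)
        tfr = tfr_hanning(make_epochs(data), [10.0])
        p = tfr.power[0, 0, 0, :]
        inner = p[np.isfinite(p)]
        assert inner.size > 5
        assert (inner.max() - inner.min()) / inner.mean() < 0.01

    def test_identical_trials_identical_spectrograms(self):
        rng = np.random.default_rng(0)
        one = rng.standard_normal((1, 2, 400))
        ep = make_epochs(np.concatenate([one, one]))
        tfr = tfr_hanning(ep, [6.0, 10.0])
        np.testing.assert_array_equal(tfr.power[0], tfr.power[1])

    def test_matches_direct_periodogram_oracle(self):
        # independent oracle: loop over windows, taper, zero-padded rfft
        rng = np.random.default_rng(1)
        data = rng.standard_normal((2, 1, 400))
        ep = make_epochs(data)
        freqs = [5.0, 11.0]
        win_len, step, pad_to = 0.5, 0.1, 4.0
        tfr = tfr_hanning(ep, freqs, win_len=win_len, step=step, pad_to=pad_to)
        win_n = int(win_len * 200)
        taper = np.hanning(win_n + 1)[:-1]          # periodic Hann
        pad_n = int(pad_to * 200)
        for fi, f in enumerate(freqs):
            bin_ix = int(round(f * pad_to))
            for ti, tc in enumerate(tfr.times):
                if not tfr.valid[fi, ti]:
                    continue
                i0 = int(round((tc - ep.times[0]) * 200)) - win_n // 2
                seg = data[:, 0, i0 : i0 + win_n] * taper
                spec = np.fft.rfft(seg, n=pad_n, axis=-1)[:, bin_ix]
                expected = np.abs(spec * 2.0 / taper.sum()) ** 2
                np.testing.assert_allclose(
                    tfr.power[:, 0, fi, ti], expected, rtol=1e-9
                )

    def test_rejects_bad_windows(self):
        ep = make_epochs(np.zeros((1, 1, 400)))
        with pytest.raises(ValueError):
            tfr_hanning(ep, [10.0], win_len=3.0)
        with pytest.raises(ValueError):
            tfr_hanning(ep, [150.0])


class TestTfrMultitaper:
    def test_zero_signal_gives_zero_power(self):
        ep = make_epochs(np.zeros((1, 1, 400)))
        tfr = tfr_multitaper(ep, [40.0, 55.0])
        assert np.nanmax(tfr.power) == 0.0

    def test_sinusoid_peaks_within_smoothing_band(self):
        times = -1.0 + np.arange(400) / 200.0
        data = np.cos(2 * np.pi * 55.0 * times)[None, None, :]
        freqs = np.arange(35.0, 80.0, 5.0)
        tfr = tfr_multitaper(make_epochs(data), freqs)
        mean_p = np.nanmean(tfr.power[0, 0], axis=1)
        peak_f = freqs[np.nanargmax(mean_p)]
        assert abs(peak_f - 55.0) <= 0.2 * 55.0

    def test_zero_smoothing_rejected(self):
        ep = make_epochs(np.zeros((1, 1, 400)))
        with pytest.raises(ValueError):
            tfr_multitaper(ep, [40.0], smoothing_fraction=0.0)


class TestAmi:
    def _tfr_pair(self, p_left, p_right):
        ep = make_epochs(np.zeros((1, 1, 400)))
        base = tfr_hanning(ep, [10.0])
        import copy

        tl, tr = copy.deepcopy(base), copy.deepcopy(base)
        tl.power = np.full_like(tl.power, p_left)
        tr.power = np.full_like(tr.power, p_right)
        return tl, tr

    def test_equal_power_gives_zero(self):
        tl, tr = self._tfr_pair(2.0, 2.0)
        assert np.all(ami(tl, tr).values == 0.0)

    def test_three_to_one_gives_fifty_percent(self):
        tl, tr = self._tfr_pair(3.0, 1.0)
        assert np.allclose(ami(tl, tr).values, 50.0)

    def test_antisymmetric_under_condition_swap(self):
        rng = np.random.default_rng(2)
        tl, tr = self._tfr_pair(1.0, 1.0)
        tl.power = rng.uniform(0.5, 2.0, tl.power.shape)
        tr.power = rng.uniform(0.5, 2.0, tr.power.shape)
        np.testing.assert_allclose(
            ami(tl, tr).values, -ami(tr, tl).values, atol=1e-12
        )

    def test_zero_total_power_flagged_not_silent(self):
        tl, tr = self._tfr_pair(0.0, 0.0)
        with pytest.warns(RuntimeWarning):
            out = ami(tl, tr)
        assert not out.defined.any()


class TestLateralizationIndex:
    def _map(self, values, channels=("L0", "L1", "R0", "R1")):
        freqs = np.arange(8.0, 14.0)
        times = np.arange(-0.8, 0.0, 0.1)
        full = np.broadcast_to(
            np.asarray(values)[:, None, None],
            (len(channels), freqs.size, times.size),
        ).copy()
        return AMIMap(
            values=full, freqs=freqs, times=times,
            channel_names=list(channels), defined=np.isfinite(full),
        )

    def test_constant_map_gives_zero(self):
        amap = self._map([7.0, 7.0, 7.0, 7.0])
        assert lateralization_index(amap, ["L0", "L1"], ["R0", "R1"]) == 0.0

    def test_direct_evaluation(self):
        amap = self._map([10.0, 10.0, -5.0, -5.0])
        assert lateralization_index(amap, ["L0", "L1"], ["R0", "R1"]) == 15.0

    def test_antisymmetric_under_set_swap(self):
        amap = self._map([4.0, 2.0, -1.0, 3.0])
        a = lateralization_index(amap, ["L0", "L1"], ["R0", "R1"])
        b = lateralization_index(amap, ["R0", "R1"], ["L0", "L1"])
        assert np.isclose(a, -b)

    def test_empty_channel_set_rejected(self):
        amap = self._map([1.0, 1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            lateralization_index(amap, [], ["R0"])


class TestEstimatePhase:
    def test_known_initial_phase_recovered_at_center(self):
        fs, f = 200.0, 10.0
        times = -1.0 + np.arange(400) / fs
        for phi0 in (-2.0, 0.0, 1.3):
            data = np.cos(2 * np.pi * f * times + phi0)[None, None, :]
            tc = estimate_phase(make_epochs(data), "ch0", f)
            expected = wrap_phase(2 * np.pi * f * tc.times + phi0)
            err = np.angle(np.exp(1j * (tc.phase[0, tc.valid] - expected[tc.valid])))
            assert np.abs(err).max() < 0.05

    def test_phase_advances_at_carrier_rate(self):
        fs, f = 200.0, 7.0
        times = -1.0 + np.arange(400) / fs
        data = np.cos(2 * np.pi * f * times + 0.5)[None, None, :]
        tc = estimate_phase(make_epochs(data), "ch0", f)
        unwrapped = np.unwrap(tc.phase[0, tc.valid])
        inc = np.median(np.diff(unwrapped))
        assert abs(inc - 2 * np.pi * f * tc.step) / (2 * np.pi * f * tc.step) < 0.05

    def test_frequency_snapping_recorded(self):
        ep = make_epochs(np.zeros((1, 1, 400)))
        tc = estimate_phase(ep, "ch0", 10.1, pad_to=4.0)
        assert tc.freq == 10.1
        assert tc.freq_used == snap_frequency(10.1, 4.0) == 10.0

    def test_edges_flagged_invalid(self):
        ep = make_epochs(np.zeros((1, 1, 400)))
        tc = estimate_phase(ep, "ch0", 4.0)       # 0.5 s window
        assert not tc.valid[0] and not tc.valid[-1]
        assert np.isnan(tc.phase[0, 0])
        assert tc.valid[tc.times.size // 2]

    def test_rejects_above_nyquist(self):
        ep = make_epochs(np.zeros((1, 1, 400)))
        with pytest.raises(ValueError):
            estimate_phase(ep, "ch0", 150.0)


@given(st.floats(-50, 50))
def test_wrap_phase_is_idempotent_and_in_range(x):
    w = wrap_phase(x)
    assert -np.pi <= w < np.pi
    assert np.isclose(float(wrap_phase(w)), float(w))
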