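"""Phase binning, per-bin decoding, cosine fit, and the circular-shift
null."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from phasedecode.decoding import ObservationSet
from phasedecode.phase_binned import (
    bin_by_phase,
    circular_shift_null,
    decode_per_bin,
    fit_cosine,
    modulation_spectrum,
    observation_bins,
    select_analysis_window,
)
from phasedecode.simulate import SimConfig, simulate_subject
from phasedecode.spectral import PhaseTimecourse, estimate_phase, wrap_phase


def make_phase_tc(phase, times=None, step=0.005, freq=10.0):
    phase = np.atleast_2d(phase)
    if times is None:
        times = np.arange(phase.shape[1]) * step
    return PhaseTimecourse(
        phase=phase, valid=np.ones(phase.shape[1], dtype=bool),
        times=np.asarray(times), freq=freq, freq_used=freq, step=step,
        window_cycles=2.0, channel="mod",
    )


class TestSelectAnalysisWindow:
    def test_observation_count_per_trial(self, demo_subject):
        epochs, _ = demo_subject
        obs = select_analysis_window(epochs, (0.4, 1.0))
        assert obs.n_obs == epochs.n_trials * 120
        obs1 = select_analysis_window(epochs, (0.4, 0.405))
        assert obs1.n_obs == epochs.n_trials * 1

    def test_window_outside_epoch_rejected(self, demo_subject):
        epochs, _ = demo_subject
        with pytest.raises(ValueError):
            select_analysis_window(epochs, (0.5, 1.7))

    def test_labels_follow_orientation(self, demo_subject):
        epochs, _ = demo_subject
        obs = select_analysis_window(epochs, (0.4, 0.5))
        cw = epochs.trial_table["orientation"].to_numpy() == "CW"
        np.testing.assert_array_equal(obs.y.astype(bool), cw[obs.trial])


class TestBinByPhase:
    def test_edge_convention(self):
        tc = make_phase_tc(np.array([[-np.pi, 0.0, np.pi - 1e-9]]))
        binning = bin_by_phase(tc, 18)
        assert binning.assignment[0, 0] == 0
        assert binning.assignment[0, 1] == 9
        assert binning.assignment[0, 2] == 17

    def test_uniform_phases_fill_bins_evenly(self):
        rng = np.random.default_rng(0)
        tc = make_phase_tc(rng.uniform(-np.pi, np.pi, (1, 100_000)))
        binning = bin_by_phase(tc, 18)
        counts = np.bincount(binning.assignment[0], minlength=18)
        assert np.all(np.abs(counts - counts.mean()) / counts.mean() < 0.05)

    def test_invalid_samples_get_minus_one(self):
        tc = make_phase_tc(np.zeros((1, 10)))
        tc.valid[:3] = False
        tc.phase[0, :3] = np.nan
        binning = bin_by_phase(tc, 18)
        assert np.all(binning.assignment[0, :3] == -1)
        assert np.all(binning.assignment[0, 3:] >= 0)

    def test_bins_partition_the_circle(self):
        rng = np.random.default_rng(1)
        tc = make_phase_tc(rng.uniform(-np.pi, np.pi, (1, 5000)))
        binning = bin_by_phase(tc, 18)
        assert binning.assignment.min() >= 0
        assert binning.assignment.max() <= 17
        assert np.isclose(binning.edges[0], -np.pi)
        assert np.isclose(binning.edges[-1], np.pi)

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            bin_by_phase(make_phase_tc(np.zeros((1, 4))), 1)


class TestFitCosine:
    def test_exact_model_recovered_to_machine_precision(self):
        theta = -np.pi + (np.arange(18) + 0.5) * 2 * np.pi / 18
        y = 2.0 + 0.5 * np.cos(theta - np.pi / 4)
        fit = fit_cosine(y, theta)
        assert abs(fit.amplitude - 0.5) < 1e-10
        assert abs(fit.preferred_phase - np.pi / 4) < 1e-10
        assert not fit.fallback_lstsq

    def test_constant_scores_give_zero_amplitude(self):
        theta = -np.pi + (np.arange(18) + 0.5) * 2 * np.pi / 18
        fit = fit_cosine(np.full(18, 3.3), theta)
        assert fit.amplitude < 1e-12

    def test_missing_bins_use_least_squares_fallback(self):
        theta = -np.pi + (np.arange(18) + 0.5) * 2 * np.pi / 18
        y = 1.0 + 0.4 * np.cos(theta - 1.0)
        y[3] = np.nan
        fit = fit_cosine(y, theta)
        assert fit.fallback_lstsq
        assert abs(fit.amplitude - 0.4) < 1e-8
        assert abs(fit.preferred_phase - 1.0) < 1e-8

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            fit_cosine([1.0, 2.0], [0.0, np.pi])

    @given(st.integers(0, 10_000))
    def test_amplitude_invariant_to_offset_and_phase_equivariant(self, seed):
        rng = np.random.default_rng(seed)
        theta = -np.pi + (np.arange(18) + 0.5) * 2 * np.pi / 18
        y = rng.normal(50, 3, 18)
        base = fit_cosine(y, theta)
        shifted = fit_cosine(y + 7.5, theta)
        assert np.isclose(base.amplitude, shifted.amplitude, atol=1e-9)
        delta = rng.uniform(-np.pi, np.pi)
        rotated = fit_cosine(y, wrap_phase(theta + delta))
        assert np.isclose(rotated.amplitude, base.amplitude, atol=1e-9)
        expected = wrap_phase(base.preferred_phase + delta)
        d = np.angle(np.exp(1j * (rotated.preferred_phase - expected)))
        assert abs(d) < 1e-9


def _uniform_phase_subject(seed, n_per_cond=16, mod_depth=0.0, **kw):
    cfg = SimConfig(
        n_trials_per_condition=n_per_cond, n_channels=8, mod_depth=mod_depth,
        seed=seed, **kw,
    )
    return simulate_subject(cfg, (seed, 77)), cfg


class TestDecodePerBin:
    def test_flat_information_gives_flat_bins(self):
        """With class information independent of phase, bin accuracies agree
        up to resampling noise."""
        (epochs, _), cfg = _uniform_phase_subject(0, mod_depth=0.0,
                                                  pattern_snr=0.6)
        obs = select_analysis_window(epochs, (0.4, 0.7))
        tc = estimate_phase(epochs, "mod", 10.0)
        binning = bin_by_phase(tc, 18)
        bd = decode_per_bin(obs, binning, n_repetitions=4,
                            rng=np.random.default_rng(3))
        accs = bd.accuracies[~bd.flagged]
        assert accs.size >= 16
        # binomial noise scale for one bin's pooled test size
        n_test = bd.counts[~bd.flagged].sum(axis=1).mean() / 5  # pseudo count
        binom_sd = 100 * np.sqrt(0.25 / n_test)
        assert accs.std() < 2.0 * binom_sd + 2.0

    def test_modulated_subject_peaks_near_optimal_phase(self):
        (epochs, truth), cfg = _uniform_phase_subject(
            1, n_per_cond=24, mod_depth=0.8, pattern_snr=0.7, phi_star=0.5
        )
        obs = select_analysis_window(epochs)
        tc = estimate_phase(epochs, "mod", cfg.f_mod)
        binning = bin_by_phase(tc, 18)
        bd = decode_per_bin(obs, binning, n_repetitions=5,
                            rng=np.random.default_rng(4))
        centers = binning.centers
        good = np.abs(np.angle(np.exp(1j * (centers - truth.phi_star)))) < np.pi / 3
        bad = np.abs(np.angle(np.exp(1j * (centers - truth.phi_star)))) > 2 * np.pi / 3
        assert np.nanmean(bd.accuracies[good]) > np.nanmean(bd.accuracies[bad]) + 5

    def test_underfilled_bins_flagged_not_dropped(self):
        (epochs, _), cfg = _uniform_phase_subject(2)
        obs = select_analysis_window(epochs, (0.4, 0.5))
        tc = estimate_phase(epochs, "mod", 10.0)
        binning = bin_by_phase(tc, 18)
        bd = decode_per_bin(obs, binning, n_repetitions=2,
                            rng=np.random.default_rng(5))
        assert bd.flagged.any()
        assert np.isnan(bd.accuracies[bd.flagged]).all()
        assert bd.accuracies.size == 18


class TestCircularShiftNull:
    def test_zero_offset_reproduces_observed_exactly(self):
        (epochs, _), cfg = _uniform_phase_subject(3, pattern_snr=0.6)
        obs = select_analysis_window(epochs, (0.4, 0.6))
        tc = estimate_phase(epochs, "mod", 10.0)
        binning = bin_by_phase(tc, 18)
        bd = decode_per_bin(obs, binning, n_repetitions=2,
                            rng=np.random.default_rng(42), min_per_class=10)
        observed = fit_cosine(bd.accuracies, binning.centers).amplitude
        null = circular_shift_null(
            tc, obs, n_perm=1, offsets=np.zeros(epochs.n_trials),
            rng=np.random.default_rng(0), decode_seed=42,
            n_repetitions=2, min_per_class=10,
        )
        assert null[0] == observed

    def test_shifted_phases_stay_wrapped(self):
        rng = np.random.default_rng(1)
        tc = make_phase_tc(rng.uniform(-np.pi, np.pi, (20, 50)))
        shifted = tc.shifted(rng.uniform(-2 * np.pi, 2 * np.pi, 20))
        assert np.all(shifted.phase >= -np.pi)
        assert np.all(shifted.phase < np.pi)

    def test_empirical_p_uniform_under_no_modulation(self):
        """Observed amplitude exchangeable with null draws when m = 0."""
        pvals = []
        for seed in range(24):
            (epochs, _), cfg = _uniform_phase_subject(
                100 + seed, n_per_cond=10, pattern_snr=0.5
            )
            obs = select_analysis_window(epochs, (0.4, 0.6))
            tc = estimate_phase(epochs, "mod", 10.0)
            binning = bin_by_phase(tc, 18)
            kw = dict(n_repetitions=2, min_per_class=10, n_folds=2)
            bd = decode_per_bin(obs, binning,
                                rng=np.random.default_rng(seed), **kw)
            amp = fit_cosine(bd.accuracies, binning.centers).amplitude
            null = circular_shift_null(
                tc, obs, n_perm=15, rng=np.random.default_rng(1000 + seed),
                decode_seed=seed, **kw,
            )
            pvals.append((1 + np.sum(null >= amp)) / (len(null) + 1))
        _, p = sps.kstest(pvals, "uniform")
        assert p > 0.01

    def test_requires_at_least_one_permutation(self):
        tc = make_phase_tc(np.zeros((2, 10)))
        with pytest.raises(ValueError):
            circular_shift_null(tc, None, n_perm=0)


class TestModulationSpectrum:
    def test_strong_modulation_beats_its_null_at_source_frequency(self):
        cfg = SimConfig(
            n_trials_per_condition=20, n_channels=8, mod_depth=0.8,
            pattern_snr=0.8, f_mod=10.0, seed=9,
        )
        epochs, _ = simulate_subject(cfg, (9, 9))
        sp = modulation_spectrum(
            epochs, "mod", [10.0], window=(0.4, 1.0),
            n_repetitions=4, n_perm=19, seed=9,
        )
        amp = sp.fits[0].amplitude
        assert amp > np.percentile(sp.null_amplitudes[0], 95)

    def test_empty_frequency_list_rejected(self, demo_subject):
        epochs, _ = demo_subject
        with pytest.raises(ValueError):
            modulation_spectrum(epochs, "mod", [])
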