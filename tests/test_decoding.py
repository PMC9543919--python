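"""Pseudo-observation grouping, whitening, balancing, SVM CV, and the
composed decoding pipeline."""

import numpy as np
import pytest
from scipy import stats as sps

from phasedecode import _svm
from phasedecode.decoding import (
    ObservationSet,
    balance_classes,
    decode,
    empirical_chance,
    make_pseudo_observations,
    prewhiten_reduce,
    svm_cv_accuracy,
    svm_cv_fold_accuracies,
)
from phasedecode.phase_binned import select_analysis_window
from phasedecode.simulate import SimConfig, simulate_subject


def obs_from_arrays(X, y):
    n = len(y)
    return ObservationSet(
        X=X, y=y, trial=np.arange(n), timepoint=np.zeros(n, dtype=int)
    )


def gaussian_obs(rng, n_per_class=50, d=6, sep=1.0):
    X0 = rng.standard_normal((n_per_class, d))
    X1 = rng.standard_normal((n_per_class, d)) + sep / np.sqrt(d)
    X = np.vstack([X0, X1])
    y = np.repeat([0, 1], n_per_class)
    return obs_from_arrays(X, y)


class TestPseudoObservations:
    def test_exhaustive_partition(self, rng):
        obs = obs_from_arrays(rng.standard_normal((10, 3)), np.zeros(10, int))
        pseudo = make_pseudo_observations(obs, 5, rng)
        assert pseudo.n_obs == 2
        used = np.sort(np.concatenate(pseudo.members))
        np.testing.assert_array_equal(used, np.arange(10))

    def test_leftovers_discarded(self, rng):
        obs = obs_from_arrays(rng.standard_normal((12, 3)), np.zeros(12, int))
        pseudo = make_pseudo_observations(obs, 5, rng)
        assert pseudo.n_obs == 2
        assert sum(len(m) for m in pseudo.members) == 10

    def test_mean_of_identical_vectors(self, rng):
        v = np.array([1.0, -2.0, 0.5])
        obs = obs_from_arrays(np.tile(v, (10, 1)), np.repeat([0, 1], 5))
        pseudo = make_pseudo_observations(obs, 5, rng)
        np.testing.assert_allclose(pseudo.X, np.tile(v, (2, 1)))

    def test_groups_never_mix_classes(self, rng):
        y = rng.integers(0, 2, 40)
        obs = obs_from_arrays(rng.standard_normal((40, 2)), y)
        pseudo = make_pseudo_observations(obs, 5, rng)
        for label, members in zip(pseudo.y, pseudo.members):
            assert np.all(y[members] == label)

    def test_no_observation_reused(self, rng):
        obs = obs_from_arrays(rng.standard_normal((37, 2)),
                              rng.integers(0, 2, 37))
        pseudo = make_pseudo_observations(obs, 5, rng)
        used = np.concatenate(pseudo.members) if pseudo.members else []
        assert len(used) == len(set(used.tolist()))


class TestPrewhitenReduce:
    def test_component_count_follows_variance_threshold(self):
        rng = np.random.default_rng(0)
        # build data with known singular values: top 2 carry 99.5%
        U, _ = np.linalg.qr(rng.standard_normal((50, 3)))
        V, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        s = np.array([10.0, 4.08, 1.0])          # s^2: 100, 16.6, 1 -> 99.2%
        s = np.array([10.0, 5.0, 0.79])          # 100, 25, 0.63 -> 99.5%
        X = (U[:, :3] * s) @ V
        X -= X.mean(axis=0)
        Z, proj = prewhiten_reduce(X, 0.99)
        assert proj.n_components == 2

    def test_whitened_covariance_is_identity(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((200, 5)) @ rng.standard_normal((5, 5))
        Z, _ = prewhiten_reduce(X, 1.0 - 1e-12)
        cov = Z.T @ Z / (Z.shape[0] - 1)
        np.testing.assert_allclose(cov, np.eye(Z.shape[1]), atol=1e-8)

    def test_retained_variance_bookkeeping(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((80, 10)) * np.linspace(3, 0.1, 10)
        Z, proj = prewhiten_reduce(X, 0.99)
        Xc = X - proj.mean
        recon = (Xc @ proj.components.T) @ proj.components
        explained = 1 - np.sum((Xc - recon) ** 2) / np.sum(Xc**2)
        assert explained >= 0.99

    def test_rank_zero_rejected(self):
        with pytest.raises(ValueError):
            prewhiten_reduce(np.ones((5, 3)))


class TestBalanceClasses:
    def test_majority_subsampled(self, rng):
        obs = obs_from_arrays(np.zeros((13, 2)), np.repeat([0, 1], [8, 5]))
        out = balance_classes(obs, rng)
        assert np.sum(out.y == 0) == np.sum(out.y == 1) == 5

    def test_balanced_input_unchanged(self, rng):
        obs = obs_from_arrays(np.arange(12.0).reshape(6, 2),
                              np.repeat([0, 1], 3))
        out = balance_classes(obs, rng)
        np.testing.assert_array_equal(np.sort(out.trial), obs.trial)

    def test_seeded_determinism(self):
        obs = obs_from_arrays(np.zeros((20, 2)), np.repeat([0, 1], [12, 8]))
        a = balance_classes(obs, np.random.default_rng(7))
        b = balance_classes(obs, np.random.default_rng(7))
        np.testing.assert_array_equal(a.trial, b.trial)

    def test_missing_class_rejected(self, rng):
        obs = obs_from_arrays(np.zeros((5, 2)), np.zeros(5, int))
        with pytest.raises(ValueError):
            balance_classes(obs, rng)


class TestSvmCv:
    def test_well_separated_clusters_are_perfect(self, rng):
        obs = gaussian_obs(rng, n_per_class=50, sep=10 * np.sqrt(6))
        acc = svm_cv_accuracy(obs.X, obs.y, rng=rng)
        assert acc == 100.0

    def test_identical_features_near_chance(self, rng):
        X = np.tile(rng.standard_normal(4), (60, 1))
        X += 1e-9 * rng.standard_normal(X.shape)
        y = np.repeat([0, 1], 30)
        acc = svm_cv_accuracy(X, y, rng=rng)
        assert 30.0 < acc < 70.0

    def test_folds_exceeding_minority_rejected(self, rng):
        obs = gaussian_obs(rng, n_per_class=3)
        with pytest.raises(ValueError):
            svm_cv_accuracy(obs.X, obs.y, n_folds=5, rng=rng)

    def test_builtin_solver_agrees_with_sklearn(self):
        """The dual-CD solver is validated against SVC(kernel='linear') on
        random fixtures: high prediction agreement, equivalent CV accuracy."""
        from sklearn.svm import SVC

        rng = np.random.default_rng(3)
        agreements, acc_diffs = [], []
        for _ in range(25):
            n, d = int(rng.integers(24, 90)), int(rng.integers(2, 9))
            X = rng.standard_normal((n, d))
            y = rng.integers(0, 2, n)
            X[y == 1] += rng.uniform(0, 1.2) * rng.standard_normal(d) / np.sqrt(d)
            w = _svm.fit_linear_svm(X, y)
            ours = _svm.predict(w, X)
            ref = SVC(kernel="linear", C=1.0).fit(X, y).predict(X)
            agreements.append(np.mean(ours == ref))
            acc_diffs.append(abs(np.mean(ours == y) - np.mean(ref == y)))
        assert np.mean(agreements) > 0.95
        assert np.min(agreements) > 0.80
        assert np.max(acc_diffs) < 0.12

    def test_backend_cv_accuracies_close(self, rng):
        obs = gaussian_obs(rng, n_per_class=40, sep=2.0)
        a = svm_cv_accuracy(obs.X, obs.y, rng=np.random.default_rng(5),
                            backend="builtin")
        b = svm_cv_accuracy(obs.X, obs.y, rng=np.random.default_rng(5),
                            backend="sklearn")
        assert abs(a - b) <= 6.0


class TestDecode:
    def test_deterministic_given_seed(self, rng):
        obs = gaussian_obs(np.random.default_rng(0), n_per_class=100, sep=2.0)
        a = decode(obs, n_repetitions=3, rng=np.random.default_rng(9))
        b = decode(obs, n_repetitions=3, rng=np.random.default_rng(9))
        assert a.accuracy == b.accuracy
        np.testing.assert_array_equal(a.per_fold, b.per_fold)

    def test_accuracy_is_mean_of_fold_means(self, rng):
        obs = gaussian_obs(np.random.default_rng(1), n_per_class=100, sep=2.0)
        r = decode(obs, n_repetitions=4, rng=rng)
        assert np.isclose(r.accuracy, r.per_fold.mean(axis=1).mean())
        assert np.all((r.per_fold >= 0) & (r.per_fold <= 100))

    def test_single_repetition_equals_manual_composition(self):
        from phasedecode.decoding import _decode_once

        obs = gaussian_obs(np.random.default_rng(2), n_per_class=80, sep=1.5)
        r = decode(obs, n_repetitions=1, group_size=5,
                   rng=np.random.default_rng(21))
        manual, _ = _decode_once(
            obs.X, obs.y, obs.trial, 5, 0.99, 5, np.random.default_rng(21)
        )
        np.testing.assert_array_equal(r.per_fold[0], manual)

    def test_high_snr_simulator_subject_decodes_well(self):
        cfg = SimConfig(n_trials_per_condition=20, n_channels=8,
                        pattern_snr=1.5, mod_depth=0.0, seed=13)
        epochs, _ = simulate_subject(cfg, (13, 0))
        obs = select_analysis_window(epochs)
        r = decode(obs, n_repetitions=3, rng=np.random.default_rng(1))
        assert r.accuracy > 90.0

    def test_accuracy_monotone_in_pattern_snr(self):
        """Sign test over seeds: more pattern SNR never hurts on average."""
        means = []
        for snr in (0.1, 0.4, 0.9):
            accs = []
            for seed in range(6):
                cfg = SimConfig(
                    n_trials_per_condition=12, n_channels=6,
                    pattern_snr=snr, mod_depth=0.0, seed=seed,
                )
                ep, _ = simulate_subject(cfg, (seed, 40))
                obs = select_analysis_window(ep, (0.4, 0.7))
                accs.append(
                    decode(obs, n_repetitions=2,
                           rng=np.random.default_rng(seed)).accuracy
                )
            means.append(np.mean(accs))
        assert means[0] < means[1] < means[2]


class TestEmpiricalChance:
    def test_zero_shuffles_empty(self, rng):
        obs = gaussian_obs(rng)
        assert empirical_chance(obs, n_shuffles=0, rng=rng).size == 0

    def test_chance_centers_near_fifty(self):
        rng = np.random.default_rng(4)
        obs = gaussian_obs(rng, n_per_class=250, d=6, sep=3.0)
        ch = empirical_chance(obs, n_shuffles=25, rng=rng)
        assert 48.0 <= ch.mean() <= 52.0

    def test_chance_insensitive_to_true_structure(self):
        rng = np.random.default_rng(5)
        strong = gaussian_obs(np.random.default_rng(6), 250, sep=6.0)
        none = gaussian_obs(np.random.default_rng(7), 250, sep=0.0)
        ch_strong = empirical_chance(strong, n_shuffles=20, rng=rng)
        ch_none = empirical_chance(none, n_shuffles=20, rng=rng)
        _, p = sps.mannwhitneyu(ch_strong, ch_none)
        assert p > 0.01
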