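"""Gaze-leakage control for neural decoding.

Above-chance decoding of the stimulus class can be a trivial consequence
of systematic gaze differences between classes.  The control iterates:
decode the class from the gaze channels alone (pseudo-observations,
10-fold CV); while gaze decoding exceeds chance (fold-wise t test against
scrambled-label accuracies), remove per fold and per class the
pseudo-observation the classifier is most confident about (largest signed
margin on the training side of the boundary) and mark its constituent
trials; repartition and repeat until accuracy fails to exceed chance five
consecutive iterations.  The marked trials are then removed from the
neural data before re-decoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from . import _svm
from .decoding import (
    DecodingResult,
    ObservationSet,
    _balanced_rows,
    _stratified_folds,
    decode,
    make_pseudo_observations,
    prewhiten_reduce,
)

__all__ = [
    "RemovalLog",
    "NonTerminationError",
    "eye_informed_removal",
    "redecode_without_trials",
    "fold_ttest_vs_scrambled",
]


class NonTerminationError(RuntimeError):
    """The removal loop hit the iteration cap; carries the log so far."""

    def __init__(self, message, log):
        super().__init__(message)
        self.log = log


@dataclass
class IterationRecord:
    iteration: int
    accuracy: float
    p_value: float
    significant: bool
    removed_trials: list[int]


@dataclass
class RemovalLog:
    iterations: list[IterationRecord] = field(default_factory=list)

    def to_rows(self):
        return [
            {
                "iteration": r.iteration,
                "accuracy": r.accuracy,
                "p_value": r.p_value,
                "significant": r.significant,
                "removed_trials": ";".join(map(str, r.removed_trials)),
            }
            for r in self.iterations
        ]


def fold_ttest_vs_scrambled(
    fold_accs: np.ndarray, scrambled_accs: np.ndarray, alpha: float = 0.05
) -> tuple[float, bool]:
    """Paired one-sided t test of fold accuracies against scrambled-label
    fold accuracies; shared by the removal loop and the re-decoding check."""
    d = np.asarray(fold_accs) - np.asarray(scrambled_accs)
    if np.allclose(d.std(ddof=1), 0.0):
        return 1.0, False
    t, p = sps.ttest_rel(fold_accs, scrambled_accs, alternative="greater")
    return float(p), bool(p < alpha)


def _fold_pass(X, y, folds, C):
    """Fit per fold; returns fold accuracies, scrambled-label accuracies,
    and per-fold weight vectors + training rows (for margin ranking)."""
    n = y.size
    all_rows = np.arange(n)
    accs = np.empty(len(folds))
    fits = []
    for k, test_rows in enumerate(folds):
        mask = np.ones(n, dtype=bool)
        mask[test_rows] = False
        train_rows = all_rows[mask]
        w = _svm.fit_linear_svm(X[train_rows], y[train_rows], C=C)
        accs[k] = 100.0 * np.mean(_svm.predict(w, X[test_rows]) == y[test_rows])
        fits.append((w, train_rows))
    return accs, fits


def _scrambled_pass(X, y, folds, C, rng):
    n = y.size
    all_rows = np.arange(n)
    scr = np.empty(len(folds))
    for k, test_rows in enumerate(folds):
        mask = np.ones(n, dtype=bool)
        mask[test_rows] = False
        train_rows = all_rows[mask]
        y_scr = rng.permutation(y[train_rows])
        w = _svm.fit_linear_svm(X[train_rows], y_scr, C=C)
        scr[k] = 100.0 * np.mean(_svm.predict(w, X[test_rows]) == y[test_rows])
    return scr


def eye_informed_removal(
    eye_obs: ObservationSet,
    rng: np.random.Generator | None = None,
    group_size: int = 5,
    n_folds: int = 10,
    variance_kept: float = 0.99,
    alpha: float = 0.05,
    stop_after: int = 5,
    max_iterations: int = 200,
    C: float = 1.0,
) -> tuple[set[int], RemovalLog]:
    """Iteratively remove the trials that make gaze decodable.

    Returns the union of removed trial indices and a per-iteration log.
    Ties in the margin ranking are broken toward the lowest trial index
    for determinism.  Raises :class:`NonTerminationError` (log attached)
    if the loop exceeds ``max_iterations``."""
    rng = np.random.default_rng() if rng is None else rng
    if np.unique(eye_obs.y).size < 2:
        raise ValueError("both classes must be present")
    removed: set[int] = set()
    log = RemovalLog()
    consecutive_chance = 0
    current = eye_obs
    for it in range(max_iterations):
        pseudo = make_pseudo_observations(current, group_size, rng)
        n0 = int(np.sum(pseudo.y == 0))
        n1 = int(np.sum(pseudo.y == 1))
        if min(n0, n1) < n_folds:
            # a class ran out of data: gaze is no longer decodable by
            # construction; stop
            break
        Z, _ = prewhiten_reduce(pseudo.X, variance_kept)
        rows = _balanced_rows(pseudo.y, rng)
        Zb, yb = Z[rows], pseudo.y[rows]
        folds = _stratified_folds(yb, n_folds, rng)
        accs, fits = _fold_pass(Zb, yb, folds, C)
        scr = _scrambled_pass(Zb, yb, folds, C, rng)
        p, significant = fold_ttest_vs_scrambled(accs, scr, alpha)
        removed_now: list[int] = []
        if significant:
            consecutive_chance = 0
            marked_rows: set[int] = set()
            for w, train_rows in fits:
                margin = _svm.decision_function(w, Zb[train_rows])
                signed = np.where(yb[train_rows] == 1, margin, -margin)
                for cls in (0, 1):
                    cls_rows = np.flatnonzero(yb[train_rows] == cls)
                    if cls_rows.size == 0:
                        continue
                    best = cls_rows[np.argmax(signed[cls_rows])]
                    marked_rows.add(int(train_rows[best]))
            for row in marked_rows:
                pseudo_row = rows[row]
                trials = pseudo.member_trials(int(pseudo_row))
                removed_now.extend(int(t) for t in trials)
            removed_now = sorted(set(removed_now) - removed)
            removed.update(removed_now)
            current = current.drop_trials(removed_now)
        else:
            consecutive_chance += 1
        log.iterations.append(
            IterationRecord(
                iteration=it,
                accuracy=float(accs.mean()),
                p_value=p,
                significant=significant,
                removed_trials=removed_now,
            )
        )
        if consecutive_chance >= stop_after:
            break
    else:
        raise NonTerminationError(
            f"gaze removal did not terminate in {max_iterations} iterations",
            log,
        )
    return removed, log


def redecode_without_trials(
    neural_obs: ObservationSet,
    removed: Sequence[int],
    n_repetitions: int = 100,
    group_size: int = 5,
    variance_kept: float = 0.99,
    n_folds: int = 10,
    rng: np.random.Generator | None = None,
    C: float = 1.0,
) -> tuple[DecodingResult, float, bool]:
    """Decode the neural data with the gaze-informative trials removed.

    Returns the decoding result plus the fold-wise t test (p, significant)
    of the last repetition against a scrambled-label pass, computed through
    the same code path as the removal loop's stopping statistic."""
    removed = set(int(t) for t in removed)
    if not removed <= set(neural_obs.trial.tolist()) and removed:
        raise ValueError("removed trials are not a subset of the neural trials")
    obs = neural_obs.drop_trials(removed) if removed else neural_obs
    if np.unique(obs.y).size < 2:
        raise ValueError("removal emptied a class")
    rng = np.random.default_rng() if rng is None else rng
    result = decode(
        obs, n_repetitions=n_repetitions, group_size=group_size,
        variance_kept=variance_kept, n_folds=n_folds, rng=rng, C=C,
    )
    # stopping-statistic check on a fresh pass
    pseudo = make_pseudo_observations(obs, group_size, rng)
    Z, _ = prewhiten_reduce(pseudo.X, variance_kept)
    rows = _balanced_rows(pseudo.y, rng)
    Zb, yb = Z[rows], pseudo.y[rows]
    folds = _stratified_folds(yb, n_folds, rng)
    accs, _ = _fold_pass(Zb, yb, folds, C)
    scr = _scrambled_pass(Zb, yb, folds, C, rng)
    p, significant = fold_ttest_vs_scrambled(accs, scr)
    return result, p, significant
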