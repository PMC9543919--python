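"""Linear (hinge-loss, L2-regularized) SVM for very small problems.

The per-bin decoding loop fits millions of tiny SVMs (bins x repetitions x
folds x permutations x frequencies x subjects), where general-purpose
library call overhead dominates the actual optimization by more than an
order of magnitude.  This module solves the standard C-SVM dual by
coordinate descent (the liblinear algorithm for L1-loss SVC), compiled
with numba, with the bias handled as an augmented constant feature.  The
scikit-learn backend in :mod:`phasedecode.decoding` solves the same
problem and is used as the equivalence reference in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def _dual_cd(X, y, C, tol, max_passes):  # pragma: no cover - numba kernel
    n, d = X.shape
    w = np.zeros(d)
    alpha = np.zeros(n)
    qii = np.empty(n)
    for i in range(n):
        s = 0.0
        for j in range(d):
            s += X[i, j] * X[i, j]
        qii[i] = s
    for _ in range(max_passes):
        max_pg = 0.0
        for i in range(n):
            g = 0.0
            for j in range(d):
                g += w[j] * X[i, j]
            g = g * y[i] - 1.0
            if alpha[i] <= 0.0:
                pg = g if g < 0.0 else 0.0
            elif alpha[i] >= C:
                pg = g if g > 0.0 else 0.0
            else:
                pg = g
            apg = abs(pg)
            if apg > max_pg:
                max_pg = apg
            if apg > 1e-12 and qii[i] > 0.0:
                old = alpha[i]
                na = old - g / qii[i]
                if na < 0.0:
                    na = 0.0
                elif na > C:
                    na = C
                alpha[i] = na
                diff = (na - old) * y[i]
                if diff != 0.0:
                    for j in range(d):
                        w[j] += diff * X[i, j]
        if max_pg < tol:
            break
    return w


@njit(cache=False)
def _cv_fold_accuracies(Xb, y, fold_id, n_folds, C, tol, max_passes):
    # pragma: no cover - numba kernel
    """Per-fold accuracy of the dual-CD SVM; Xb already bias-augmented,
    y in {-1, +1}."""
    n, d = Xb.shape
    accs = np.empty(n_folds)
    for k in range(n_folds):
        n_tr = 0
        for i in range(n):
            if fold_id[i] != k:
                n_tr += 1
        Xtr = np.empty((n_tr, d))
        ytr = np.empty(n_tr)
        j = 0
        for i in range(n):
            if fold_id[i] != k:
                Xtr[j] = Xb[i]
                ytr[j] = y[i]
                j += 1
        w = _dual_cd(Xtr, ytr, C, tol, max_passes)
        good = 0
        total = 0
        for i in range(n):
            if fold_id[i] == k:
                s = 0.0
                for jj in range(d):
                    s += w[jj] * Xb[i, jj]
                pred = 1.0 if s > 0.0 else -1.0
                if pred == y[i]:
                    good += 1
                total += 1
        accs[k] = 100.0 * good / total
    return accs


def cv_fold_accuracies(X, y01, fold_id, n_folds, C=1.0, tol=1e-3,
                       max_passes=300):
    """Stratified-CV fold accuracies with the builtin solver (percent)."""
    X = np.ascontiguousarray(X, dtype=np.float64)
    n, d = X.shape
    Xb = np.empty((n, d + 1))
    Xb[:, :d] = X
    Xb[:, d] = 1.0
    ypm = np.where(np.asarray(y01) > 0, 1.0, -1.0)
    return _cv_fold_accuracies(
        Xb, ypm, np.ascontiguousarray(fold_id, dtype=np.int64),
        n_folds, float(C), tol, max_passes,
    )


def fit_linear_svm(
    X: np.ndarray, y01: np.ndarray, C: float = 1.0,
    tol: float = 1e-3, max_passes: int = 300,
) -> np.ndarray:
    """Fit on labels in {0, 1}; returns weights of length d+1 (last = bias)."""
    X = np.ascontiguousarray(X, dtype=np.float64)
    n, d = X.shape
    Xb = np.empty((n, d + 1))
    Xb[:, :d] = X
    Xb[:, d] = 1.0
    ypm = np.where(np.asarray(y01) > 0, 1.0, -1.0)
    return _dual_cd(Xb, ypm, float(C), tol, max_passes)


def decision_function(w: np.ndarray, X: np.ndarray) -> np.ndarray:
    return X @ w[:-1] + w[-1]


def predict(w: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Predicted labels in {0, 1}."""
    return (decision_function(w, X) > 0).astype(np.int8)
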