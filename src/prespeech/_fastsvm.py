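"""Compiled linear max-margin classifier and cross-validation kernels.

The permutation machinery (label-shuffle nulls, time-shuffle thresholds)
re-runs the identical stratified-CV decoding procedure thousands of times on
small trial matrices, so the inner loop is a numba-compiled dual coordinate
descent solver for the L2-regularized hinge-loss SVM (the liblinear
formulation, sequential sweeps, bias handled as an appended unit feature).
Feature standardization is fitted inside each training fold.

Equivalence with ``sklearn.svm.LinearSVC(loss="hinge")`` is asserted in the
test suite; sklearn remains the independent reference, not the hot path.
"""

from __future__ import annotations

import warnings

import numpy as np
from numba import njit

__all__ = [
    "cv_accuracy_curve",
    "fit_linear_svc",
    "decision_values",
    "stratified_fold_ids",
    "effective_n_folds",
]


@njit(cache=True)
def _fit_dcd(X, y, C, max_sweeps, tol):
    """Dual coordinate descent for min_w 0.5||w||^2 + C sum hinge(y, w.x).

    X must already carry the bias column. Sequential sweeps; converged when
    the largest projected gradient in a sweep drops below ``tol``.
    """
    n, d = X.shape
    w = np.zeros(d)
    alpha = np.zeros(n)
    qd = np.empty(n)
    for i in range(n):
        s = 0.0
        for j in range(d):
            s += X[i, j] * X[i, j]
        qd[i] = s
    for _ in range(max_sweeps):
        max_pg = 0.0
        for i in range(n):
            if qd[i] <= 0.0:
                continue
            g = 0.0
            for j in range(d):
                g += w[j] * X[i, j]
            g = y[i] * g - 1.0
            a = alpha[i]
            if a <= 0.0:
                pg = g if g < 0.0 else 0.0
            elif a >= C:
                pg = g if g > 0.0 else 0.0
            else:
                pg = g
            apg = abs(pg)
            if apg > max_pg:
                max_pg = apg
            if apg > 1e-12:
                na = a - g / qd[i]
                if na < 0.0:
                    na = 0.0
                elif na > C:
                    na = C
                da = (na - a) * y[i]
                if da != 0.0:
                    for j in range(d):
                        w[j] += da * X[i, j]
                    alpha[i] = na
        if max_pg < tol:
            break
    return w


@njit(cache=True)
def _cv_curve(F, y, fold_id, n_folds, C, max_sweeps, tol):
    """Stratified-CV accuracy for every window of a feature stack.

    F: (n_windows, n_trials, n_features); y: +/-1; fold_id: fold index per
    trial. Returns (mean accuracy per window, per-fold accuracies).
    """
    n_windows, n, d = F.shape
    acc = np.zeros(n_windows)
    fold_acc = np.zeros((n_windows, n_folds))
    mu = np.empty(d)
    sd = np.empty(d)
    Xtr = np.empty((n, d + 1))
    ytr = np.empty(n)
    Xte = np.empty((n, d + 1))
    for w_i in range(n_windows):
        for f in range(n_folds):
            ntr = 0
            nte = 0
            for j in range(d):
                mu[j] = 0.0
                sd[j] = 0.0
            # training-fold moments
            for i in range(n):
                if fold_id[i] != f:
                    for j in range(d):
                        mu[j] += F[w_i, i, j]
                    ntr += 1
                else:
                    nte += 1
            if ntr == 0 or nte == 0:
                fold_acc[w_i, f] = np.nan
                continue
            for j in range(d):
                mu[j] /= ntr
            for i in range(n):
                if fold_id[i] != f:
                    for j in range(d):
                        diff = F[w_i, i, j] - mu[j]
                        sd[j] += diff * diff
            for j in range(d):
                s = np.sqrt(sd[j] / ntr)
                sd[j] = s if s > 1e-12 else 1.0
            ti = 0
            ei = 0
            for i in range(n):
                if fold_id[i] != f:
                    for j in range(d):
                        Xtr[ti, j] = (F[w_i, i, j] - mu[j]) / sd[j]
                    Xtr[ti, d] = 1.0
                    ytr[ti] = y[i]
                    ti += 1
                else:
                    for j in range(d):
                        Xte[ei, j] = (F[w_i, i, j] - mu[j]) / sd[j]
                    Xte[ei, d] = 1.0
                    ei += 1
            w_vec = _fit_dcd(Xtr[:ntr], ytr[:ntr], C, max_sweeps, tol)
            correct = 0
            ei = 0
            for i in range(n):
                if fold_id[i] == f:
                    s = 0.0
                    for j in range(d + 1):
                        s += w_vec[j] * Xte[ei, j]
                    pred = 1.0 if s >= 0.0 else -1.0
                    if pred == y[i]:
                        correct += 1
                    ei += 1
            fold_acc[w_i, f] = correct / nte
        m = 0.0
        k = 0
        for f in range(n_folds):
            if not np.isnan(fold_acc[w_i, f]):
                m += fold_acc[w_i, f]
                k += 1
        acc[w_i] = m / k if k > 0 else np.nan
    return acc, fold_acc


def cv_accuracy_curve(F, y, fold_id, n_folds, C=1.0, max_sweeps=200, tol=1e-3):
    """Mean and per-fold stratified-CV accuracy per window.

    Parameters
    ----------
    F : ndarray (n_windows, n_trials, n_features)
    y : ndarray of +/-1 labels
    fold_id : ndarray of fold assignments in ``range(n_folds)``
    """
    F = np.ascontiguousarray(F, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    fold_id = np.asarray(fold_id, dtype=np.int64)
    return _cv_curve(F, y, fold_id, int(n_folds), float(C), int(max_sweeps), float(tol))


def fit_linear_svc(X, y, C=1.0, max_sweeps=500, tol=1e-4):
    """Fit on an (n, d) matrix (bias appended internally); returns (w, b)."""
    X = np.ascontiguousarray(X, dtype=np.float64)
    Xb = np.hstack([X, np.ones((X.shape[0], 1))])
    w = _fit_dcd(Xb, np.asarray(y, dtype=np.float64), float(C), int(max_sweeps), float(tol))
    return w[:-1], w[-1]


def decision_values(X, w, b):
    return np.asarray(X, dtype=np.float64) @ w + b


def effective_n_folds(y, n_folds):
    """Cap the fold count at the smallest class size, warning when reduced."""
    _, counts = np.unique(y, return_counts=True)
    smallest = int(counts.min())
    if smallest < n_folds:
        warnings.warn(
            f"reducing folds from {n_folds} to {smallest} (smallest class size)",
            stacklevel=2,
        )
        return max(smallest, 2)
    return n_folds


def stratified_fold_ids(y, n_folds, rng):
    """Random stratified fold assignment: per class, shuffle then round-robin."""
    y = np.asarray(y)
    fold = np.empty(y.shape[0], dtype=np.int64)
    for c_i, cls in enumerate(np.unique(y)):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        # offset by class index so remainder trials do not pile into fold 0
        fold[idx] = (np.arange(idx.size) + c_i) % n_folds
    return fold
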