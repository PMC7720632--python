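"""Linear soft-margin SVM via dual coordinate descent, with LOOCV drivers.

The backward-elimination wrapper evaluates a leave-one-out
cross-validated SVM ROC AUC for every candidate feature removal at every
elimination step -- on the order of 10^5-10^6 SVM fits per pipeline run.
These numba kernels keep that tractable on one CPU. The optimisation
problem (hinge loss, C fixed) is the same one sklearn's
``LinearSVC(loss="hinge")`` solves; the tests assert decision-value
agreement on random instances. The LOOCV path fits without an intercept
(see ``svm_fit``).

Numerical contract: deterministic permuted update order (fixed xorshift
stream), liblinear-style shrinking and projected-gradient-range stopping,
folds warm-started from the full-data dual solution, stopping tolerance
0.1 inside the LOOCV loop (held-out AUC stable to ~0.01 against fully
converged fits; the loose-tolerance error is shared across the feature
subsets the elimination wrapper compares).
"""
from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, inline="never")
def _fit_dcd(X, y, C, alpha, w, tol, max_epochs):
    """In-place dual coordinate descent on the hinge-loss SVM dual.

    The standard solver for this problem: per-epoch permutation of the
    update order (deterministic xorshift stream), shrinking of variables
    pinned at the box bounds, and the projected-gradient range stopping
    rule ``max(PG) - min(PG) < tol`` with a final full pass over the
    shrunk set. ``X`` already carries the bias column; ``alpha``/``w``
    are buffers (pass zeros for a cold start; ``w`` must equal
    ``sum_i alpha_i y_i X_i`` on entry).
    """
    n, d = X.shape
    Qii = np.empty(n)
    for i in range(n):
        s = 0.0
        for k in range(d):
            s += X[i, k] * X[i, k]
        Qii[i] = s
    index = np.arange(n)
    active = n
    pgmax_old = np.inf
    pgmin_old = -np.inf
    state = np.uint64(2463534242)
    for _ in range(max_epochs):
        pgmax_new = -np.inf
        pgmin_new = np.inf
        # Fisher-Yates permutation of the active set (deterministic)
        for s_i in range(active - 1, 0, -1):
            state ^= state << np.uint64(13)
            state ^= state >> np.uint64(7)
            state ^= state << np.uint64(17)
            j = int(state % np.uint64(s_i + 1))
            tmp = index[s_i]
            index[s_i] = index[j]
            index[j] = tmp
        s_i = 0
        while s_i < active:
            i = index[s_i]
            G = 0.0
            for k in range(d):
                G += w[k] * X[i, k]
            G = y[i] * G - 1.0
            a = alpha[i]
            pg = 0.0
            shrink = False
            if a <= 0.0:
                if G > pgmax_old:
                    shrink = True
                elif G < 0.0:
                    pg = G
            elif a >= C:
                if G < pgmin_old:
                    shrink = True
                elif G > 0.0:
                    pg = G
            else:
                pg = G
            if shrink:
                active -= 1
                index[s_i] = index[active]
                index[active] = i
                continue
            if pg > pgmax_new:
                pgmax_new = pg
            if pg < pgmin_new:
                pgmin_new = pg
            if (pg > 1e-13 or pg < -1e-13) and Qii[i] > 0.0:
                a_new = a - G / Qii[i]
                if a_new < 0.0:
                    a_new = 0.0
                elif a_new > C:
                    a_new = C
                da = a_new - a
                if da != 0.0:
                    alpha[i] = a_new
                    yda = y[i] * da
                    for k in range(d):
                        w[k] += yda * X[i, k]
            s_i += 1
        if pgmax_new - pgmin_new <= tol:
            if active == n:
                break
            # converged on the shrunk problem: re-activate and re-check
            active = n
            pgmax_old = np.inf
            pgmin_old = -np.inf
            continue
        pgmax_old = pgmax_new if pgmax_new > 0.0 else np.inf
        pgmin_old = pgmin_new if pgmin_new < 0.0 else -np.inf


@njit(cache=True)
def _auc_midrank(scores, y):
    """ROC AUC with mid-rank handling of tied scores."""
    n = scores.size
    order = np.argsort(scores)
    ranks = np.empty(n)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and scores[order[j + 1]] == scores[order[i]]:
            j += 1
        r = 0.5 * (i + j) + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = r
        i = j + 1
    n_pos = 0
    rank_sum = 0.0
    for i in range(n):
        if y[i] > 0.0:
            n_pos += 1
            rank_sum += ranks[i]
    n_neg = n - n_pos
    if n_pos == 0 or n_neg == 0:
        return 0.5
    return (rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


@njit(cache=True)
def _loocv_scores(X, y, C, tol_full, tol_fold, max_epochs):
    """Held-out decision values of a LOOCV linear SVM.

    Features are standardized inside each training fold; the held-out
    sample is transformed with the fold's statistics. Every fold is
    warm-started from the full-data dual solution (the leave-one-out
    optimum differs from it only through the removed sample and the
    slightly shifted standardization), which cuts the epoch count by an
    order of magnitude. A degenerate (single-class) training fold scores
    the held-out sample with the class-prior decision value (+/-1).
    """
    n, d = X.shape
    col_sum = np.zeros(d)
    col_sq = np.zeros(d)
    for i in range(n):
        for k in range(d):
            v = X[i, k]
            col_sum[k] += v
            col_sq[k] += v * v

    # full-data fit (globally standardized) used as the warm start
    mu_f = np.empty(d)
    sd_f = np.empty(d)
    for k in range(d):
        mu_f[k] = col_sum[k] / n
        var = (col_sq[k] - n * mu_f[k] * mu_f[k]) / (n - 1) if n > 1 else 0.0
        sd_f[k] = np.sqrt(var) if var > 1e-24 else 1.0
    Xs = np.empty((n, d))
    for i in range(n):
        for k in range(d):
            Xs[i, k] = (X[i, k] - mu_f[k]) / sd_f[k]
    alpha_full = np.zeros(n)
    w_full = np.zeros(d)
    _fit_dcd(Xs, y, C, alpha_full, w_full, tol_full, max_epochs)

    scores = np.empty(n)
    m = n - 1
    Xf = np.empty((m, d))
    yf = np.empty(m)
    alpha = np.empty(m)
    w = np.empty(d)
    mu = np.empty(d)
    sd = np.empty(d)
    for i in range(n):
        for k in range(d):
            s = col_sum[k] - X[i, k]
            q = col_sq[k] - X[i, k] * X[i, k]
            mu[k] = s / m
            var = (q - m * mu[k] * mu[k]) / (m - 1) if m > 1 else 0.0
            sd[k] = np.sqrt(var) if var > 1e-24 else 1.0
        n_pos = 0
        r = 0
        for j in range(n):
            if j == i:
                continue
            yf[r] = y[j]
            if y[j] > 0.0:
                n_pos += 1
            for k in range(d):
                Xf[r, k] = (X[j, k] - mu[k]) / sd[k]
            alpha[r] = alpha_full[j]
            r += 1
        if n_pos == 0 or n_pos == m:
            scores[i] = 1.0 if n_pos == m else -1.0
            continue
        for k in range(d):
            w[k] = 0.0
        for j in range(m):
            if alpha[j] != 0.0:
                yaj = yf[j] * alpha[j]
                for k in range(d):
                    w[k] += yaj * Xf[j, k]
        _fit_dcd(Xf, yf, C, alpha, w, tol_fold, max_epochs)
        s = 0.0
        for k in range(d):
            s += w[k] * (X[i, k] - mu[k]) / sd[k]
        scores[i] = s
    return scores


@njit(cache=True)
def _loocv_auc_kernel(X, y, C):
    scores = _loocv_scores(X, y, C, 0.05, 0.1, 100000)
    return _auc_midrank(scores, y)


@njit(cache=True)
def _loocv_auc_each_removed(X, y, C):
    """LOOCV AUC of the panel with each feature removed in turn."""
    n, d = X.shape
    out = np.empty(d)
    Xr = np.empty((n, d - 1))
    for f in range(d):
        c = 0
        for k in range(d):
            if k == f:
                continue
            for i in range(n):
                Xr[i, c] = X[i, k]
            c += 1
        out[f] = _loocv_auc_kernel(Xr, y, C)
    return out


def svm_fit(X, y, C: float = 1.0, tol: float = 1e-8, max_epochs: int = 20000,
            fit_intercept: bool = True):
    """Fit the linear SVM on data as given (no standardization).

    Returns ``(w, b)``; with ``fit_intercept`` the bias enters through
    feature augmentation (and is hence penalized), exactly as in
    sklearn's hinge-loss LinearSVC. The LOOCV wrapper uses the
    intercept-free form: on fold-standardized features the intercept
    carries no ranking information, but it tracks the training fold's
    class imbalance, which in leave-one-out runs systematically against
    the held-out sample and biases the null AUC below 0.5.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.where(np.asarray(y) > 0, 1.0, -1.0)
    n, d = X.shape
    Xb = np.hstack([X, np.ones((n, 1))]) if fit_intercept else X
    alpha = np.zeros(n)
    w = np.zeros(Xb.shape[1])
    _fit_dcd(np.ascontiguousarray(Xb), y, C, alpha, w, tol, max_epochs)
    b = float(w[d]) if fit_intercept else 0.0
    return w[:d].copy(), b


def loocv_auc(X, labels, C: float = 1.0) -> float:
    """Leave-one-out cross-validated linear-SVM ROC AUC.

    ``labels`` are binary (0/1 or boolean); features are standardized
    inside each training fold; AUC uses mid-rank tie handling. Fully
    deterministic.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.where(np.asarray(labels) > 0, 1.0, -1.0)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be (n_samples, n_features) matching labels")
    if len(np.unique(y)) < 2:
        raise ValueError("need two classes for LOOCV AUC")
    if np.unique(y, return_counts=True)[1].min() < 2:
        raise ValueError("need at least 2 samples per class")
    return float(_loocv_auc_kernel(X, y, C))
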