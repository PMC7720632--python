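"""Parametric empirical-Bayes batch correction (ComBat-style).

Location/scale adjustment per analyte and batch: standardize each
analyte, estimate per-batch location (gamma) and scale (delta), shrink
them toward common priors -- normal on the locations, inverse-gamma on
the scales, hyperparameters by method of moments -- via the standard
iterative solve, adjust and back-transform. Only the batch factor enters
the model (no biological covariates). Missing values are ignored in all
moments and passed through unchanged.

One deliberate deviation from the classical algorithm: the adjusted
matrix is re-centered per analyte to the original grand mean (plain EB
adjustment preserves it only approximately); see docs/methods.md.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


def _aprior(delta_hat: np.ndarray) -> float:
    m = np.nanmean(delta_hat)
    s2 = np.nanvar(delta_hat, ddof=1)
    return (2 * s2 + m**2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m = np.nanmean(delta_hat)
    s2 = np.nanvar(delta_hat, ddof=1)
    return (m * s2 + m**3) / s2


def _it_sol(Z_b: np.ndarray, g_hat: np.ndarray, d_hat: np.ndarray,
            g_bar: float, t2: float, a: float, b: float,
            conv: float = 1e-4, max_iter: int = 500):
    """Iterative solve for the EB-shrunk batch location/scale (standard
    parametric ComBat inner loop); NaN-aware."""
    n = np.sum(np.isfinite(Z_b), axis=1).astype(float)
    g_old = g_hat.copy()
    d_old = d_hat.copy()
    for _ in range(max_iter):
        g_new = (n * t2 * g_hat + d_old * g_bar) / (n * t2 + d_old)
        sum2 = np.nansum((Z_b - g_new[:, None]) ** 2, axis=1)
        d_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        change = max(
            np.nanmax(np.abs(g_new - g_old) / (np.abs(g_old) + 1e-12)),
            np.nanmax(np.abs(d_new - d_old) / (np.abs(d_old) + 1e-12)),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def combat_correct(X: pd.DataFrame, batch) -> pd.DataFrame:
    """Remove additive/multiplicative batch effects from a samples x
    analytes matrix (log2 scale).

    Parameters
    ----------
    X : DataFrame
        Samples in rows, analytes in columns; NaN = missing.
    batch : sequence
        Batch label per sample (e.g. scan date).

    Returns a DataFrame of the same shape. A single batch returns the
    input unchanged (no contrast to estimate); a batch with fewer than
    two samples raises (merge or drop it first). All-missing analytes and
    zero-variance analytes pass through untouched.
    """
    batch = pd.Series(np.asarray(batch), index=X.index)
    codes, levels = pd.factorize(batch)
    n_batches = len(levels)
    if n_batches == 1:
        return X.copy()
    counts = np.bincount(codes)
    if counts.min() < 2:
        bad = levels[int(np.argmin(counts))]
        raise ValueError(
            f"batch {bad!r} has {counts.min()} sample(s); ComBat needs >= 2 "
            "per batch -- merge it with another batch or drop it"
        )

    # analytes x samples, float
    Y = X.to_numpy(dtype=float).T
    G, N = Y.shape
    present = np.isfinite(Y)
    n_per_gene = present.sum(axis=1)

    batch_mean = np.full((G, n_batches), np.nan)
    n_gb = np.zeros((G, n_batches))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN analytes
        for b in range(n_batches):
            cols = codes == b
            batch_mean[:, b] = np.nanmean(Y[:, cols], axis=1)
            n_gb[:, b] = present[:, cols].sum(axis=1)

    weights = n_gb / np.maximum(n_gb.sum(axis=1, keepdims=True), 1)
    grand_mean = np.nansum(np.nan_to_num(batch_mean) * weights, axis=1)
    fitted = batch_mean[:, codes]  # per-sample fitted batch mean
    resid = Y - fitted
    var_pooled = np.nansum(np.where(present, resid**2, 0.0), axis=1) / np.maximum(
        n_per_gene, 1
    )

    adjustable = (n_per_gene >= 2) & (var_pooled > 0) & np.all(n_gb >= 2, axis=1)
    if not adjustable.any():
        return X.copy()

    Z = (Y - grand_mean[:, None]) / np.sqrt(var_pooled)[:, None]

    Y_adj = Y.copy()
    gamma_star = np.zeros((G, n_batches))
    delta_star = np.ones((G, n_batches))
    for b in range(n_batches):
        cols = codes == b
        Z_b = Z[np.ix_(adjustable, cols)]
        g_hat = np.nanmean(Z_b, axis=1)
        with np.errstate(invalid="ignore"):
            d_hat = np.nanvar(Z_b, axis=1, ddof=1)
        d_hat = np.where(np.isfinite(d_hat) & (d_hat > 0), d_hat, 1.0)
        g_bar = float(np.mean(g_hat))
        t2 = float(np.var(g_hat, ddof=1))
        s2 = np.var(d_hat, ddof=1)
        if t2 <= 0 or s2 <= 0:
            # no gene-to-gene spread: nothing to shrink, use the estimates
            g_star, d_star = g_hat, d_hat
        else:
            a = _aprior(d_hat)
            bb = _bprior(d_hat)
            g_star, d_star = _it_sol(Z_b, g_hat, d_hat, g_bar, t2, a, bb)
        gamma_star[adjustable, b] = g_star
        delta_star[adjustable, b] = d_star

    g_full = gamma_star[:, codes]
    d_full = delta_star[:, codes]
    Z_adj = (Z - g_full) / np.sqrt(d_full)
    adj = Z_adj * np.sqrt(var_pooled)[:, None] + grand_mean[:, None]
    Y_adj[adjustable] = adj[adjustable]

    # preserve the per-analyte grand mean exactly (design choice; plain EB
    # adjustment only preserves it approximately)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        new_mean = np.nanmean(Y_adj, axis=1)
    shift = np.where(
        adjustable & np.isfinite(new_mean), grand_mean - new_mean, 0.0
    )
    Y_adj = Y_adj + shift[:, None]

    return pd.DataFrame(Y_adj.T, index=X.index, columns=X.columns)
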