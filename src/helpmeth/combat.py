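"""Parametric empirical-Bayes batch adjustment (ComBat).

Removes additive (location) and multiplicative (scale) batch effects
from the methylation matrix while protecting outcome covariates.  Each
feature is standardised under a model containing the protected design
and batch indicators; per-batch location (gamma) and scale (delta^2)
estimates are shrunk toward pooled priors — normal for gamma,
inverse-gamma for delta^2, hyperparameters by method of moments — via
the usual iterative EB update, then the data are back-transformed.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted


def _aprior(d: np.ndarray) -> float:
    m, s2 = d.mean(), d.var(ddof=1)
    return (2.0 * s2 + m**2) / s2


def _bprior(d: np.ndarray) -> float:
    m, s2 = d.mean(), d.var(ddof=1)
    return (m * s2 + m**3) / s2


def _it_sol(sdat, g_hat, d_hat, g_bar, t2, a, b, tol=1e-4, max_iter=1000):
    """Iterate the EB posterior updates for one batch until convergence."""
    n = sdat.shape[0]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = (n * t2 * g_hat + d_old * g_bar) / (n * t2 + d_old)
        sum2 = ((sdat - g_new[None, :]) ** 2).sum(axis=0)
        d_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        change = max(
            np.max(np.abs(g_new - g_old) / np.abs(g_old)),
            np.max(np.abs(d_new - d_old) / np.abs(d_old)),
        )
        g_old, d_old = g_new, d_new
        if change < tol:
            break
    return g_old, d_old


class ComBat(TransformerMixin, BaseEstimator):
    """Empirical-Bayes location/scale batch adjustment.

    scikit-learn transformer on ``X`` of shape ``(n_samples,
    n_features)``.  Batch labels and the protected covariate design are
    given at ``fit``; ``transform`` adjusts the same samples.

    Parameters
    ----------
    clip : tuple or None
        Clip adjusted values to this range (methylation scores live on
        0-100); ``None`` disables clipping.
    tol : float
        Convergence tolerance of the EB iteration.

    Attributes
    ----------
    gamma_star_, delta_star_ : ndarray (n_batches, n_features)
        Shrunk per-batch location and scale estimates.
    var_pooled_ : ndarray (n_features,)
        Pooled residual variance of the standardisation model.
    clip_fraction_ : float
        Fraction of adjusted entries that hit the clip bounds.
    """

    def __init__(self, clip=(0.0, 100.0), tol=1e-4, max_iter=1000):
        self.clip = clip
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None, *, batch, design=None):
        X, batch, design = self._validate(X, batch, design)
        n, _ = X.shape
        self.batches_, batch_idx = np.unique(batch, return_inverse=True)
        nb = self.batches_.size
        counts = np.bincount(batch_idx, minlength=nb)
        if nb < 2:
            # nothing to adjust; transform becomes the identity
            self.gamma_star_ = None
            return self
        onehot = np.zeros((n, nb))
        onehot[np.arange(n), batch_idx] = 1.0
        full = onehot if design is None else np.column_stack([onehot, design])
        if np.linalg.matrix_rank(full) < full.shape[1]:
            raise ValueError("rank-deficient design (batch confounded with covariates?)")

        beta, *_ = np.linalg.lstsq(full, X, rcond=None)
        grand = counts @ beta[:nb] / n  # (n_features,)
        resid = X - full @ beta
        var_pooled = (resid**2).mean(axis=0)
        if np.any(var_pooled <= 0):
            raise ValueError("zero pooled variance; constant features must be removed")

        stand_mean = np.tile(grand, (n, 1))
        if design is not None:
            stand_mean = stand_mean + design @ beta[nb:]
        sdat = (X - stand_mean) / np.sqrt(var_pooled)[None, :]

        gamma_hat = np.vstack(
            [sdat[batch_idx == b].mean(axis=0) for b in range(nb)]
        )
        singleton = counts < 2
        if singleton.any():
            warnings.warn(
                "singleton batch: scale adjustment skipped for "
                f"{self.batches_[singleton].tolist()}"
            )
        delta_hat = np.vstack(
            [
                sdat[batch_idx == b].var(axis=0, ddof=1)
                if counts[b] > 1
                else np.ones(X.shape[1])
                for b in range(nb)
            ]
        )

        gamma_star = np.empty_like(gamma_hat)
        delta_star = np.empty_like(delta_hat)
        for b in range(nb):
            if counts[b] < 2:
                gamma_star[b] = gamma_hat[b]
                delta_star[b] = 1.0
                continue
            g_bar = gamma_hat[b].mean()
            t2 = gamma_hat[b].var(ddof=1)
            a, bb = _aprior(delta_hat[b]), _bprior(delta_hat[b])
            gamma_star[b], delta_star[b] = _it_sol(
                sdat[batch_idx == b],
                gamma_hat[b],
                delta_hat[b],
                g_bar,
                t2,
                a,
                bb,
                tol=self.tol,
                max_iter=self.max_iter,
            )

        self.batch_idx_ = batch_idx
        self.gamma_hat_, self.delta_hat_ = gamma_hat, delta_hat
        self.gamma_star_, self.delta_star_ = gamma_star, delta_star
        self.var_pooled_ = var_pooled
        self.stand_mean_ = stand_mean
        return self

    def transform(self, X):
        check_is_fitted(self, "batches_")
        index = columns = None
        if isinstance(X, pd.DataFrame):
            index, columns = X.index, X.columns
        Xa = np.asarray(X, dtype=float)
        if self.gamma_star_ is None:  # single batch
            out = Xa.copy()
        else:
            if Xa.shape != self.stand_mean_.shape:
                raise ValueError("transform expects the samples seen at fit")
            sdat = (Xa - self.stand_mean_) / np.sqrt(self.var_pooled_)[None, :]
            adj = (sdat - self.gamma_star_[self.batch_idx_]) / np.sqrt(
                self.delta_star_[self.batch_idx_]
            )
            out = adj * np.sqrt(self.var_pooled_)[None, :] + self.stand_mean_
        if self.clip is not None:
            lo, hi = self.clip
            self.clip_fraction_ = float(((out < lo) | (out > hi)).mean())
            np.clip(out, lo, hi, out=out)
        else:
            self.clip_fraction_ = 0.0
        if index is not None:
            return pd.DataFrame(out, index=index, columns=columns)
        return out

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X, y, **fit_params).transform(X)

    @staticmethod
    def _validate(X, batch, design):
        Xa = np.asarray(X, dtype=float)
        if Xa.ndim != 2:
            raise ValueError("X must be (n_samples, n_features)")
        batch = np.asarray(batch)
        if batch.shape[0] != Xa.shape[0]:
            raise ValueError("batch labels must match the number of samples")
        if design is not None:
            design = np.asarray(design, dtype=float)
            if design.ndim == 1:
                design = design[:, None]
            if design.shape[0] != Xa.shape[0]:
                raise ValueError("design must match the number of samples")
        return Xa, batch, design


def combat(
    meth: pd.DataFrame,
    batch,
    protect: pd.DataFrame | np.ndarray | None = None,
    clip=(0.0, 100.0),
) -> tuple[pd.DataFrame, ComBat]:
    """Adjust a sites x samples methylation matrix for batch effects.

    ``protect`` is the outcome design to preserve (e.g. dummy-coded
    group labels, without an intercept).  Returns the adjusted matrix in
    the same orientation plus the fitted model.
    """
    model = ComBat(clip=clip)
    adjusted = model.fit_transform(meth.T, batch=batch, design=protect)
    return adjusted.T, model


def group_design(groups: pd.Series | np.ndarray) -> np.ndarray:
    """Dummy-code a categorical outcome (drop-first) for protection."""
    d = pd.get_dummies(pd.Series(np.asarray(groups)), drop_first=True)
    return d.to_numpy(dtype=float)
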