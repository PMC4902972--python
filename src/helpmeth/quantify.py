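"""Angle-metric methylation quantification from HpaII/MspI tag counts.

The methylation score of a site is derived from the angle of the
normalised (HpaII, MspI) signal vector:

    theta = arctan(h / m),   score = 100 * (1 - theta / (pi/2))

where ``h`` is the sample's HpaII counts-per-million at the site and
``m`` the pooled MspI reference counts-per-million.  No HpaII signal
(the enzyme was blocked by methylation) gives 100; HpaII signal equal to
the reference gives 50; HpaII dominating drives the score toward 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted


def normalize_counts(counts: pd.DataFrame | pd.Series) -> pd.DataFrame | pd.Series:
    """Scale each library (column) to counts per million of its total.

    Raises
    ------
    ValueError
        If any library has an all-zero total.
    """
    if isinstance(counts, pd.Series):
        total = counts.sum()
        if total <= 0:
            raise ValueError("all-zero library cannot be normalised")
        return counts * (1e6 / total)
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"all-zero libraries cannot be normalised: {bad}")
    return counts * (1e6 / totals)


def angle_score(h_norm, m_norm):
    """Angle-metric methylation score on the 0-100 scale.

    ``score = 100 * (1 - arctan(h/m) / (pi/2))``: decreasing in the
    HpaII signal ``h_norm``, increasing in the reference signal
    ``m_norm``, which must be positive.
    """
    h = np.asarray(h_norm, dtype=float)
    m = np.asarray(m_norm, dtype=float)
    if np.any(m <= 0):
        raise ValueError("m_norm must be positive (unquantifiable site)")
    if np.any(h < 0):
        raise ValueError("h_norm must be non-negative")
    score = 100.0 * (1.0 - np.arctan(h / m) / (np.pi / 2.0))
    if score.ndim == 0:
        return float(score)
    return score


class HelpTagQuantifier(TransformerMixin, BaseEstimator):
    """Transform HpaII tag counts into angle methylation scores.

    scikit-learn transformer operating on ``X`` of shape
    ``(n_samples, n_sites)``.  ``fit`` normalises the pooled MspI
    reference and flags sites whose raw reference count falls below
    ``min_mspi``; ``transform`` returns scores with those sites set to
    NaN (flagged, not scored).

    Parameters
    ----------
    mspi_reference : pandas.Series
        Raw MspI tag count per site (index = site ids, aligned with the
        columns of ``X``).
    min_mspi : int
        Sites with a reference count strictly below this are not scored.

    Attributes
    ----------
    mspi_cpm_ : ndarray
        Reference library in counts per million.
    low_mspi_ : ndarray of bool
        Sites excluded by the reference-count floor.
    """

    def __init__(self, mspi_reference: pd.Series | None = None, min_mspi: int = 4):
        self.mspi_reference = mspi_reference
        self.min_mspi = min_mspi

    def fit(self, X, y=None):
        if self.mspi_reference is None:
            raise ValueError("mspi_reference is required")
        ref = pd.Series(self.mspi_reference)
        X = self._check_X(X, ref)
        self.site_ids_ = np.asarray(ref.index)
        self.low_mspi_ = ref.to_numpy() < self.min_mspi
        self.mspi_cpm_ = normalize_counts(ref).to_numpy(dtype=float)
        return self

    def transform(self, X):
        check_is_fitted(self, "mspi_cpm_")
        ref = pd.Series(self.mspi_reference)
        X = self._check_X(X, ref)
        h = np.asarray(X, dtype=float)
        h_cpm = h * (1e6 / h.sum(axis=1, keepdims=True))
        ok = ~self.low_mspi_
        scores = np.full(h.shape, np.nan)
        scores[:, ok] = angle_score(h_cpm[:, ok], self.mspi_cpm_[None, ok])
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(scores, index=X.index, columns=X.columns)
        return scores

    @staticmethod
    def _check_X(X, ref):
        if isinstance(X, pd.DataFrame):
            if not np.array_equal(np.asarray(X.columns), np.asarray(ref.index)):
                raise ValueError("X columns must match the reference site index")
        else:
            X = np.asarray(X)
            if X.ndim != 2 or X.shape[1] != ref.size:
                raise ValueError("X must be (n_samples, n_sites) matching the reference")
        if np.asarray(X).min() < 0:
            raise ValueError("counts must be non-negative")
        if np.asarray(X).sum(axis=1).min() <= 0:
            raise ValueError("all-zero HpaII library")
        return X


def quantify(
    hpaii: pd.DataFrame, mspi_ref: pd.Series, min_mspi: int = 4
) -> pd.DataFrame:
    """Angle scores for a sites x samples HpaII count table.

    Thin wrapper over :class:`HelpTagQuantifier` keeping the
    sites-as-rows orientation of the on-disk tables.  Sites with an MspI
    reference count below ``min_mspi`` are returned as NaN.
    """
    if not hpaii.index.equals(mspi_ref.index):
        raise ValueError("HpaII and MspI tables must share the site index")
    q = HelpTagQuantifier(mspi_reference=mspi_ref, min_mspi=min_mspi)
    return q.fit(hpaii.T).transform(hpaii.T).T
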