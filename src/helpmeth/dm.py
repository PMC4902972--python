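"""Differential-methylation calling under three covariate regression models.

Per site, the methylation score is regressed on (1) maximum systolic
blood pressure, (2) ordinal proteinuria grade, (3) both together.
Significance is the ANOVA F-test of each model against the
intercept-only null, Benjamini-Hochberg adjusted across sites per
model.  A site is called differentially methylated (DM) under a model
when its adjusted p falls below the FDR threshold *and* the absolute
PE-vs-control group mean difference exceeds the effect gate (10 score
units by default); the hypertension-only group does not enter the
effect difference.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

PROTEINURIA_LABELS = {
    "negative/trace": 0,
    "negative": 0,
    "trace": 0,
    "1+": 1,
    "2+": 2,
    "3+": 3,
    ">3+": 3,
    ">=3+": 3,
    "≥3+": 3,
}

MODELS = {
    "model1": ("maxSBP",),
    "model2": ("proteinuria_grade",),
    "model3": ("maxSBP", "proteinuria_grade"),
}


def encode_proteinuria(labels) -> np.ndarray:
    """Ordinal encoding of dipstick proteinuria: negative/trace, 1+, 2+, >=3+ -> 0..3."""
    if isinstance(labels, (pd.Series, np.ndarray)):
        labels = list(labels)
    elif not isinstance(labels, (list, tuple)):
        labels = [labels]
    out = []
    for lab in labels:
        if isinstance(lab, (int, np.integer)):
            if not 0 <= int(lab) <= 3:
                raise ValueError(f"proteinuria grade out of range: {lab!r}")
            out.append(int(lab))
            continue
        key = str(lab).strip().lower()
        if key in {"0", "1", "2", "3"}:
            out.append(int(key))
        elif key in PROTEINURIA_LABELS:
            out.append(PROTEINURIA_LABELS[key])
        else:
            raise ValueError(f"unknown proteinuria label: {lab!r}")
    return np.asarray(out, dtype=int)


def _model_f_p(Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised full-vs-intercept F-test for every column of Y.

    Y is (n_samples, n_sites); X the design including the intercept.
    Returns (F, p, rss_full).  Constant sites get p = 1 by convention.
    """
    n, p = X.shape
    q, _ = np.linalg.qr(X)
    resid = Y - q @ (q.T @ Y)
    rss1 = (resid**2).sum(axis=0)
    yc = Y - Y.mean(axis=0)
    rss0 = (yc**2).sum(axis=0)
    df1, df2 = p - 1, n - p
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((rss0 - rss1) / df1) / (rss1 / df2)
    pvals = stats.f.sf(f, df1, df2)
    constant = rss0 <= 1e-12
    pvals = np.where(constant | ~np.isfinite(f), 1.0, pvals)
    f = np.where(np.isfinite(f), f, 0.0)
    return f, pvals, rss1


class DifferentialMethylation(BaseEstimator):
    """Fit the three covariate models and call DM sites.

    scikit-learn style estimator: ``fit(X, meta)`` with ``X`` of shape
    ``(n_samples, n_sites)`` and ``meta`` carrying ``maxSBP``,
    ``proteinuria_grade`` and ``group`` columns for the same samples.

    Parameters
    ----------
    fdr : float
        Benjamini-Hochberg threshold on the per-model adjusted p.
    delta : float
        Gate on the absolute PE-minus-control mean score difference.

    Attributes
    ----------
    results_ : pandas.DataFrame
        Per-site statistics: per model the slope(s), F, p, q and DM
        flag, plus the shared ``delta`` column.
    """

    def __init__(self, fdr: float = 0.05, delta: float = 10.0):
        self.fdr = fdr
        self.delta = delta

    def fit(self, X, meta: pd.DataFrame, y=None):
        if isinstance(X, pd.DataFrame):
            sites = X.columns
            Y = X.to_numpy(dtype=float)
        else:
            Y = np.asarray(X, dtype=float)
            sites = pd.RangeIndex(Y.shape[1])
        if Y.shape[0] != len(meta):
            raise ValueError("X and meta must describe the same samples")
        n = Y.shape[0]
        grade = encode_proteinuria(meta["proteinuria_grade"])
        covs = {"maxSBP": meta["maxSBP"].to_numpy(float),
                "proteinuria_grade": grade.astype(float)}

        res = pd.DataFrame(index=sites)
        is_pe = (meta["group"] == "pe").to_numpy()
        is_ctrl = (meta["group"] == "control").to_numpy()
        if is_pe.sum() < 3 or is_ctrl.sum() < 3:
            raise ValueError("need >=3 PE and >=3 control samples for the effect gate")
        res["delta"] = Y[is_pe].mean(axis=0) - Y[is_ctrl].mean(axis=0)

        for model, names in MODELS.items():
            Xd = np.column_stack([np.ones(n)] + [covs[c] for c in names])
            f, p, rss = _model_f_p(Y, Xd)
            beta, *_ = np.linalg.lstsq(Xd, Y, rcond=None)
            q = multipletests(p, method="fdr_bh")[1]
            for j, c in enumerate(names):
                res[f"{model}_beta_{c}"] = beta[1 + j]
            res[f"{model}_F"] = f
            res[f"{model}_p"] = p
            res[f"{model}_q"] = q
            res[f"{model}_rss"] = rss
            res[f"dm_{model}"] = (q < self.fdr) & (res["delta"].abs() > self.delta)
        self.results_ = res
        return self

    def dm_sites(self, model: str) -> pd.Index:
        return self.results_.index[self.results_[f"dm_{model}"]]


def fit_models(
    meth: pd.DataFrame, meta: pd.DataFrame, fdr: float = 0.05, delta: float = 10.0
) -> pd.DataFrame:
    """Per-site DM statistics for a sites x samples matrix (thin wrapper)."""
    est = DifferentialMethylation(fdr=fdr, delta=delta)
    est.fit(meth.T, meta)
    return est.results_


def model_overlap(results: pd.DataFrame) -> dict[str, int]:
    """Counts of DM sites in every subset of the three models (Venn counts)."""
    flags = {m: results[f"dm_{m}"] for m in MODELS}
    out = {m: int(flags[m].sum()) for m in MODELS}
    for a, b in combinations(MODELS, 2):
        out[f"{a}&{b}"] = int((flags[a] & flags[b]).sum())
    out["model1&model2&model3"] = int(
        (flags["model1"] & flags["model2"] & flags["model3"]).sum()
    )
    return out
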