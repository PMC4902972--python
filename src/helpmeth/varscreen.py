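"""Variably methylated locus screen: PE-vs-control variance F-test.

Preeclampsia is heterogeneous (early vs late onset, severity spectrum),
so exposure may inflate the *spread* of methylation within the PE group
rather than shift its mean.  Per site, the ratio of unbiased sample
variances (PE over control) is tested with the two-sided variance-ratio
F-test; sites with Benjamini-Hochberg adjusted p below a stringent
threshold and a PE-inflated ratio above the fold gate are called
variably methylated (var) sites.  Sites are mapped to genes whose
interval, extended by a window, covers them.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests


def f_test_variance(control_scores, pe_scores) -> tuple[float, float]:
    """Variance ratio PE/control and two-sided F-test p-value.

    ``p = 2 * min(P(F <= ratio), P(F >= ratio))`` with
    ``(n_pe - 1, n_control - 1)`` degrees of freedom, capped at 1.
    Zero variance in either group leaves the p undefined (NaN).
    """
    c = np.asarray(control_scores, dtype=float)
    p_ = np.asarray(pe_scores, dtype=float)
    if c.size < 2 or p_.size < 2:
        raise ValueError("need >=2 samples per group")
    vc, vp = c.var(ddof=1), p_.var(ddof=1)
    if vc == 0 or vp == 0:
        warnings.warn("zero variance in a group: p undefined, site skipped")
        return (np.inf if vc == 0 else 0.0), float("nan")
    ratio = vp / vc
    df1, df2 = p_.size - 1, c.size - 1
    pval = 2.0 * min(stats.f.cdf(ratio, df1, df2), stats.f.sf(ratio, df1, df2))
    return float(ratio), float(min(pval, 1.0))


class VarianceScreen(BaseEstimator):
    """Call var sites from a samples x sites matrix and group labels.

    Parameters
    ----------
    q_threshold : float
        BH-adjusted p threshold (stringent by design; default 1e-7).
    ratio_threshold : float
        Minimum PE/control variance ratio; calls are restricted to the
        PE-inflated direction (ratio > 1 is implied by the default 20).

    Attributes
    ----------
    results_ : pandas.DataFrame
        Per site: control and PE variances, ratio, p, q and the var flag.
        Zero-variance sites carry NaN p and are never flagged.
    """

    def __init__(self, q_threshold: float = 1e-7, ratio_threshold: float = 20.0):
        self.q_threshold = q_threshold
        self.ratio_threshold = ratio_threshold

    def fit(self, X, groups, y=None):
        if isinstance(X, pd.DataFrame):
            sites = X.columns
            Y = X.to_numpy(dtype=float)
        else:
            Y = np.asarray(X, dtype=float)
            sites = pd.RangeIndex(Y.shape[1])
        groups = np.asarray(groups)
        is_pe, is_ctrl = groups == "pe", groups == "control"
        n_pe, n_c = int(is_pe.sum()), int(is_ctrl.sum())
        if n_pe < 2 or n_c < 2:
            raise ValueError("need >=2 PE and >=2 control samples")
        vc = Y[is_ctrl].var(axis=0, ddof=1)
        vp = Y[is_pe].var(axis=0, ddof=1)
        degenerate = (vc == 0) | (vp == 0)
        if degenerate.any():
            warnings.warn(
                f"{int(degenerate.sum())} zero-variance sites skipped in the F-test"
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = vp / vc
        df1, df2 = n_pe - 1, n_c - 1
        p = 2.0 * np.minimum(stats.f.cdf(ratio, df1, df2), stats.f.sf(ratio, df1, df2))
        p = np.minimum(p, 1.0)
        p[degenerate] = np.nan
        q = np.full_like(p, np.nan)
        ok = ~np.isnan(p)
        if ok.any():
            q[ok] = multipletests(p[ok], method="fdr_bh")[1]
        flag = ok & (q < self.q_threshold) & (ratio > self.ratio_threshold) & (ratio > 1)
        self.results_ = pd.DataFrame(
            {
                "var_control": vc,
                "var_pe": vp,
                "ratio": ratio,
                "p": p,
                "q": q,
                "var_flag": flag,
            },
            index=sites,
        )
        return self

    @property
    def var_sites_(self) -> pd.Index:
        return self.results_.index[self.results_["var_flag"]]


def call_var_hpaii(
    meth: pd.DataFrame,
    groups,
    q_threshold: float = 1e-7,
    ratio_threshold: float = 20.0,
) -> pd.DataFrame:
    """Per-site variance screen on a sites x samples matrix (thin wrapper)."""
    screen = VarianceScreen(q_threshold=q_threshold, ratio_threshold=ratio_threshold)
    screen.fit(meth.T, np.asarray(groups))
    return screen.results_


def assign_genes(
    sites: pd.DataFrame, genes: pd.DataFrame, window: int = 50000
) -> pd.DataFrame:
    """Map each site to every gene whose window-extended interval covers it.

    Gene intervals are half-open BED ``[start, end)`` extended by
    ``window`` on both sides; a site exactly ``window + 1`` bp beyond a
    gene end is unassigned.  Returns long format (one row per
    site-gene pair); sites with no gene are absent.
    """
    trees: dict[str, IntervalTree] = {}
    for c, sub in genes.groupby("chrom"):
        tree = IntervalTree()
        for start, end, gid in zip(sub["start"], sub["end"], sub["gene_id"]):
            tree.addi(int(start) - window, int(end) + window, gid)
        trees[c] = tree
    rows = []
    for sid, row in sites.iterrows():
        tree = trees.get(row["chrom"])
        if tree is None:
            continue
        for iv in tree.at(int(row["pos"])):
            rows.append((sid, iv.data))
    return pd.DataFrame(rows, columns=["site_id", "gene_id"])


def per_gene_counts(
    var_results: pd.DataFrame, site_genes: pd.DataFrame
) -> pd.Series:
    """Number of var-flagged sites per gene (a site counts once per gene)."""
    flagged = set(var_results.index[var_results["var_flag"]])
    hits = site_genes[site_genes["site_id"].isin(flagged)]
    return hits.groupby("gene_id")["site_id"].nunique().sort_values(ascending=False)
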