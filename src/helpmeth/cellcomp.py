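"""Cell-subtype composition handling.

The amnion mixes two cell types — amniotic epithelial (AE) and stromal
(AS) cells — in sample-specific proportions, which imprints a broad
correlated signal on the methylation matrix.  This module (1) calls
AE-vs-AS differentially methylated CpGs from bisulfite counts of the
purified isolates, (2) maps them onto HpaII sites to obtain candidate
composition reporters, (3) selects the most robust reporter — a
candidate free of phenotype association whose methylation tracks the
dominant axis of matrix variability — and (4) prunes every site whose
profile correlates with the reporter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


def pool_replicates(wgbs: pd.DataFrame) -> pd.DataFrame:
    """Sum methylated/total read counts across replicates per CpG."""
    pooled = (
        wgbs.groupby(["chrom", "pos"], as_index=False)[["meth", "total"]].sum()
    )
    return pooled


def call_celltype_dmrs(
    ae: pd.DataFrame, as_: pd.DataFrame, p_threshold: float = 1e-5
) -> pd.DataFrame:
    """Fisher's exact test per CpG on pooled AE vs AS bisulfite counts.

    Replicates are pooled (summed) per cell type — low-coverage
    bisulfite data cannot support per-replicate testing.  Returns the
    per-CpG table with two-sided p-values and an ``is_dmr`` flag
    (p < ``p_threshold``); zero-coverage CpGs are skipped.
    """
    a = pool_replicates(ae).rename(columns={"meth": "meth_ae", "total": "total_ae"})
    b = pool_replicates(as_).rename(columns={"meth": "meth_as", "total": "total_as"})
    merged = a.merge(b, on=["chrom", "pos"], how="inner")
    covered = (merged["total_ae"] > 0) & (merged["total_as"] > 0)
    merged = merged.loc[covered].reset_index(drop=True)

    ma = merged["meth_ae"].to_numpy(np.int64)
    ta = merged["total_ae"].to_numpy(np.int64)
    mb = merged["meth_as"].to_numpy(np.int64)
    tb = merged["total_as"].to_numpy(np.int64)
    pvals = np.ones(len(merged))
    for i in range(len(merged)):
        table = [[ma[i], ta[i] - ma[i]], [mb[i], tb[i] - mb[i]]]
        pvals[i] = stats.fisher_exact(table, alternative="two-sided")[1]
    merged["p"] = pvals
    merged["is_dmr"] = pvals < p_threshold
    return merged


def candidates_at_hpaii(
    dmrs: pd.DataFrame, sites: pd.DataFrame, window: int = 0
) -> list[str]:
    """HpaII sites whose CpG lies within ``window`` bp of a DMR CpG.

    ``dmrs`` is the output of :func:`call_celltype_dmrs` (only rows with
    ``is_dmr`` are used, or all rows if the column is absent).
    """
    d = dmrs[dmrs["is_dmr"]] if "is_dmr" in dmrs.columns else dmrs
    out: list[str] = []
    pos = sites["pos"].to_numpy(np.int64)
    for c, sub in d.groupby("chrom"):
        mask = (sites["chrom"] == c).to_numpy()
        if not mask.any():
            continue
        dp = np.sort(sub["pos"].to_numpy(np.int64))
        p = pos[mask]
        lo = np.searchsorted(dp, p - window, side="left")
        hi = np.searchsorted(dp, p + window, side="right")
        out.extend(sites.index[mask][hi > lo])
    return sorted(out)


@dataclass
class ReporterResult:
    """Reporter selection outcome and the pruned site universe."""

    candidates: pd.DataFrame
    reporter: str
    retained: pd.Index
    rho: pd.Series = field(repr=False)


def _simple_regression_p(y: np.ndarray, x: np.ndarray) -> float:
    """Two-sided slope p of an OLS simple regression (constant x -> p=1)."""
    if np.std(x) == 0 or np.std(y) == 0:
        return 1.0
    return float(stats.linregress(x, y).pvalue)


def select_reporter(
    candidates: list[str],
    meth: pd.DataFrame,
    meta: pd.DataFrame,
    pheno_alpha: float = 0.01,
) -> pd.DataFrame:
    """Score composition-reporter candidates and pick the most robust one.

    For each candidate HpaII site the phenotype association is the
    smaller p of its methylation regressed on maximum systolic BP and on
    proteinuria grade; candidates below ``pheno_alpha`` are excluded as
    phenotype-confounded.  The variability association is the p-value of
    the candidate regressed on the first principal component of the full
    matrix (the dominant axis that composition drives); among
    unconfounded candidates the smallest variability p wins.

    Returns the candidate table with columns ``pheno_p``, ``var_p``,
    ``excluded`` and ``selected``.

    Raises
    ------
    RuntimeError
        If every candidate is phenotype-confounded (no composition
        adjustment is possible).
    """
    if len(candidates) == 0:
        raise ValueError("at least one candidate is required")
    X = meth.T.to_numpy(dtype=float)  # samples x sites
    X = X - X.mean(axis=0)
    # first left singular vector = PC1 sample scores
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    pc1 = u[:, 0] * s[0]

    sbp = meta["maxSBP"].to_numpy(float)
    grade = meta["proteinuria_grade"].to_numpy(float)
    rows = []
    for site in candidates:
        y = meth.loc[site].to_numpy(float)
        pheno_p = min(
            _simple_regression_p(y, sbp), _simple_regression_p(y, grade)
        )
        var_p = _simple_regression_p(y, pc1)
        rows.append((site, pheno_p, var_p))
    table = pd.DataFrame(rows, columns=["site_id", "pheno_p", "var_p"]).set_index(
        "site_id"
    )
    table["excluded"] = table["pheno_p"] < pheno_alpha
    eligible = table[~table["excluded"]]
    if eligible.empty:
        raise RuntimeError(
            "all reporter candidates are phenotype-associated; "
            "composition adjustment is not possible"
        )
    reporter = eligible["var_p"].idxmin()
    table["selected"] = table.index == reporter
    return table


def prune_correlated(
    meth: pd.DataFrame, reporter: str, rho_threshold: float = 0.3
) -> ReporterResult | pd.Index:
    """Remove sites whose |Spearman rho| with the reporter exceeds the threshold.

    The reporter itself is removed too.  Constant-score sites have an
    undefined correlation and are retained with a warning.  Returns the
    retained site index and the per-site rho (NaN where undefined).
    """
    if reporter not in meth.index:
        raise ValueError(f"reporter {reporter!r} not present in the matrix")
    vals = meth.to_numpy(dtype=float)
    ranks = stats.rankdata(vals, axis=1)
    r_rep = stats.rankdata(meth.loc[reporter].to_numpy(float))
    rc = ranks - ranks.mean(axis=1, keepdims=True)
    rr = r_rep - r_rep.mean()
    denom = np.sqrt((rc**2).sum(axis=1) * (rr**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rc @ rr) / denom
    rho = pd.Series(rho, index=meth.index, name="rho")
    n_const = int(rho.isna().sum())
    if n_const:
        warnings.warn(f"{n_const} constant-score sites: rho undefined, retained")
    drop = (rho.abs() > rho_threshold).fillna(False)
    drop.loc[reporter] = True
    retained = meth.index[~drop.to_numpy()]
    return retained, rho


def composition_prune(
    meth: pd.DataFrame,
    sites: pd.DataFrame,
    wgbs_ae: pd.DataFrame,
    wgbs_as: pd.DataFrame,
    meta: pd.DataFrame,
    dmr_p: float = 1e-5,
    candidate_window: int = 0,
    pheno_alpha: float = 0.01,
    rho_threshold: float = 0.3,
) -> ReporterResult:
    """Full composition stage: DMRs -> candidates -> reporter -> pruning."""
    dmrs = call_celltype_dmrs(wgbs_ae, wgbs_as, p_threshold=dmr_p)
    cand = candidates_at_hpaii(dmrs, sites, window=candidate_window)
    cand = [c for c in cand if c in meth.index]
    table = select_reporter(cand, meth, meta, pheno_alpha=pheno_alpha)
    reporter = table.index[table["selected"]][0]
    retained, rho = prune_correlated(meth, reporter, rho_threshold=rho_threshold)
    return ReporterResult(candidates=table, reporter=reporter, retained=retained, rho=rho)
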