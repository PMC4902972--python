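"""Cohort characteristics statistics.

Categorical variables are compared across the three exposure groups with
the Fisher-Freeman-Halton exact test (the r x c generalisation of
Fisher's exact test, computed by full enumeration of tables with the
observed margins); continuous variables with the pooled-variance t-test
(two groups) or one-way ANOVA (three or more), computable from raw
values or from (mean, sd, n) summaries alone.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

# relative tolerance when comparing table probabilities for the
# two-sided "as or more extreme" ordering (ties at printed precision)
_TIE_RTOL = 1e-7


def _log_table_prob(table: np.ndarray, lr: np.ndarray, lc: np.ndarray, ln: float) -> float:
    return float(lr.sum() + lc.sum() - ln - gammaln(table + 1.0).sum())


def fisher_exact_rxc(
    table,
    max_tables: int = 5_000_000,
    monte_carlo: int | None = None,
    seed: int = 0,
) -> float:
    """Two-sided Fisher-Freeman-Halton exact p for an r x c table.

    The p-value sums the multivariate hypergeometric probabilities of
    every table with the observed margins whose probability does not
    exceed the observed table's (within relative tolerance 1e-7).

    Parameters
    ----------
    max_tables : int
        Enumeration budget; exceeding it raises unless ``monte_carlo``
        is given.
    monte_carlo : int, optional
        Number of Patefield-sampled tables for the seeded Monte-Carlo
        estimate used instead of enumeration.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("table must be at least 2 x 2")
    if (t < 0).any():
        raise ValueError("table entries must be non-negative")
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    n = int(t.sum())
    if n == 0:
        return 1.0
    lr, lc, ln = gammaln(rows + 1.0), gammaln(cols + 1.0), gammaln(n + 1.0)
    logp_obs = _log_table_prob(t, lr, lc, ln)
    cutoff = logp_obs + math.log1p(_TIE_RTOL)

    if monte_carlo is not None:
        rng = np.random.default_rng(seed)
        dist = stats.random_table(rows, cols)
        draws = dist.rvs(size=monte_carlo, method="patefield", random_state=rng)
        logps = (
            lr.sum()
            + lc.sum()
            - ln
            - gammaln(np.asarray(draws) + 1.0).sum(axis=(1, 2))
        )
        hits = int((logps <= cutoff).sum())
        return (hits + 1) / (monte_carlo + 1)

    # full enumeration: fill the table cell by cell in row-major order;
    # the last cell of each row and the whole last row are determined.
    r, c = t.shape
    total = 0.0
    count = 0

    def recurse(i: int, cell: np.ndarray, col_left: np.ndarray) -> None:
        nonlocal total, count
        if i == r - 1:
            if (col_left < 0).any():
                return
            cand = cell.copy()
            cand[r - 1] = col_left
            count += 1
            if count > max_tables:
                raise RuntimeError(
                    "enumeration budget exceeded; pass monte_carlo=N for a "
                    "seeded Monte-Carlo p-value"
                )
            lp = _log_table_prob(cand, lr, lc, ln)
            if lp <= cutoff:
                total += math.exp(lp)
            return
        _fill_row(i, 0, rows[i], cell, col_left)

    def _fill_row(i, j, row_left, cell, col_left):
        if j == c - 1:
            if row_left > col_left[j]:
                return
            cell[i, j] = row_left
            recurse(i + 1, cell, col_left - cell[i])
            return
        hi = min(row_left, col_left[j])
        for v in range(hi + 1):
            cell[i, j] = v
            _fill_row(i, j + 1, row_left - v, cell, col_left)

    recurse(0, np.zeros_like(t), cols.copy())
    return min(total, 1.0)


def continuous_test(
    groups=None, *, means=None, sds=None, ns=None
) -> float:
    """t-test (2 groups) or one-way ANOVA (>=3) p, from raw values or summaries.

    Pass either ``groups`` (a sequence of per-group value arrays) or the
    ``means``/``sds``/``ns`` summary triplet.  The two-group test is the
    two-sided pooled-variance t-test; the raw and summary paths are
    algebraically identical.
    """
    if groups is not None:
        arrays = [np.asarray(g, dtype=float) for g in groups]
        means = np.array([a.mean() for a in arrays])
        sds = np.array([a.std(ddof=1) for a in arrays])
        ns = np.array([a.size for a in arrays])
    else:
        means = np.asarray(means, dtype=float)
        sds = np.asarray(sds, dtype=float)
        ns = np.asarray(ns, dtype=int)
    if means.size < 2:
        raise ValueError("need at least two groups")
    if (ns < 2).any() or (sds <= 0).any():
        raise ValueError("each group needs n >= 2 and sd > 0")

    if means.size == 2:
        df = int(ns.sum() - 2)
        sp2 = (((ns - 1) * sds**2).sum()) / df
        tstat = (means[0] - means[1]) / math.sqrt(sp2 * (1 / ns[0] + 1 / ns[1]))
        return float(2 * stats.t.sf(abs(tstat), df))

    n = int(ns.sum())
    grand = float((ns * means).sum() / n)
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1) * sds**2).sum())
    df1, df2 = means.size - 1, n - means.size
    f = (ssb / df1) / (ssw / df2)
    return float(stats.f.sf(f, df1, df2))


_CATEGORICAL = ["sex", "primiparous", "smoked", "history_pe", "mgso4", "anemia", "obese"]
_CONTINUOUS = ["maternal_age", "gestational_week", "birth_weight", "maxSBP", "maxDBP"]
_GROUP_ORDER = ["control", "hypertension", "pe"]


def summarize_cohort(meta: pd.DataFrame) -> pd.DataFrame:
    """Characteristics table: per-group summaries plus a p-value per variable.

    Continuous variables report mean +/- sd per group with a one-way
    ANOVA p; categorical ones report level counts with the exact r x c
    test p.  Missing columns are reported in the ``note`` column rather
    than raising.
    """
    groups = [g for g in _GROUP_ORDER if g in set(meta["group"])]
    rows = []
    for var in _CONTINUOUS:
        if var not in meta.columns:
            rows.append({"variable": var, "p": np.nan, "note": "missing column"})
            continue
        per = [meta.loc[meta["group"] == g, var].dropna().to_numpy() for g in groups]
        entry = {"variable": var, "note": ""}
        for g, vals in zip(groups, per):
            entry[g] = f"{vals.mean():.1f} ± {vals.std(ddof=1):.1f}"
        entry["p"] = continuous_test(per)
        rows.append(entry)
    for var in _CATEGORICAL:
        if var not in meta.columns:
            rows.append({"variable": var, "p": np.nan, "note": "missing column"})
            continue
        ct = pd.crosstab(meta[var], meta["group"]).reindex(columns=groups, fill_value=0)
        entry = {"variable": var, "note": ""}
        for g in groups:
            entry[g] = "/".join(str(v) for v in ct[g].to_numpy())
        if ct.shape[0] < 2:
            entry["p"] = 1.0
            entry["note"] = "single level"
        else:
            entry["p"] = fisher_exact_rxc(ct.to_numpy())
        rows.append(entry)
    return pd.DataFrame(rows).set_index("variable")
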