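"""Independent oracles used by the test suite (never the implementation)."""

from __future__ import annotations

import itertools
import math
import subprocess
import tempfile
from pathlib import Path

import numpy as np


def fisher_rxc_tiny_oracle(table: np.ndarray) -> float:
    """Exhaustive Fisher-Freeman-Halton p by iterating *all* candidate
    matrices with entries up to the grand total and rejecting margin
    mismatches.  Only viable for tiny tables; deliberately naive and
    structurally unlike the package's constrained enumeration."""
    t = np.asarray(table, dtype=int)
    rows, cols, n = t.sum(1), t.sum(0), int(t.sum())

    def prob(m):
        num = sum(math.lgamma(x + 1) for x in list(rows) + list(cols))
        den = math.lgamma(n + 1) + sum(math.lgamma(x + 1) for x in m.ravel())
        return math.exp(num - den)

    p_obs = prob(t)
    total = 0.0
    shape = t.shape
    for cells in itertools.product(range(n + 1), repeat=t.size):
        m = np.array(cells).reshape(shape)
        if (m.sum(1) == rows).all() and (m.sum(0) == cols).all():
            p = prob(m)
            if p <= p_obs * (1 + 1e-9):
                total += p
    return min(total, 1.0)


def r_fisher_p(table: np.ndarray) -> float:
    """R's fisher.test as an independent exact-test oracle."""
    t = np.asarray(table, dtype=int)
    rows = ",".join("c(" + ",".join(map(str, r)) + ")" for r in t)
    script = f"cat(format(fisher.test(rbind({rows}))$p.value, digits=15))"
    out = subprocess.run(
        ["Rscript", "-e", script], capture_output=True, text=True, check=True
    )
    return float(out.stdout.strip())


def r_combat(X: np.ndarray, batch: np.ndarray, group: np.ndarray) -> np.ndarray:
    """sva::ComBat (parametric) as the batch-adjustment oracle.

    X is features x samples; returns the adjusted matrix.
    """
    with tempfile.TemporaryDirectory() as td:
        td = Path(td)
        np.savetxt(td / "x.txt", X)
        np.savetxt(td / "batch.txt", batch, fmt="%d")
        np.savetxt(td / "group.txt", group, fmt="%d")
        script = f"""
suppressMessages(library(sva))
x <- as.matrix(read.table("{td}/x.txt"))
batch <- scan("{td}/batch.txt")
group <- scan("{td}/group.txt")
mod <- model.matrix(~factor(group))
out <- ComBat(dat=x, batch=factor(batch), mod=mod, par.prior=TRUE)
write.table(out, "{td}/out.txt", row.names=FALSE, col.names=FALSE)
"""
        subprocess.run(["Rscript", "-e", script], capture_output=True, text=True, check=True)
        return np.loadtxt(td / "out.txt")


def bh_reject_oracle(pvals: np.ndarray, alpha: float) -> np.ndarray:
    """Benjamini-Hochberg rejection set straight from the step-up
    definition: largest k with p_(k) <= k*alpha/n, reject all p at or
    below that order statistic."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    sorted_p = p[order]
    ks = np.flatnonzero(sorted_p <= (np.arange(1, n + 1) * alpha / n))
    reject = np.zeros(n, dtype=bool)
    if ks.size:
        reject[order[: ks[-1] + 1]] = True
    return reject
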