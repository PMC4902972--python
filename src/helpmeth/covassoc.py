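"""Covariate attribution of methylation variability via PCA.

The top principal components of the (per-site mean-centred) methylation
matrix summarise the dominant axes of inter-sample variability; each
component is regressed on each clinical covariate, and each covariate
additionally receives one joint test against all components together.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA


@dataclass
class PCAResult:
    """Top-K principal components of the sample space."""

    scores: pd.DataFrame          # samples x PCs
    explained_variance_ratio: np.ndarray
    model: PCA

    @property
    def k(self) -> int:
        return self.scores.shape[1]


@dataclass
class AssociationHeatmap:
    """Per-(covariate, PC) p-values plus one joint p per covariate."""

    pvalues: pd.DataFrame         # covariates x PCs
    joint: pd.Series              # per covariate

    @property
    def neglog10(self) -> pd.DataFrame:
        return -np.log10(self.pvalues)


def pca(meth: pd.DataFrame, k: int = 10) -> PCAResult:
    """PCA of the samples over sites, mean-centring each site only.

    ``meth`` is sites x samples with no missing entries.  Scores keep
    the 0-100 scale (no per-site variance scaling).
    """
    X = meth.T.to_numpy(dtype=float)  # samples x sites
    if np.isnan(X).any():
        raise ValueError("methylation matrix contains missing values")
    k = int(k)
    if k > min(X.shape):
        raise ValueError(f"k={k} exceeds matrix rank bound {min(X.shape)}")
    model = PCA(n_components=k, svd_solver="randomized", random_state=0)
    scores = model.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=meth.columns, columns=cols),
        explained_variance_ratio=model.explained_variance_ratio_,
        model=model,
    )


def _is_continuous(series: pd.Series) -> bool:
    if series.dtype.kind in "fc":
        return True
    if series.dtype.kind in "iu":
        # ordinal integer covariates (e.g. proteinuria grade) are
        # treated as continuous regressors
        return series.nunique() > 2
    return False


def pc_covariate_matrix(
    pcs: PCAResult, meta: pd.DataFrame, covariates: list[str] | None = None
) -> AssociationHeatmap:
    """Linear-regression / ANOVA p-values of each PC on each covariate.

    Continuous covariates use a simple linear regression of the PC
    score; categorical ones a one-way ANOVA across levels.  The joint
    test per covariate regresses the covariate on all K PC scores
    together (overall F-test); categorical covariates use the dummy
    coding of their levels as a multivariate response, combining each
    dummy's F-test by the minimum Bonferroni-adjusted p.  Single-level
    covariates are skipped with a warning.
    """
    if covariates is None:
        covariates = [c for c in meta.columns]
    scores = pcs.scores.loc[meta.index]
    S = scores.to_numpy(float)
    rows, joint = {}, {}
    for cov in covariates:
        series = meta[cov]
        if series.nunique() < 2:
            warnings.warn(f"covariate {cov!r} has a single level; skipped")
            continue
        if _is_continuous(series):
            x = series.to_numpy(float)
            pvals = [
                stats.linregress(x, scores[c].to_numpy()).pvalue
                for c in scores.columns
            ]
            joint[cov] = _joint_f_p(x, S)
        else:
            codes, _ = pd.factorize(series)
            groups_per_pc = lambda c: [
                scores[c].to_numpy()[codes == g] for g in np.unique(codes)
            ]
            pvals = [stats.f_oneway(*groups_per_pc(c)).pvalue for c in scores.columns]
            dummies = pd.get_dummies(series, drop_first=True).to_numpy(float)
            ps = [_joint_f_p(dummies[:, j], S) for j in range(dummies.shape[1])]
            joint[cov] = min(1.0, min(ps) * len(ps))
        rows[cov] = pvals
    pvalues = pd.DataFrame.from_dict(rows, orient="index", columns=pcs.scores.columns)
    return AssociationHeatmap(pvalues=pvalues, joint=pd.Series(joint, name="joint_p"))


def _joint_f_p(y: np.ndarray, S: np.ndarray) -> float:
    """Overall F-test p of y regressed on all columns of S plus intercept."""
    n, k = S.shape
    X = np.column_stack([np.ones(n), S])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss1 = float(((y - X @ beta) ** 2).sum())
    rss0 = float(((y - y.mean()) ** 2).sum())
    if rss0 <= 0:
        return 1.0
    df1, df2 = k, n - k - 1
    if rss1 <= 0:
        return 0.0
    f = ((rss0 - rss1) / df1) / (rss1 / df2)
    return float(stats.f.sf(f, df1, df2))


def plot_heatmap(heatmap: AssociationHeatmap, path: str) -> None:
    """Render the -log10 p heatmap (covariates x PCs) to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = heatmap.neglog10
    fig, ax = plt.subplots(
        figsize=(1 + 0.6 * data.shape[1], 1 + 0.4 * data.shape[0])
    )
    im = ax.imshow(data.to_numpy(), aspect="auto", cmap="Blues")
    ax.set_xticks(range(data.shape[1]), data.columns, rotation=45)
    ax.set_yticks(range(data.shape[0]), data.index)
    fig.colorbar(im, ax=ax, label="-log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
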