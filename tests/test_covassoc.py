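"""PCA covariate attribution: variance shares, association p-values."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import helpmeth as hm
from helpmeth.covassoc import AssociationHeatmap


def _planted_matrix(share=0.6, n_sites=400, n=40, seed=0):
    rng = np.random.default_rng(seed)
    direction = rng.normal(size=n_sites)
    direction /= np.linalg.norm(direction)
    scores = rng.normal(size=n)
    noise = rng.normal(size=(n_sites, n))
    noise_var = noise.var()
    amp = np.sqrt(share / (1 - share) * noise_var * n_sites)
    X = amp * np.outer(direction, scores) + noise
    return pd.DataFrame(X, index=[f"s{i}" for i in range(n_sites)]), scores


def test_pc1_captures_planted_variance_share():
    meth, _ = _planted_matrix(share=0.6)
    res = hm.pca(meth, k=5)
    assert res.explained_variance_ratio[0] == pytest.approx(0.6, abs=0.1)
    assert np.all(np.diff(res.explained_variance_ratio) <= 1e-12)


def test_duplicated_samples_get_identical_scores():
    meth, _ = _planted_matrix()
    dup = pd.concat([meth, meth.add_suffix("_copy", axis=1)], axis=1)
    res = hm.pca(dup, k=3)
    a = res.scores.iloc[: meth.shape[1]].to_numpy()
    b = res.scores.iloc[meth.shape[1]:].to_numpy()
    assert np.allclose(a, b, atol=1e-8)


def test_scores_orthogonal():
    meth, _ = _planted_matrix(seed=3)
    res = hm.pca(meth, k=6)
    gram = res.scores.to_numpy().T @ res.scores.to_numpy()
    off = gram - np.diag(np.diag(gram))
    assert np.abs(off).max() < 1e-6 * np.abs(np.diag(gram)).max()


def test_k_larger_than_rank_rejected():
    meth, _ = _planted_matrix(n=10)
    with pytest.raises(ValueError):
        hm.pca(meth, k=11)


def test_covariate_equal_to_pc1_has_tiny_p():
    meth, scores = _planted_matrix(share=0.8, seed=5)
    res = hm.pca(meth, k=4)
    meta = pd.DataFrame({"v": res.scores["PC1"].to_numpy()}, index=res.scores.index)
    heat = hm.pc_covariate_matrix(res, meta)
    assert heat.pvalues.loc["v", "PC1"] < 1e-12
    assert heat.joint["v"] < 1e-12


def test_categorical_covariate_uses_anova_and_joint_test():
    meth, scores = _planted_matrix(share=0.8, seed=6)
    res = hm.pca(meth, k=4)
    lab = np.where(res.scores["PC1"] > res.scores["PC1"].median(), "a", "b")
    meta = pd.DataFrame({"lab": lab}, index=res.scores.index)
    heat = hm.pc_covariate_matrix(res, meta)
    assert heat.pvalues.loc["lab", "PC1"] < 1e-6
    assert heat.joint["lab"] < 1e-4


def test_single_level_covariate_skipped_with_warning():
    meth, _ = _planted_matrix(seed=7)
    res = hm.pca(meth, k=3)
    meta = pd.DataFrame({"c": ["x"] * meth.shape[1]}, index=res.scores.index)
    with pytest.warns(UserWarning, match="single level"):
        heat = hm.pc_covariate_matrix(res, meta)
    assert "c" not in heat.pvalues.index


def test_pvalues_invariant_to_affine_rescaling():
    meth, _ = _planted_matrix(seed=8)
    res = hm.pca(meth, k=4)
    rng = np.random.default_rng(1)
    cov = rng.normal(size=meth.shape[1])
    a = hm.pc_covariate_matrix(res, pd.DataFrame({"v": cov}, index=res.scores.index))
    b = hm.pc_covariate_matrix(
        res, pd.DataFrame({"v": 3.7 * cov - 11.0}, index=res.scores.index)
    )
    assert np.allclose(a.pvalues.to_numpy(), b.pvalues.to_numpy(), rtol=1e-8)
    assert a.joint["v"] == pytest.approx(b.joint["v"], rel=1e-8)


def test_independent_covariate_joint_p_uniform():
    """Null joint p over seeded replicates is uniform (KS)."""
    meth, _ = _planted_matrix(seed=9)
    res = hm.pca(meth, k=4)
    rng = np.random.default_rng(42)
    ps = []
    for _ in range(300):
        cov = rng.normal(size=meth.shape[1])
        heat = hm.pc_covariate_matrix(
            res, pd.DataFrame({"v": cov}, index=res.scores.index)
        )
        ps.append(heat.joint["v"])
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_batch_signal_drops_after_adjustment():
    cfg = hm.SimulationConfig(n_sites=1000, seed=21, mean_depth=5000,
                              hpaii_dispersion=1e-4, batch_shift_loc=10.0)
    c = hm.simulate_cohort(cfg)
    meth = hm.quantify(c.hpaii, c.mspi).dropna()
    meta = c.metadata

    def batch_minlogp(m):
        res = hm.pca(m, k=10)
        heat = hm.pc_covariate_matrix(res, meta[["batch"]].astype(str))
        return heat.neglog10.loc["batch"].max()

    adj, _ = hm.combat(meth, meta["batch"], protect=hm.group_design(meta["group"]))
    assert batch_minlogp(adj) < batch_minlogp(meth)


def test_batch_joint_p_nonsignificant_after_adjustment_across_seeds():
    """Joint batch association is null (p > 0.05) in >= 90% of seeded runs."""
    hits = 0
    seeds = range(10)
    for seed in seeds:
        cfg = hm.SimulationConfig(n_sites=600, seed=1000 + seed, mean_depth=5000,
                                  hpaii_dispersion=1e-4, batch_shift_loc=10.0)
        c = hm.simulate_cohort(cfg)
        meth = hm.quantify(c.hpaii, c.mspi).dropna()
        adj, _ = hm.combat(meth, c.metadata["batch"],
                           protect=hm.group_design(c.metadata["group"]))
        res = hm.pca(adj, k=10)
        heat = hm.pc_covariate_matrix(res, c.metadata[["batch"]].astype(str))
        if heat.joint["batch"] > 0.05:
            hits += 1
    assert hits >= 9
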