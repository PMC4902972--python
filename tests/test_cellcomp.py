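"""Cell-composition stage: DMR calling, reporter selection, pruning."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import comb

import helpmeth as hm


def _wgbs(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "meth", "total"]).assign(
        cell_type="x", replicate=1
    )


def test_dmr_fisher_closed_form_extreme_table():
    ae = _wgbs([("chr1", 100, 20, 20)])
    as_ = _wgbs([("chr1", 100, 0, 20)])
    res = hm.call_celltype_dmrs(ae, as_)
    expected = 2.0 / comb(40, 20, exact=True)
    assert res["p"].iloc[0] == pytest.approx(expected, rel=1e-9)
    assert res["is_dmr"].iloc[0]


def test_dmr_identical_proportions_not_called():
    ae = _wgbs([("chr1", 100, 10, 20)])
    as_ = _wgbs([("chr1", 100, 10, 20)])
    res = hm.call_celltype_dmrs(ae, as_)
    assert res["p"].iloc[0] == pytest.approx(1.0)
    assert not res["is_dmr"].iloc[0]


def test_depth_six_tables_can_never_reach_threshold():
    """Enumerate every 2x2 arrangement at per-type depth 6: min p >> 1e-5."""
    pmin = 1.0
    for a, b in itertools.product(range(7), repeat=2):
        p = stats.fisher_exact([[a, 6 - a], [b, 6 - b]])[1]
        pmin = min(pmin, p)
    assert pmin > 1e-5
    ae = _wgbs([("chr1", 100, 3, 6)])
    as_ = _wgbs([("chr1", 100, 3, 6)])
    assert not hm.call_celltype_dmrs(ae, as_)["is_dmr"].iloc[0]


def test_replicates_are_pooled_before_testing():
    ae = pd.concat([_wgbs([("chr1", 100, 10, 10)]).assign(replicate=r) for r in (1, 2)])
    as_ = pd.concat([_wgbs([("chr1", 100, 0, 10)]).assign(replicate=r) for r in (1, 2)])
    res = hm.call_celltype_dmrs(ae, as_)
    expected = 2.0 / comb(40, 20, exact=True)
    assert res["p"].iloc[0] == pytest.approx(expected, rel=1e-9)


def test_zero_coverage_cpgs_skipped():
    ae = _wgbs([("chr1", 100, 0, 0), ("chr1", 200, 5, 10)])
    as_ = _wgbs([("chr1", 100, 3, 5), ("chr1", 200, 5, 10)])
    res = hm.call_celltype_dmrs(ae, as_)
    assert list(res["pos"]) == [200]


def test_candidate_window_semantics():
    sites = pd.DataFrame(
        {"chrom": ["chr1", "chr1"], "pos": [100, 500]},
        index=pd.Index(["h1", "h2"], name="site_id"),
    )
    dmrs = pd.DataFrame({"chrom": ["chr1"], "pos": [105], "is_dmr": [True]})
    assert hm.candidates_at_hpaii(dmrs, sites, window=0) == []
    assert hm.candidates_at_hpaii(dmrs, sites, window=10) == ["h1"]
    exact = pd.DataFrame({"chrom": ["chr1"], "pos": [100], "is_dmr": [True]})
    assert hm.candidates_at_hpaii(exact, sites, window=0) == ["h1"]


def test_planted_dmr_sites_recovered_as_candidates(deep_cohort):
    dmrs = hm.call_celltype_dmrs(deep_cohort.wgbs_ae, deep_cohort.wgbs_as)
    cand = set(hm.candidates_at_hpaii(dmrs, deep_cohort.annotation.sites))
    truth = deep_cohort.truth.site_truth
    planted = set(truth.index[truth["celltype_dmr"]])
    assert len(planted & cand) / len(planted) >= 0.95


def test_reporter_selection_excludes_phenotype_confounded(deep_cohort, deep_meth):
    sites = deep_cohort.annotation.sites.loc[deep_meth.index]
    res = hm.composition_prune(
        deep_meth, sites, deep_cohort.wgbs_ae, deep_cohort.wgbs_as,
        deep_cohort.metadata,
    )
    truth = deep_cohort.truth.site_truth
    assert truth.loc[res.reporter, "celltype_dmr"]
    assert not truth.loc[res.reporter, "confounded"]
    confounded = truth.index[truth["confounded"]]
    in_cand = res.candidates.index.intersection(confounded)
    assert len(in_cand) > 0
    assert res.candidates.loc[in_cand, "excluded"].all()


def test_single_unconfounded_candidate_selected_trivially(deep_meth, deep_cohort):
    truth = deep_cohort.truth.site_truth
    sole = truth.index[truth["celltype_dmr"] & ~truth["confounded"]][0]
    table = hm.select_reporter([sole], deep_meth, deep_cohort.metadata)
    assert table.loc[sole, "selected"]


def test_all_candidates_confounded_aborts(deep_meth, deep_cohort):
    truth = deep_cohort.truth.site_truth
    conf = [s for s in truth.index[truth["confounded"]] if s in deep_meth.index]
    with pytest.raises(RuntimeError, match="not possible"):
        hm.select_reporter(conf, deep_meth, deep_cohort.metadata)


def test_prune_removes_reporter_and_correlated_sites(deep_meth):
    reporter = deep_meth.index[0]
    clone = deep_meth.copy()
    clone.loc["clone"] = clone.loc[reporter]  # identical profile, rho = 1
    retained, rho = hm.prune_correlated(clone, reporter)
    assert reporter not in retained
    assert "clone" not in retained
    assert rho.loc["clone"] == pytest.approx(1.0)
    post = rho.loc[retained].abs()
    assert (post <= 0.3).all()


def test_prune_retains_constant_site_with_warning(deep_meth):
    m = deep_meth.iloc[:50].copy()
    m.loc["flat"] = 42.0
    with pytest.warns(UserWarning, match="constant"):
        retained, rho = hm.prune_correlated(m, m.index[0])
    assert "flat" in retained
    assert np.isnan(rho.loc["flat"])


def test_null_site_survival_matches_permutation_null(rng):
    """Independent sites are pruned at about the null rate of |rho| > 0.3."""
    n = 62
    reporter = rng.normal(size=n)
    null_sites = rng.normal(size=(3000, n))
    m = pd.DataFrame(np.vstack([reporter, null_sites]),
                     index=["rep"] + [f"s{i}" for i in range(3000)])
    retained, _ = hm.prune_correlated(m, "rep")
    # permutation oracle for P(|rho| > 0.3) at n = 62
    perm = np.array([
        stats.spearmanr(reporter, rng.permutation(null_sites[i % 3000]))[0]
        for i in range(2000)
    ])
    p_null = (np.abs(perm) > 0.3).mean()
    survival = len(retained) / 3000
    assert survival == pytest.approx(1 - p_null, abs=0.02)


def test_composition_axis_attenuated_by_pruning():
    """With only a composition signal planted, pruning strips the PC1-pi link."""
    cfg = hm.SimulationConfig(n_sites=1200, seed=77, mean_depth=5000,
                              hpaii_dispersion=1e-4, batch_shift_loc=0.0,
                              n_dm_planted=0, n_var_planted=0, n_confounded_dmr=0)
    c = hm.simulate_cohort(cfg)
    meth = hm.quantify(c.hpaii, c.mspi).dropna()
    pi = c.truth.sample_truth["pi"].to_numpy()

    def pc1_corr(m):
        scores = hm.pca(m, k=2).scores["PC1"].to_numpy()
        return abs(np.corrcoef(scores, pi)[0, 1])

    truth = c.truth.site_truth
    reporter = [s for s in truth.index[truth["celltype_dmr"]] if s in meth.index][0]
    retained, _ = hm.prune_correlated(meth, reporter)
    pre, post = pc1_corr(meth), pc1_corr(meth.loc[retained])
    assert pre > 0.9
    # a weak coherent composition echo survives (per-sample normalisation
    # factors track pi), but the axis is clearly attenuated
    assert post < pre - 0.2
    # mixture consistency: reporter methylation tracks pi tightly
    assert abs(stats.spearmanr(meth.loc[reporter], pi)[0]) > 0.85
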