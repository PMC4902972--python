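"""Generator contracts: determinism, flag strata, planted-effect arithmetic."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import helpmeth as hm
from helpmeth.simulate import generate_annotation


def test_config_validation_rejects_bad_values():
    with pytest.raises(ValueError):
        hm.SimulationConfig(n_sites=0)
    with pytest.raises(ValueError):
        hm.SimulationConfig(frac_repeat=1.5)
    with pytest.raises(ValueError):
        hm.SimulationConfig(n_control=1)
    with pytest.raises(ValueError):
        hm.SimulationConfig(mean_depth=2)


def test_site_table_deterministic_and_fraction_controlled():
    cfg = hm.SimulationConfig(n_sites=1000, frac_repeat=0.1, seed=5)
    a = hm.generate_site_table(cfg)
    b = hm.generate_site_table(cfg)
    pd.testing.assert_frame_equal(a, b)
    # binomial 99% bounds for n=1000, p=0.1
    lo, hi = stats.binom.ppf([0.005, 0.995], 1000, 0.1)
    assert lo <= a["repeat"].sum() <= hi
    none = hm.generate_site_table(hm.SimulationConfig(n_sites=500, frac_snp_flank=0.0))
    assert not none["snp_flank"].any()


def test_annotation_intervals_consistent_with_flags():
    cfg = hm.SimulationConfig(n_sites=600, seed=3)
    ann = generate_annotation(cfg)
    reflagged = hm.flag_snp_flank(ann.sites, ann.snps, flank=28)
    assert (reflagged["snp_flank"] == ann.sites["snp_flank"]).all()
    rerep = hm.flag_repeats(ann.sites, ann.repeats)
    assert (rerep["repeat"] == ann.sites["repeat"]).all()


def test_metadata_matches_cohort_design():
    meta = hm.generate_metadata(hm.SimulationConfig())
    assert len(meta) == 62
    assert (meta["group"] == "pe").sum() == 36
    assert (meta.loc[meta["group"] != "pe", "proteinuria_grade"] == 0).all()
    assert (meta.loc[meta["group"] == "pe", "proteinuria_grade"] > 0).all()
    # group-wise SBP ordering: control < hypertension < PE on average
    means = meta.groupby("group")["maxSBP"].mean()
    assert means["control"] < means["hypertension"] < means["pe"]
    again = hm.generate_metadata(hm.SimulationConfig())
    pd.testing.assert_frame_equal(meta, again)


def test_truth_pure_mixture_endpoint_equals_ae_profile():
    cfg = hm.SimulationConfig(
        n_sites=300, n_dm_planted=0, n_var_planted=0, n_confounded_dmr=0,
        sd_within=0.0, batch_shift_loc=0.0, seed=7,
    )
    sites = hm.generate_site_table(cfg)
    meta = hm.generate_metadata(cfg)
    truth = hm.generate_truth(sites, meta, cfg, pi=np.ones(cfg.n_samples))
    expected = truth.site_truth["ae"].to_numpy()[:, None]
    assert np.allclose(truth.m_true.to_numpy(), expected)


def test_planted_sbp_effect_separates_groups_by_expected_delta():
    cfg = hm.SimulationConfig(n_sites=800, beta_sbp=0.5, sd_within=0.0,
                              batch_shift_loc=0.0, seed=9)
    sites = hm.generate_site_table(cfg)
    meta = hm.generate_metadata(cfg)
    truth = hm.generate_truth(sites, meta, cfg, pi=np.full(cfg.n_samples, 0.8))
    planted = truth.site_truth["dm_class"] == "sbp"
    is_pe = (meta["group"] == "pe").to_numpy()
    is_ctrl = (meta["group"] == "control").to_numpy()
    m = truth.m_true.to_numpy()[planted.to_numpy()]
    observed = m[:, is_pe].mean() - m[:, is_ctrl].mean()
    sbp_gap = meta.loc[is_pe, "maxSBP"].mean() - meta.loc[is_ctrl, "maxSBP"].mean()
    assert observed == pytest.approx(0.5 * sbp_gap, abs=0.5)


def test_variance_inflation_factor_recovered_over_replicates():
    ratios = []
    for seed in range(25):
        cfg = hm.SimulationConfig(n_sites=200, n_var_planted=10, n_dm_planted=0,
                                  n_celltype_dmr=0, n_confounded_dmr=0,
                                  var_inflation=25.0, sd_within=2.0,
                                  batch_shift_loc=0.0, seed=seed)
        sites = hm.generate_site_table(cfg)
        meta = hm.generate_metadata(cfg)
        truth = hm.generate_truth(sites, meta, cfg, pi=np.full(cfg.n_samples, 0.8))
        v = truth.site_truth["var_flag"].to_numpy()
        m = truth.m_true.to_numpy()[v]
        is_pe = (meta["group"] == "pe").to_numpy()
        is_ctrl = (meta["group"] == "control").to_numpy()
        ratios.append(m[:, is_pe].var(ddof=1, axis=1).mean()
                      / m[:, is_ctrl].var(ddof=1, axis=1).mean())
    assert np.mean(ratios) == pytest.approx(25.0, rel=0.2)


def test_fully_methylated_sites_draw_zero_hpaii_counts():
    cfg = hm.SimulationConfig(n_sites=100, sd_within=0.0, n_dm_planted=0,
                              n_var_planted=0, n_celltype_dmr=0,
                              n_confounded_dmr=0, batch_shift_loc=0.0, seed=2)
    sites = hm.generate_site_table(cfg)
    meta = hm.generate_metadata(cfg)
    truth = hm.generate_truth(sites, meta, cfg, pi=np.full(cfg.n_samples, 1.0))
    truth.m_true.iloc[:, :] = 100.0
    hpaii, _ = hm.generate_tag_counts(truth, cfg)
    assert (hpaii.to_numpy() == 0).all()


def test_tag_count_round_trip_recovers_methylation(deep_cohort, deep_meth):
    m = deep_meth.to_numpy()
    t = deep_cohort.truth.m_true.loc[deep_meth.index].to_numpy()
    assert abs((m - t).mean()) < 3.0
    # specifically around the intermediate band used by the spec examples
    band = (t.mean(axis=1) > 45) & (t.mean(axis=1) < 55)
    if band.any():
        assert abs((m[band] - t[band]).mean()) < 3.0


def test_wgbs_counts_deterministic_and_bounded(deep_cohort, deep_config):
    import copy

    ae, as_ = hm.generate_wgbs_counts(deep_cohort.truth, config=deep_config)
    ae2, _ = hm.generate_wgbs_counts(deep_cohort.truth, config=deep_config)
    pd.testing.assert_frame_equal(ae, ae2)
    assert (ae["meth"] <= ae["total"]).all()
    # a fully unmethylated cell profile never yields methylated reads
    truth = hm.TruthTable(
        site_truth=deep_cohort.truth.site_truth.copy(),
        sample_truth=deep_cohort.truth.sample_truth,
        m_true=deep_cohort.truth.m_true,
    )
    truth.site_truth.loc[truth.site_truth.index[0], "ae"] = 0.0
    ae3, _ = hm.generate_wgbs_counts(truth, config=deep_config)
    first = truth.site_truth.iloc[0]
    sel = (ae3["chrom"] == first["chrom"]) & (ae3["pos"] == first["pos"])
    assert (ae3.loc[sel, "meth"] == 0).all()


def test_same_seed_reproduces_counts(deep_config, deep_cohort):
    again = hm.simulate_cohort(deep_config)
    pd.testing.assert_frame_equal(again.hpaii, deep_cohort.hpaii)
    pd.testing.assert_series_equal(again.mspi, deep_cohort.mspi)
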