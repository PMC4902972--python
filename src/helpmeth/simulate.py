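"""Synthetic amnion methylation cohort generator.

Produces every input the analysis pipeline consumes: site annotation with
SNP/repeat/sex-chromosome strata, cohort metadata emulating the published
group summaries, a two-cell-type ground-truth methylation mixture with
planted covariate effects, HpaII/MspI tag counts around the angle-metric
expectation, and bisulfite read counts for purified amniotic epithelial
(AE) and stromal (AS) isolates.  A truth table records every planted
effect for parameter-recovery tests.

The baseline methylome is a three-component mixture (lowly methylated
CpG-island-like loci, intermediate loci, highly methylated loci).  The
component weights are fixed so that the methylome-wide mean of
``tan((1 - m/100) * pi/2)`` is 1, which makes the counts-per-million
normalised HpaII/MspI signal ratio calibrated: at high depth the angle
score recovers the true methylation level without bias (the angle
transform is the exact inverse of the tan link used for the expected
HpaII signal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimulationConfig

# Mixture of baseline methylation levels: U(12,30), U(30,70), U(70,90)
# with weights solved so E[tan((1-m/100)*pi/2)] = 1 under the default
# within-group noise (sd 4) -- i.e. the library-composition factor is ~1
# and CPM-normalised angle scores are calibrated (see module docstring).
# Roughly 17% unmethylated, 20% intermediate, 63% methylated: the
# genome-typical bimodal picture.  Component bounds keep >=2.5 sd of
# headroom to the score boundaries so the Gaussian within-group noise is
# effectively uncensored by the [0, 100] clip.
_BASELINE_COMPONENTS = ((12.0, 30.0), (30.0, 70.0), (70.0, 90.0))
_BASELINE_WEIGHTS = (0.17117184, 0.2, 0.62882816)

# Distinct sub-streams per generator stage so each stage is reproducible
# in isolation from the single config seed.
_STAGE = {"annotation": 0, "metadata": 1, "truth": 2, "counts": 3, "wgbs": 4}

_SITE_SPACING = 2000
_SITE_JITTER = 1000
_GENE_LENGTH = 20000
_GENE_PERIOD = 50000

# Per-group clinical distributions emulating the published cohort
# summaries (maximum systolic/diastolic BP medians and IQRs; PE
# proteinuria grades 1+/2+/>=3+ in proportions 13:8:9).
_CLINICAL = {
    "control": dict(sbp=(129.0, 9.0), dbp=(81.0, 6.0), week=(39.6, 0.8),
                    weight=(3454.0, 400.0), sex=5 / 15, primiparous=3 / 15,
                    smoked=0.0, history_pe=0.0, mgso4=0.0, anemia=4 / 15,
                    obese=4 / 15),
    "hypertension": dict(sbp=(159.0, 16.0), dbp=(100.0, 10.0), week=(38.6, 1.4),
                         weight=(3097.0, 607.0), sex=8 / 11, primiparous=6 / 11,
                         smoked=0.0, history_pe=2 / 11, mgso4=6 / 11,
                         anemia=1 / 11, obese=4 / 11),
    "pe": dict(sbp=(172.0, 17.0), dbp=(106.0, 12.0), week=(38.4, 1.5),
               weight=(2931.0, 767.0), sex=15 / 36, primiparous=24 / 36,
               smoked=2 / 36, history_pe=5 / 36, mgso4=25 / 36,
               anemia=5 / 36, obese=17 / 36),
}
_PE_GRADE_P = np.array([13.0, 8.0, 9.0]) / 30.0  # grades 1, 2, 3


def _rng(config: SimulationConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng([_STAGE[stage], config.seed])


@dataclass
class SyntheticAnnotation:
    """Site table plus the interval inputs consistent with its flags."""

    sites: pd.DataFrame
    snps: pd.DataFrame
    repeats: pd.DataFrame
    genes: pd.DataFrame


@dataclass
class TruthTable:
    """Ground truth of a simulated cohort.

    ``site_truth`` has one row per site (AE/AS levels, planted-effect
    class, variance and cell-type-DMR flags); ``sample_truth`` has one
    row per sample (true AE fraction ``pi`` and batch); ``m_true`` is the
    sites x samples matrix of per-sample methylation after effects,
    noise and batch distortion, clipped to [0, 100].
    """

    site_truth: pd.DataFrame
    sample_truth: pd.DataFrame
    m_true: pd.DataFrame


@dataclass
class SimulatedCohort:
    annotation: SyntheticAnnotation
    metadata: pd.DataFrame
    truth: TruthTable
    hpaii: pd.DataFrame
    mspi: pd.Series
    wgbs_ae: pd.DataFrame
    wgbs_as: pd.DataFrame
    config: SimulationConfig = field(repr=False, default=None)


def generate_annotation(config: SimulationConfig) -> SyntheticAnnotation:
    """Generate the site table together with SNP/repeat/gene intervals.

    Sites are spaced >= 1 kb apart so a SNP planted inside one site's
    +/-28 bp window can never flag a neighbour; every flag stratum is
    therefore independently exercisable downstream.
    """
    config.validate()
    rng = _rng(config, "annotation")
    n = config.n_sites

    sex = rng.random(n) < config.frac_sex_chrom
    n_auto_chrom = 4
    chrom = np.where(sex, "chrX", "")
    auto_idx = np.flatnonzero(~sex)
    chrom[auto_idx] = [f"chr{1 + i % n_auto_chrom}" for i in range(auto_idx.size)]

    pos = np.zeros(n, dtype=np.int64)
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        pos[idx] = (
            _SITE_SPACING * (1 + np.arange(idx.size))
            + rng.integers(0, _SITE_JITTER, idx.size)
        )

    snp_flank = rng.random(n) < config.frac_snp_flank
    repeat = rng.random(n) < config.frac_repeat

    sites = pd.DataFrame(
        {
            "site_id": [f"Hpa_{i:07d}" for i in range(1, n + 1)],
            "chrom": chrom,
            "pos": pos,
            "snp_flank": snp_flank,
            "repeat": repeat,
        }
    ).set_index("site_id")

    # SNPs: one inside the window of every flagged site; decoys just
    # outside the window for a tenth of the unflagged sites.
    snp_rows = []
    for sid, row in sites[sites.snp_flank].iterrows():
        snp_rows.append((row.chrom, int(row.pos) + int(rng.integers(-28, 29))))
    decoys = sites[~sites.snp_flank].sample(
        frac=0.1, random_state=int(rng.integers(2**31))
    )
    for sid, row in decoys.iterrows():
        snp_rows.append((row.chrom, int(row.pos) + 29 + int(rng.integers(0, 50))))
    snps = pd.DataFrame(snp_rows, columns=["chrom", "pos"]).sort_values(
        ["chrom", "pos"], ignore_index=True
    )

    # Repeats: half-open intervals containing flagged positions; decoy
    # intervals that start just past unflagged positions.
    rep_rows = []
    for sid, row in sites[sites["repeat"]].iterrows():
        rep_rows.append((row.chrom, int(row.pos) - 10, int(row.pos) + 11))
    decoys = sites[~sites["repeat"]].sample(
        frac=0.05, random_state=int(rng.integers(2**31))
    )
    for sid, row in decoys.iterrows():
        rep_rows.append((row.chrom, int(row.pos) + 30, int(row.pos) + 60))
    repeats = pd.DataFrame(
        rep_rows, columns=["chrom", "start", "end"]
    ).sort_values(["chrom", "start"], ignore_index=True)

    # Genes: 20-kb intervals tiled every 50 kb along each chromosome.
    gene_rows = []
    g = 0
    for c in sorted(np.unique(chrom)):
        span = int(pos[chrom == c].max()) + _GENE_PERIOD
        for start in range(10_000, span, _GENE_PERIOD):
            g += 1
            gene_rows.append((c, start, start + _GENE_LENGTH, f"gene_{g:04d}"))
    genes = pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "gene_id"])

    return SyntheticAnnotation(sites=sites, snps=snps, repeats=repeats, genes=genes)


def generate_site_table(config: SimulationConfig) -> pd.DataFrame:
    """Site table only (see :func:`generate_annotation` for intervals)."""
    return generate_annotation(config).sites


def generate_metadata(config: SimulationConfig) -> pd.DataFrame:
    """One row per sample: group, blood pressure, proteinuria, batch, covariates.

    Proteinuria is 0 for control/hypertension samples; every PE sample
    draws a positive grade (1/2/3 with probabilities 13/30, 8/30, 9/30).
    Batches are assigned round-robin within group so batch is balanced
    against the outcome.
    """
    config.validate()
    rng = _rng(config, "metadata")
    rows = []
    counts = [
        ("control", config.n_control),
        ("hypertension", config.n_htn),
        ("pe", config.n_pe),
    ]
    i = 0
    for group, n_g in counts:
        c = _CLINICAL[group]
        for j in range(n_g):
            i += 1
            grade = 0
            if group == "pe":
                grade = int(rng.choice([1, 2, 3], p=_PE_GRADE_P))
            rows.append(
                {
                    "sample_id": f"S{i:03d}",
                    "group": group,
                    "maxSBP": float(np.round(rng.normal(*c["sbp"]))),
                    "maxDBP": float(np.round(rng.normal(*c["dbp"]))),
                    "proteinuria_grade": grade,
                    "batch": j % config.n_batches,
                    "sex": "male" if rng.random() < c["sex"] else "female",
                    "primiparous": bool(rng.random() < c["primiparous"]),
                    "smoked": bool(rng.random() < c["smoked"]),
                    "history_pe": bool(rng.random() < c["history_pe"]),
                    "mgso4": bool(rng.random() < c["mgso4"]),
                    "anemia": bool(rng.random() < c["anemia"]),
                    "obese": bool(rng.random() < c["obese"]),
                    "maternal_age": float(np.round(rng.normal(26.8, 5.5), 1)),
                    "gestational_week": float(np.round(rng.normal(*c["week"]), 1)),
                    "birth_weight": float(np.round(rng.normal(*c["weight"]))),
                }
            )
    meta = pd.DataFrame(rows).set_index("sample_id")
    meta["maxSBP"] = meta["maxSBP"].clip(90, 260)
    meta["maxDBP"] = meta["maxDBP"].clip(50, 160)
    return meta


def _draw_baseline(rng: np.random.Generator, n: int) -> np.ndarray:
    comp = rng.choice(len(_BASELINE_COMPONENTS), size=n, p=_BASELINE_WEIGHTS)
    lo = np.array([c[0] for c in _BASELINE_COMPONENTS])[comp]
    hi = np.array([c[1] for c in _BASELINE_COMPONENTS])[comp]
    return rng.uniform(lo, hi)


def generate_truth(
    sites: pd.DataFrame,
    meta: pd.DataFrame,
    config: SimulationConfig,
    pi: np.ndarray | None = None,
) -> TruthTable:
    """Plant the two-cell-type mixture, covariate effects, noise and batches.

    Per-sample truth at site i is ``pi_s * AE_i + (1 - pi_s) * AS_i``
    plus covariate-linear shifts at planted loci, then per-sample
    biological noise (inflated ``var_inflation``-fold for PE samples at
    variance-planted loci) scaled by the batch scale factor, plus the
    batch location offset; finally clipped to [0, 100].

    Parameters
    ----------
    pi : array of float, optional
        Override the per-sample AE fraction (default Beta(8, 2), the
        epithelium-dominant composition of the amnion).
    """
    if sites.shape[0] != config.n_sites:
        raise ValueError("site table size does not match config.n_sites")
    if meta.shape[0] != config.n_samples:
        raise ValueError("metadata size does not match config cohort sizes")
    rng = _rng(config, "truth")
    n, s = config.n_sites, config.n_samples

    baseline = _draw_baseline(rng, n)

    eligible = np.flatnonzero(
        (~sites["snp_flank"].to_numpy())
        & (~sites["repeat"].to_numpy())
        & (~sites["chrom"].isin(["chrX", "chrY", "X", "Y"]).to_numpy())
    )
    need = config.n_celltype_dmr + 3 * config.n_dm_planted + config.n_var_planted
    if eligible.size < need:
        raise ValueError(
            f"only {eligible.size} filter-clean sites but {need} planted loci requested"
        )
    chosen = rng.choice(eligible, size=need, replace=False)
    k = config.n_celltype_dmr
    dmr_idx = chosen[:k]
    sbp_idx = chosen[k : k + config.n_dm_planted]
    prot_idx = chosen[k + config.n_dm_planted : k + 2 * config.n_dm_planted]
    both_idx = chosen[k + 2 * config.n_dm_planted : k + 3 * config.n_dm_planted]
    var_idx = chosen[k + 3 * config.n_dm_planted :]

    ae = baseline.copy()
    as_ = baseline.copy()
    # Planted DM / variance loci start from intermediate methylation so
    # the effect headroom stays inside [0, 100].
    for idx, lo, hi in ((sbp_idx, 35, 60), (prot_idx, 35, 60),
                        (both_idx, 30, 55), (var_idx, 35, 65)):
        if idx.size:
            mid = rng.uniform(lo, hi, idx.size)
            ae[idx] = mid
            as_[idx] = mid
    # Cell-type DMRs: AE/AS discordant in both directions.
    half = k // 2
    ae[dmr_idx[:half]], as_[dmr_idx[:half]] = 85.0, 15.0
    ae[dmr_idx[half:]], as_[dmr_idx[half:]] = 15.0, 85.0

    dm_class = np.full(n, "none", dtype=object)
    dm_class[sbp_idx] = "sbp"
    dm_class[prot_idx] = "prot"
    dm_class[both_idx] = "both"
    confounded = np.zeros(n, dtype=bool)
    confounded[dmr_idx[: config.n_confounded_dmr]] = True
    var_flag = np.zeros(n, dtype=bool)
    var_flag[var_idx] = True
    celltype_dmr = np.zeros(n, dtype=bool)
    celltype_dmr[dmr_idx] = True

    if pi is None:
        pi = rng.beta(8.0, 2.0, size=s)
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (s,) or pi.min() < 0 or pi.max() > 1:
        raise ValueError("pi must be one fraction in [0, 1] per sample")

    m = np.outer(ae, pi) + np.outer(as_, 1.0 - pi)  # sites x samples

    sbp = meta["maxSBP"].to_numpy(float)
    grade = meta["proteinuria_grade"].to_numpy(float)
    is_pe = (meta["group"] == "pe").to_numpy()

    sbp_effect = config.beta_sbp * (sbp - 130.0)
    prot_effect = config.delta_proteinuria * grade
    m[sbp_idx] += sbp_effect
    m[prot_idx] += prot_effect
    m[both_idx] += sbp_effect + prot_effect
    m[confounded] += prot_effect

    sd = np.full((n, s), config.sd_within)
    sd[np.ix_(var_idx, np.flatnonzero(is_pe))] *= np.sqrt(config.var_inflation)
    eps = rng.standard_normal((n, s)) * sd

    batch = meta["batch"].to_numpy(int)
    if config.n_batches > 1:
        frac = batch / (config.n_batches - 1) - 0.5
        loc = config.batch_shift_loc * frac
        scale = np.power(config.batch_shift_scale, frac)
    else:
        loc = np.zeros(s)
        scale = np.ones(s)
    m = m + loc[None, :] + eps * scale[None, :]
    np.clip(m, 0.0, 100.0, out=m)

    site_truth = pd.DataFrame(
        {
            "chrom": sites["chrom"].to_numpy(),
            "pos": sites["pos"].to_numpy(),
            "ae": ae,
            "as_": as_,
            "celltype_dmr": celltype_dmr,
            "confounded": confounded,
            "dm_class": dm_class,
            "var_flag": var_flag,
        },
        index=sites.index,
    )
    sample_truth = pd.DataFrame({"pi": pi, "batch": batch}, index=meta.index)
    m_true = pd.DataFrame(m, index=sites.index, columns=meta.index)
    return TruthTable(site_truth=site_truth, sample_truth=sample_truth, m_true=m_true)


def generate_tag_counts(
    truth: TruthTable, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.Series]:
    """Draw HpaII (per sample) and pooled-reference MspI tag counts.

    The MspI reference is Poisson around ``mean_depth`` times a
    log-normal site weight (one pooled library shared by every sample).
    The expected HpaII count follows the tan link
    ``weight * depth * library_factor * tan((1 - m/100) * pi/2)`` so the
    angle transform inverts it exactly; counts are negative binomial
    with dispersion ``hpaii_dispersion`` (Poisson in the zero-dispersion
    limit).  A fully methylated site (m = 100) yields HpaII counts of 0.
    """
    rng = _rng(config, "counts")
    m = truth.m_true.to_numpy()
    n, s = m.shape

    w = rng.lognormal(mean=0.0, sigma=0.5, size=n)
    mspi = rng.poisson(w * config.mean_depth)

    u = np.clip(1.0 - m / 100.0, 0.0, 0.995)
    t = np.tan(u * np.pi / 2.0)
    lib = rng.lognormal(mean=0.0, sigma=0.2, size=s)
    mu = w[:, None] * config.mean_depth * t * lib[None, :]

    if config.hpaii_dispersion < 1e-8:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / config.hpaii_dispersion
        with np.errstate(divide="ignore", invalid="ignore"):
            p = r / (r + mu)
        counts = np.where(mu > 0, rng.negative_binomial(r, np.clip(p, 1e-12, 1.0)), 0)

    hpaii = pd.DataFrame(counts, index=truth.m_true.index, columns=truth.m_true.columns)
    mspi = pd.Series(mspi, index=truth.m_true.index, name="mspi")
    return hpaii, mspi


def generate_wgbs_counts(
    truth: TruthTable,
    n_replicates: int | None = None,
    depth: float | None = None,
    config: SimulationConfig | None = None,
    seed: int = 4,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bisulfite read counts for purified AE and AS cell isolates.

    Per CpG (one per HpaII site) and replicate, the total read count is
    Poisson with the given mean depth and the methylated count is
    binomial with the cell type's true methylation fraction.
    """
    if config is not None:
        n_replicates = n_replicates or config.wgbs_replicates
        depth = depth or config.wgbs_depth
        rng = _rng(config, "wgbs")
    else:
        rng = np.random.default_rng([_STAGE["wgbs"], seed])
    n_replicates = int(n_replicates or 5)
    depth = float(depth if depth is not None else 10.0)
    if depth <= 0:
        raise ValueError("depth must be positive")

    out = []
    for cell, level in (("AE", truth.site_truth["ae"]), ("AS", truth.site_truth["as_"])):
        frames = []
        for rep in range(1, n_replicates + 1):
            total = rng.poisson(depth, size=level.size)
            meth = rng.binomial(total, level.to_numpy() / 100.0)
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": truth.site_truth["chrom"].to_numpy(),
                        "pos": truth.site_truth["pos"].to_numpy(),
                        "cell_type": cell,
                        "replicate": rep,
                        "meth": meth,
                        "total": total,
                    }
                )
            )
        out.append(pd.concat(frames, ignore_index=True))
    return out[0], out[1]


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Run every generator stage and bundle the results."""
    annotation = generate_annotation(config)
    metadata = generate_metadata(config)
    truth = generate_truth(annotation.sites, metadata, config)
    hpaii, mspi = generate_tag_counts(truth, config)
    wgbs_ae, wgbs_as = generate_wgbs_counts(truth, config=config)
    return SimulatedCohort(
        annotation=annotation,
        metadata=metadata,
        truth=truth,
        hpaii=hpaii,
        mspi=mspi,
        wgbs_ae=wgbs_ae,
        wgbs_as=wgbs_as,
        config=config,
    )
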