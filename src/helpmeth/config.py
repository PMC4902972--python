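"""Configuration objects for the simulator and the analysis pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml


@dataclass
class SimulationConfig:
    """Parameters of the synthetic amnion methylation cohort.

    The cohort layout (15 control / 11 hypertension / 36 preeclampsia
    samples) mirrors the study design the package analyses; blood-pressure
    and proteinuria distributions are drawn to match the published group
    summaries.  Effect sizes (``beta_sbp``, ``delta_proteinuria``,
    ``var_inflation``) are simulation parameters on the 0-100 methylation
    score scale.

    Parameters
    ----------
    n_sites : int
        Number of HpaII sites to simulate.
    n_control, n_htn, n_pe : int
        Group sizes (control / hypertension-only / preeclampsia).
    frac_snp_flank, frac_repeat, frac_sex_chrom : float
        Fractions of sites carrying each exclusion flag.
    n_celltype_dmr : int
        Number of loci discordant between amniotic epithelial (AE) and
        stromal (AS) cells; these carry the cell-composition signal.
    n_confounded_dmr : int
        Of the cell-type DMRs, how many additionally carry a proteinuria
        effect (phenotype-confounded reporter candidates).
    n_dm_planted : int
        Number of differentially methylated loci planted *per* responsive
        class (systolic-BP-responsive, proteinuria-responsive, and
        both-responsive).
    n_var_planted : int
        Number of loci with inflated within-PE-group variance.
    beta_sbp : float
        Score change per mmHg of maximum systolic blood pressure at
        SBP-responsive loci.
    delta_proteinuria : float
        Score change per ordinal proteinuria grade (0-3).
    var_inflation : float
        Multiplicative variance factor for PE samples at variance-planted
        loci.
    sd_within : float
        Within-group biological standard deviation of the methylation
        score at every locus (score units).
    n_batches : int
        Number of processing batches.
    batch_shift_loc, batch_shift_scale : float
        Additive location offset (score units, total spread between the
        extreme batches) and multiplicative scale ratio between batches.
    mean_depth : float
        Expected MspI reference tag count per unit site weight.
    hpaii_dispersion : float
        Negative-binomial dispersion of HpaII tag counts (variance =
        mu + dispersion * mu^2); values below 1e-8 fall back to Poisson.
    wgbs_depth : float
        Expected per-CpG read depth of each bisulfite replicate.
    wgbs_replicates : int
        Replicates per purified cell type.
    seed : int
        Seed for all randomness in the generator.
    """

    n_sites: int = 5000
    n_control: int = 15
    n_htn: int = 11
    n_pe: int = 36
    frac_snp_flank: float = 0.05
    frac_repeat: float = 0.10
    frac_sex_chrom: float = 0.05
    n_celltype_dmr: int = 150
    n_confounded_dmr: int = 1
    n_dm_planted: int = 40
    n_var_planted: int = 40
    beta_sbp: float = 0.4
    delta_proteinuria: float = 6.0
    var_inflation: float = 25.0
    sd_within: float = 4.0
    n_batches: int = 2
    batch_shift_loc: float = 10.0
    batch_shift_scale: float = 1.0
    mean_depth: float = 50.0
    hpaii_dispersion: float = 0.05
    wgbs_depth: float = 10.0
    wgbs_replicates: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_sites <= 0:
            raise ValueError("n_sites must be positive")
        for name in ("frac_snp_flank", "frac_repeat", "frac_sex_chrom"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("n_control", "n_htn", "n_pe"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2 so variances are estimable")
        if self.mean_depth < 4:
            raise ValueError("mean_depth must be >= 4")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")
        if self.var_inflation <= 0 or self.sd_within < 0:
            raise ValueError("variance parameters must be positive")

    @property
    def n_samples(self) -> int:
        return self.n_control + self.n_htn + self.n_pe

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class PipelineConfig:
    """Stage parameters and input paths for a full analysis run.

    Defaults are the thresholds used throughout the analysis: a 28-bp
    SNP-exclusion flank, an MspI floor of 4 tags, a Spearman pruning
    threshold of 0.3, FDR 0.05 with a 10-unit effect gate for
    differential methylation, and an FDR of 1e-7 with a 20-fold ratio
    gate for the variance screen.
    """

    hpaii: Optional[str] = None
    mspi: Optional[str] = None
    sites: Optional[str] = None
    snps: Optional[str] = None
    repeats: Optional[str] = None
    genes: Optional[str] = None
    metadata: Optional[str] = None
    wgbs_ae: Optional[str] = None
    wgbs_as: Optional[str] = None
    outdir: str = "helpmeth_run"

    flank: int = 28
    min_mspi: int = 4
    rho_threshold: float = 0.3
    pheno_alpha: float = 0.01
    dmr_p: float = 1e-5
    candidate_window: int = 0
    n_pcs: int = 10
    fdr: float = 0.05
    delta: float = 10.0
    var_q: float = 1e-7
    var_ratio: float = 20.0
    gene_window: int = 50000
    seed: int = 0

    def validate(self) -> None:
        for name in ("fdr", "delta", "var_q", "var_ratio", "rho_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.flank < 0 or self.gene_window < 0 or self.candidate_window < 0:
            raise ValueError("windows must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)
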