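"""Readers and writers for the pipeline's plain-text formats.

Conventions: coordinates are 0-based half-open (BED native); count and
methylation matrices are stored sites-as-rows, samples-as-columns TSV
keyed by ``site_id``; bisulfite counts use the Bismark coverage layout
(chrom, start, end, percent methylated, methylated count, unmethylated
count).  Write-then-read round-trips are exact for integers and within
1e-12 for reals.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


class ParseError(ValueError):
    def __init__(self, path, lineno, msg):
        super().__init__(f"{path}:{lineno}: {msg}")


def read_bed(path) -> pd.DataFrame:
    """BED (3+ columns, half-open). Returns chrom/start/end (+name if present)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(path, lineno, "BED needs >=3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError(path, lineno, "non-integer coordinates")
            if start < 0 or end < start:
                raise ParseError(path, lineno, f"bad interval [{start}, {end})")
            rows.append((parts[0], start, end, parts[3] if len(parts) > 3 else None))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    if df["name"].isna().all():
        df = df.drop(columns="name")
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = ["chrom", "start", "end"] + (["name"] if "name" in df.columns else [])
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_positions_bed(path) -> pd.DataFrame:
    """Single-base BED (e.g. SNPs): returns chrom/pos with pos = start."""
    bed = read_bed(path)
    return pd.DataFrame({"chrom": bed["chrom"], "pos": bed["start"]})


def write_positions_bed(df: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {"chrom": df["chrom"], "start": df["pos"], "end": df["pos"] + 1}
    )
    write_bed(out, path)


def read_genes_bed(path) -> pd.DataFrame:
    bed = read_bed(path)
    if "name" not in bed.columns:
        raise ValueError("gene BED needs a 4th (name) column")
    return bed.rename(columns={"name": "gene_id"})


def write_genes_bed(df: pd.DataFrame, path) -> None:
    write_bed(df.rename(columns={"gene_id": "name"}), path)


def read_site_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="site_id")
    for col in ("snp_flank", "repeat"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df


def write_site_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=True, index_label="site_id")


def read_matrix_tsv(path) -> pd.DataFrame:
    """Sites x samples matrix keyed by site_id."""
    return pd.read_csv(path, sep="\t", index_col="site_id")


def write_matrix_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=True, index_label="site_id")


def read_mspi_tsv(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col="site_id")
    return df.iloc[:, 0].rename("mspi")


def write_mspi_tsv(s: pd.Series, path) -> None:
    s.rename("mspi").to_frame().to_csv(path, sep="\t", index_label="site_id")


def read_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="sample_id")


def write_metadata(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index_label="sample_id")


def read_coverage(path) -> pd.DataFrame:
    """Bismark-coverage-style TSV -> per-CpG counts.

    Columns: chrom, start, end, percent methylated, methylated count,
    unmethylated count.  Zero-coverage rows are parsed and flagged via
    ``total == 0``.  A ``replicate`` column may follow the standard six.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(path, lineno, "coverage rows need >=6 columns")
            try:
                meth, unmeth = int(parts[4]), int(parts[5])
                rows.append(
                    (
                        parts[0],
                        int(parts[1]),
                        meth,
                        meth + unmeth,
                        int(parts[6]) if len(parts) > 6 else 1,
                    )
                )
            except ValueError:
                raise ParseError(path, lineno, "malformed coverage row")
    return pd.DataFrame(rows, columns=["chrom", "pos", "meth", "total", "replicate"])


def write_coverage(df: pd.DataFrame, path) -> None:
    total = df["total"].to_numpy()
    meth = df["meth"].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(total > 0, 100.0 * meth / np.maximum(total, 1), 0.0)
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["pos"],
            "end": df["pos"] + 1,
            "pct": np.round(pct, 6),
            "meth": meth,
            "unmeth": total - meth,
            "replicate": df.get("replicate", 1),
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def write_cohort(cohort, outdir) -> dict[str, str]:
    """Write every simulated input to ``outdir``; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ann, truth = cohort.annotation, cohort.truth
    paths = {
        "sites": outdir / "sites.tsv",
        "snps": outdir / "snps.bed",
        "repeats": outdir / "repeats.bed",
        "genes": outdir / "genes.bed",
        "hpaii": outdir / "hpaii_counts.tsv",
        "mspi": outdir / "mspi_counts.tsv",
        "metadata": outdir / "metadata.csv",
        "wgbs_ae": outdir / "wgbs_AE.cov.tsv",
        "wgbs_as": outdir / "wgbs_AS.cov.tsv",
        "truth_sites": outdir / "truth_sites.tsv",
        "truth_samples": outdir / "truth_samples.tsv",
    }
    write_site_table(ann.sites, paths["sites"])
    write_positions_bed(ann.snps, paths["snps"])
    write_bed(ann.repeats, paths["repeats"])
    write_genes_bed(ann.genes, paths["genes"])
    write_matrix_tsv(cohort.hpaii, paths["hpaii"])
    write_mspi_tsv(cohort.mspi, paths["mspi"])
    write_metadata(cohort.metadata, paths["metadata"])
    write_coverage(cohort.wgbs_ae, paths["wgbs_ae"])
    write_coverage(cohort.wgbs_as, paths["wgbs_as"])
    write_site_table(truth.site_truth, paths["truth_sites"])
    truth.sample_truth.to_csv(paths["truth_samples"], sep="\t", index_label="sample_id")
    return {k: str(v) for k, v in paths.items()}
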