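"""Conservative locus exclusions: SNP flanks, low MspI, sex chromosomes, repeats.

Coordinates are 0-based.  The SNP flank window is closed on both ends
(a SNP exactly 28 bp away flags the site); repeat intervals use
half-open BED semantics (a site at ``end`` is outside the repeat).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

SEX_CHROMS = frozenset({"chrX", "chrY", "X", "Y"})


@dataclass
class FilterReport:
    """Per-rule exclusion accounting.

    ``removed_any`` counts sites failing at least one rule, so
    ``retained + removed_any`` equals the input size; per-rule columns
    each count a doubly-failing site once.
    """

    n_input: int
    removed_snp_flank: int
    removed_low_mspi: int
    removed_sex_chrom: int
    removed_repeat: int
    removed_any: int
    retained: int

    def to_dict(self) -> dict:
        return asdict(self)


def flag_snp_flank(
    sites: pd.DataFrame, snps: pd.DataFrame, flank: int = 28
) -> pd.DataFrame:
    """Flag sites with a SNP within ``flank`` bp (inclusive both ends).

    ``snps`` needs ``chrom`` and ``pos`` columns.  Returns a copy of the
    site table with the ``snp_flank`` column recomputed.
    """
    if flank < 0:
        raise ValueError("flank must be non-negative")
    out = sites.copy()
    flags = np.zeros(len(sites), dtype=bool)
    pos = sites["pos"].to_numpy(np.int64)
    for c, sub in snps.groupby("chrom"):
        mask = (sites["chrom"] == c).to_numpy()
        if not mask.any():
            continue
        sp = np.sort(sub["pos"].to_numpy(np.int64))
        p = pos[mask]
        lo = np.searchsorted(sp, p - flank, side="left")
        hi = np.searchsorted(sp, p + flank, side="right")
        flags[mask] = hi > lo
    out["snp_flank"] = flags
    return out


def flag_repeats(sites: pd.DataFrame, repeats: pd.DataFrame) -> pd.DataFrame:
    """Flag sites whose position falls inside any half-open repeat interval."""
    out = sites.copy()
    flags = np.zeros(len(sites), dtype=bool)
    pos = sites["pos"].to_numpy(np.int64)
    for c, sub in repeats.groupby("chrom"):
        mask = (sites["chrom"] == c).to_numpy()
        if not mask.any():
            continue
        merged = _merge_intervals(
            sub["start"].to_numpy(np.int64), sub["end"].to_numpy(np.int64)
        )
        starts, ends = merged
        p = pos[mask]
        idx = np.searchsorted(starts, p, side="right") - 1
        inside = (idx >= 0) & (p < ends[np.clip(idx, 0, None)])
        flags[mask] = inside
    out["repeat"] = flags
    return out


def _merge_intervals(starts: np.ndarray, ends: np.ndarray):
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    m_starts, m_ends = [], []
    cur_s, cur_e = starts[0], ends[0]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            m_starts.append(cur_s)
            m_ends.append(cur_e)
            cur_s, cur_e = s, e
    m_starts.append(cur_s)
    m_ends.append(cur_e)
    return np.asarray(m_starts), np.asarray(m_ends)


def apply_filters(
    sites: pd.DataFrame, min_mspi: int = 4
) -> tuple[pd.DataFrame, FilterReport]:
    """Retain sites passing every exclusion rule.

    Requires ``snp_flank`` and ``repeat`` boolean columns plus an
    ``mspi_count`` column; a site is kept when it carries no SNP-flank
    flag, its MspI reference count is at least ``min_mspi`` (the rule
    removes strictly-low counts), it is autosomal, and it is not in a
    repeat.
    """
    snp = sites["snp_flank"].to_numpy(bool)
    rep = sites["repeat"].to_numpy(bool)
    sex = sites["chrom"].isin(SEX_CHROMS).to_numpy()
    low = sites["mspi_count"].to_numpy() < min_mspi
    bad = snp | rep | sex | low
    report = FilterReport(
        n_input=len(sites),
        removed_snp_flank=int(snp.sum()),
        removed_low_mspi=int(low.sum()),
        removed_sex_chrom=int(sex.sum()),
        removed_repeat=int(rep.sum()),
        removed_any=int(bad.sum()),
        retained=int((~bad).sum()),
    )
    return sites.loc[~bad].copy(), report
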