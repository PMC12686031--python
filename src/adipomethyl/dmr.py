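"""Differentially methylated region (DMR) calling and locus counting.

A DMR is a run of array CpGs containing at least three differentially
methylated positions (DMPs), with every gap between consecutive member
CpGs under 1 kb (strictly: a 1000 bp gap breaks a region) and at most
three non-DMP CpGs lying strictly between the first and last member DMP.
Regions are built by a left-to-right greedy scan that extends through
non-DMPs while the constraints hold and trims trailing non-DMPs, so each
region starts and ends at a DMP and each DMP belongs to at most one
region.  The number of distinct associated loci is then
``total DMPs − DMPs inside DMRs + number of DMRs``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Dmr", "call_dmrs", "call_dmrs_table", "count_distinct_loci"]

MAX_GAP = 1000       # bp; a gap >= this splits regions
MIN_DMPS = 3
MAX_NON_DMPS = 3


@dataclass(frozen=True)
class Dmr:
    chrom: str
    start: int          # position of the first member DMP (1-based)
    end: int            # position of the last member DMP
    member_cpgs: tuple  # ordered CpG ids of member DMPs
    n_dmps: int
    n_non_dmps_spanned: int


def call_dmrs(positions, is_dmp, cpg_ids=None, chrom: str = "chr?") -> list[Dmr]:
    """Call DMRs on one chromosome's sorted CpG list.

    ``positions`` must be strictly increasing; ``is_dmp`` flags the
    significant CpGs.  Greedy scan: start at the leftmost unused DMP,
    extend rightwards CpG by CpG, stopping when the next CpG is >= 1 kb
    away or admitting it would exceed three spanned non-DMPs; the region
    is then trimmed back to its last DMP and emitted if it holds >= 3
    DMPs.
    """
    pos = np.asarray(positions, dtype=np.int64)
    dmp = np.asarray(is_dmp, dtype=bool)
    if pos.size != dmp.size:
        raise ValueError("positions and is_dmp must have equal length")
    if np.any(np.diff(pos) <= 0):
        raise ValueError("positions must be strictly increasing within a chromosome")
    if cpg_ids is None:
        cpg_ids = [f"cpg_{p}" for p in pos]

    regions: list[Dmr] = []
    n = pos.size
    i = 0
    while i < n:
        if not dmp[i]:
            i += 1
            continue
        # extend from the DMP at i
        last = i          # index of last CpG admitted
        last_dmp = i      # index of last admitted DMP
        non_dmps = 0      # non-DMPs strictly inside [i, last_dmp]
        pending_non = 0   # non-DMPs admitted after last_dmp (not yet spanned)
        j = i + 1
        while j < n:
            if pos[j] - pos[last] >= MAX_GAP:
                break
            if dmp[j]:
                if non_dmps + pending_non > MAX_NON_DMPS:
                    break
                non_dmps += pending_non
                pending_non = 0
                last_dmp = j
            else:
                pending_non += 1
                if non_dmps + pending_non > MAX_NON_DMPS:
                    # no later DMP could be admitted past this point
                    break
            last = j
            j += 1
        members = [k for k in range(i, last_dmp + 1) if dmp[k]]
        if len(members) >= MIN_DMPS:
            regions.append(Dmr(
                chrom=chrom,
                start=int(pos[members[0]]),
                end=int(pos[members[-1]]),
                member_cpgs=tuple(cpg_ids[k] for k in members),
                n_dmps=len(members),
                n_non_dmps_spanned=int((last_dmp - i + 1) - len(members)),
            ))
            i = last_dmp + 1
        else:
            i += 1
    return regions


def call_dmrs_table(meta_table: pd.DataFrame, annotation: pd.DataFrame) -> list[Dmr]:
    """Call DMRs genome-wide from a MetaRecord table plus probe positions.

    ``significant`` flags define the DMPs; calling runs per chromosome on
    position-sorted CpGs and the per-chromosome results are concatenated
    (no region crosses a chromosome boundary).
    """
    ann = annotation.set_index("cpg_id")
    df = meta_table[["cpg_id", "significant"]].copy()
    df["chrom"] = ann.reindex(df["cpg_id"])["chrom"].to_numpy()
    df["pos"] = ann.reindex(df["cpg_id"])["pos"].to_numpy()
    if df[["chrom", "pos"]].isna().any().any():
        raise ValueError("meta table contains CpGs absent from the annotation")
    regions: list[Dmr] = []
    for chrom, sub in df.sort_values("pos").groupby("chrom", sort=True):
        sub = sub.drop_duplicates(subset="pos")
        regions.extend(call_dmrs(sub["pos"].to_numpy(),
                                 sub["significant"].to_numpy(),
                                 list(sub["cpg_id"]), chrom=str(chrom)))
    return regions


def count_distinct_loci(n_dmps_total: int, dmrs: list[Dmr]) -> int:
    """Distinct loci = total DMPs − DMPs inside DMRs + number of DMRs."""
    in_regions = sum(d.n_dmps for d in dmrs)
    if in_regions > n_dmps_total:
        raise ValueError(
            f"DMRs contain {in_regions} DMPs but only {n_dmps_total} exist")
    return int(n_dmps_total - in_regions + len(dmrs))
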