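"""Windowed genome scans: sliding-window rates, percentile outlier regions,
recurrent regions across samples, fixed-SNP-count heterozygosity windows,
and region exclusion.

Window construction follows the bedtools-makewindows dialect (start at 0,
advance by the step while the start is inside the chromosome, truncate the
final windows at the chromosome end); outlier selection uses the
nearest-rank percentile with ties included.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import MISSING, Interval, SampleCallset, merge_intervals

logger = logging.getLogger(__name__)


@dataclass
class WindowStat:
    interval: Interval
    n_total: int
    n_event: int

    @property
    def rate(self) -> Optional[float]:
        return None if self.n_total == 0 else self.n_event / self.n_total


def make_windows(chrom_lengths: dict, size: int, step: int) -> list[Interval]:
    if size <= 0 or step <= 0:
        raise ValueError("size and step must be positive")
    out = []
    for chrom, length in chrom_lengths.items():
        start = 0
        while start < length:
            out.append(Interval(chrom, start, min(start + size, length)))
            start += step
    return out


def window_rates(
    sites: pd.DataFrame,
    denom: np.ndarray,
    numer: np.ndarray,
    windows: Sequence[Interval],
) -> list[WindowStat]:
    """Per-window event rates; a site contributes to every window containing
    its position.  ``denom``/``numer`` are per-site boolean flags (a numerator
    site must also be in the denominator)."""
    denom = np.asarray(denom, bool)
    numer = np.asarray(numer, bool)
    if ((~denom) & numer).any():
        raise ValueError("numerator flags must imply denominator flags")
    by_chrom = {}
    pos0 = sites["pos"].to_numpy() - 1
    chrom_arr = sites["chrom"].to_numpy()
    for chrom in pd.unique(chrom_arr):
        m = chrom_arr == chrom
        p = pos0[m]
        cd = np.concatenate([[0], np.cumsum(denom[m])])
        cn = np.concatenate([[0], np.cumsum(numer[m])])
        by_chrom[chrom] = (p, cd, cn)
    out = []
    for w in windows:
        if w.chrom not in by_chrom:
            out.append(WindowStat(w, 0, 0))
            continue
        p, cd, cn = by_chrom[w.chrom]
        lo = np.searchsorted(p, w.start, "left")
        hi = np.searchsorted(p, w.end, "left")
        out.append(WindowStat(w, int(cd[hi] - cd[lo]), int(cn[hi] - cn[lo])))
    return out


def percentile_outliers(stats: Sequence[WindowStat], tail: str, pct: float = 1.0) -> list[Interval]:
    """Windows at or beyond the nearest-rank ``pct``-percentile, merged.

    ``tail="bottom"`` selects low rates (concordance outliers), ``"top"``
    selects high rates (FPR outliers).  Windows with undefined rates are
    excluded from ranking.  Ties at the threshold are all included.
    """
    if tail not in ("bottom", "top"):
        raise ValueError("tail must be 'bottom' or 'top'")
    defined = [s for s in stats if s.rate is not None]
    if not defined:
        return []
    if len(defined) < 100.0 / pct:
        logger.warning("percentile_outliers: only %d defined windows for pct=%s", len(defined), pct)
    rates = np.array([s.rate for s in defined])
    k = max(1, math.ceil(pct / 100.0 * len(defined)))
    order = np.sort(rates)
    if tail == "bottom":
        thr = order[k - 1]
        sel = [s for s in defined if s.rate <= thr]
    else:
        thr = order[len(order) - k]
        sel = [s for s in defined if s.rate >= thr]
    return merge_intervals([s.interval for s in sel], touching=True)


def recurrent_regions(
    per_sample_outliers: Sequence[Sequence[Interval]],
    min_samples: int = 3,
) -> list[Interval]:
    """Regions (merged across all samples' outliers) hit by >= ``min_samples``
    samples; the payload carries the contributing-sample count."""
    if len(per_sample_outliers) < min_samples:
        raise ValueError("fewer outlier sets than min_samples")
    all_iv = [iv for sample in per_sample_outliers for iv in sample]
    if not all_iv:
        return []
    merged = merge_intervals(all_iv, touching=True)
    out = []
    for region in merged:
        n = sum(
            1
            for sample in per_sample_outliers
            if any(region.overlaps(iv) for iv in sample)
        )
        if n >= min_samples:
            out.append(Interval(region.chrom, region.start, region.end, n))
    return out


def het_windows(callset: SampleCallset, window_snps: int = 50) -> pd.DataFrame:
    """Heterozygote counts in consecutive non-overlapping blocks of exactly
    ``window_snps`` non-missing calls (per chromosome; trailing partial
    blocks dropped).  Returns chrom, start, end (bp span of the block), n_het."""
    rows = []
    chrom_arr = callset.sites["chrom"].to_numpy()
    pos = callset.sites["pos"].to_numpy()
    dos = callset.dosage
    for chrom in pd.unique(chrom_arr):
        m = (chrom_arr == chrom) & (dos != MISSING)
        p = pos[m]
        d = dos[m]
        n_blocks = len(d) // window_snps
        for b in range(n_blocks):
            sl = slice(b * window_snps, (b + 1) * window_snps)
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(p[sl][0]) - 1,
                    "end": int(p[sl][-1]),
                    "n_het": int((d[sl] == 1).sum()),
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_het"])


def exclude_regions(
    sites: pd.DataFrame,
    callsets: Sequence[SampleCallset],
    regions: Sequence[Interval],
) -> tuple[pd.DataFrame, list[SampleCallset]]:
    """Drop every site falling inside any region, consistently across all
    callsets.  Returns the filtered site table and new callsets."""
    pos0 = sites["pos"].to_numpy() - 1
    chrom_arr = sites["chrom"].to_numpy()
    drop = np.zeros(len(sites), dtype=bool)
    for r in regions:
        drop |= (chrom_arr == r.chrom) & (pos0 >= r.start) & (pos0 < r.end)
    keep_idx = np.flatnonzero(~drop)
    new_sites = sites.iloc[keep_idx].reset_index(drop=True)
    out = []
    for cs in callsets:
        gp = None if cs.gp is None else cs.gp[keep_idx]
        out.append(SampleCallset(cs.sample_id, new_sites, cs.dosage[keep_idx], gp))
    return new_sites, out


def edge_flagged(regions: Sequence[Interval], chrom_lengths: dict, edge_bp: int = 2_000_000) -> list[bool]:
    """Flag regions overlapping the first/last ``edge_bp`` of their chromosome
    (annotation only; nothing is auto-excluded)."""
    flags = []
    for r in regions:
        L = chrom_lengths.get(r.chrom)
        if L is None:
            flags.append(False)
            continue
        flags.append(r.start < edge_bp or r.end > L - edge_bp)
    return flags
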