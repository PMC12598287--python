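"""Outgroup f3 shared-drift statistic with a weighted block jackknife, and
group allele-frequency computation.

f3(O; A, B) = E[(o - a)(o - b)] over sites, with o/a/b the ALT-allele
frequencies in the outgroup and the two test populations.  Larger values
mean more shared drift of A and B relative to the outgroup.  Standard
errors come from a delete-one block jackknife over contiguous physical
blocks, weighted by per-block site counts (blocks absorb linkage).  No
finite-sample bias correction is applied, the convention in outgroup mode
where only the ranking of f3 values matters; ``h_correction=True`` enables
the within-population heterozygosity correction variant.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .types import MISSING, SampleCallset


@dataclass
class FreqTable:
    """Per-population ALT-frequency estimates with observation counts."""

    sites: pd.DataFrame
    freqs: pd.DataFrame   # one column per population, NaN where unobserved
    counts: pd.DataFrame  # diploid individuals observed per site


def group_freqs(callsets: Sequence[SampleCallset], groups: Dict[str, Sequence[str]]) -> FreqTable:
    """ALT-allele frequency per site per population: dosage sum over
    2 x (non-missing individuals); sites with no observation get NaN."""
    by_id = {cs.sample_id: cs for cs in callsets}
    n = len(callsets[0].sites)
    freqs = {}
    counts = {}
    for pop, members in groups.items():
        if not members:
            raise ValueError(f"empty group {pop!r}")
        dos = np.stack([by_id[s].dosage for s in members])
        called = dos != MISSING
        n_obs = called.sum(axis=0)
        with np.errstate(invalid="ignore"):
            f = np.where(called, dos, 0).sum(axis=0) / (2.0 * np.maximum(n_obs, 1))
        f = np.where(n_obs == 0, np.nan, f)
        freqs[pop] = f
        counts[pop] = n_obs
    return FreqTable(callsets[0].sites, pd.DataFrame(freqs), pd.DataFrame(counts))


@dataclass
class F3Result:
    f3: float
    se: Optional[float]
    z: Optional[float]
    n_sites: int
    n_blocks: int
    block_estimates: Optional[np.ndarray] = None

    def __repr__(self) -> str:  # pragma: no cover
        se = "NA" if self.se is None else f"{self.se:.6f}"
        z = "NA" if self.z is None else f"{self.z:.3f}"
        return (
            f"F3Result(f3={self.f3:.6f}, se={se}, z={z}, "
            f"n_sites={self.n_sites}, n_blocks={self.n_blocks})"
        )


def outgroup_f3(
    freq_table: FreqTable,
    pop_o: str,
    pop_a: str,
    pop_b: str,
    block_size_bp: int = 5_000_000,
    h_correction: bool = False,
) -> F3Result:
    """f3(pop_o; pop_a, pop_b) with weighted delete-one-block jackknife SE.

    Sites unobserved in any of the three populations are skipped.  Blocks
    are contiguous ``block_size_bp`` windows by physical position; the SE is
    the Busing weighted jackknife over leave-one-block estimates (undefined
    with fewer than two non-empty blocks).
    """
    f = freq_table.freqs
    for pop in (pop_o, pop_a, pop_b):
        if pop not in f.columns:
            raise KeyError(f"population {pop!r} not in frequency table")
    o = f[pop_o].to_numpy()
    a = f[pop_a].to_numpy()
    b = f[pop_b].to_numpy()
    used = ~(np.isnan(o) | np.isnan(a) | np.isnan(b))
    if not used.any():
        raise ValueError("all sites skipped: no jointly observed site")
    v = (o[used] - a[used]) * (o[used] - b[used])
    if h_correction:
        cnt = freq_table.counts[pop_a].to_numpy()[used]
        ha = a[used] * (1 - a[used]) / np.maximum(2 * cnt - 1, 1)
        v = v - ha

    sites = freq_table.sites
    chrom = sites["chrom"].to_numpy()[used]
    pos0 = sites["pos"].to_numpy()[used] - 1
    block_key = pd.Series(list(zip(chrom, pos0 // block_size_bp)))
    codes = pd.factorize(block_key)[0]
    n_blocks = codes.max() + 1
    n_total = len(v)
    f3 = float(v.mean())
    if n_blocks < 2:
        return F3Result(f3, None, None, n_total, int(n_blocks))

    sums = np.bincount(codes, weights=v, minlength=n_blocks)
    sizes = np.bincount(codes, minlength=n_blocks).astype(float)
    total = v.sum()
    theta_j = (total - sums) / (n_total - sizes)  # leave-one-block estimates
    h = n_total / sizes
    g = n_blocks
    theta_jack = g * f3 - float(((1 - sizes / n_total) * theta_j).sum())
    tau = h * f3 - (h - 1) * theta_j
    var = float((((tau - theta_jack) ** 2) / (h - 1)).sum() / g)
    se = float(np.sqrt(var))
    z = None if se == 0 else f3 / se
    return F3Result(f3, se, z, n_total, int(n_blocks), theta_j)


def f3_table(
    freq_table: FreqTable,
    pop_o: str,
    pairs: Sequence[tuple],
    block_size_bp: int = 5_000_000,
) -> pd.DataFrame:
    rows = []
    for (pa, pb) in pairs:
        r = outgroup_f3(freq_table, pop_o, pa, pb, block_size_bp)
        rows.append(
            {
                "pop_a": pa,
                "pop_b": pb,
                "outgroup": pop_o,
                "f3": r.f3,
                "se": r.se,
                "z": r.z,
                "n_sites": r.n_sites,
                "n_blocks": r.n_blocks,
            }
        )
    return pd.DataFrame(rows)
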