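"""Core domain containers shared across the pipeline.

Coordinate conventions
----------------------
Variant sites carry their 1-based VCF position in the ``pos`` column of the
site table.  All *intervals* (windows, ROH/IBD segments, BED records,
exclusion regions) are 0-based half-open, the BED convention.  A site at
1-based position ``p`` lies inside interval ``[start, end)`` iff
``start <= p - 1 < end``.

Genotypes are unphased diploid dosages of the ALT allele: 0 (hom-ref),
1 (het), 2 (hom-alt), with :data:`MISSING` (= -1) for no-calls.  Genotype
probability (GP) triples, when present, are ``(p_homref, p_het, p_homalt)``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: Sentinel dosage for a missing genotype call.
MISSING: int = -1

#: Columns every site table must carry.  ``alt_freq`` is the panel ALT-allele
#: frequency; ``maf`` is its folded (minor-allele) counterpart in [0, 0.5].
SITE_COLUMNS = ("chrom", "pos", "ref", "alt", "alt_freq", "maf")


def make_site_table(
    chrom: Sequence[str],
    pos: Sequence[int],
    ref: Sequence[str],
    alt: Sequence[str],
    alt_freq: Sequence[float],
) -> pd.DataFrame:
    """Assemble a validated site table (sorted by chrom, pos)."""
    df = pd.DataFrame(
        {
            "chrom": np.asarray(chrom, dtype=object),
            "pos": np.asarray(pos, dtype=np.int64),
            "ref": np.asarray(ref, dtype=object),
            "alt": np.asarray(alt, dtype=object),
            "alt_freq": np.asarray(alt_freq, dtype=float),
        }
    )
    df["maf"] = np.minimum(df["alt_freq"], 1.0 - df["alt_freq"])
    validate_site_table(df)
    return df


def validate_site_table(sites: pd.DataFrame) -> None:
    for col in SITE_COLUMNS:
        if col not in sites.columns:
            raise ValueError(f"site table missing column {col!r}")
    if (sites["pos"] < 1).any():
        raise ValueError("site positions must be 1-based (>= 1)")
    if ((sites["maf"] < 0) | (sites["maf"] > 0.5)).any():
        raise ValueError("maf must lie in [0, 0.5]")
    if (sites["ref"] == sites["alt"]).any():
        raise ValueError("ref and alt alleles must differ")
    for _, grp in sites.groupby("chrom", sort=False):
        d = np.diff(grp["pos"].to_numpy())
        if (d <= 0).any():
            raise ValueError("site positions must be strictly increasing per chromosome")


@dataclass
class SampleCallset:
    """Genotype calls for one sample, aligned to a shared site table.

    Attributes
    ----------
    sample_id : str
    sites : pandas.DataFrame
        Shared site table (see :func:`make_site_table`); never mutated.
    dosage : ndarray of int8
        ALT dosage per site; ``MISSING`` (-1) for no-calls.
    gp : ndarray of shape (n_sites, 3), optional
        Genotype probability triples; rows sum to 1 where defined.
    """

    sample_id: str
    sites: pd.DataFrame
    dosage: np.ndarray
    gp: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if len(self.dosage) != len(self.sites):
            raise ValueError("dosage length must match site table")
        if self.gp is not None:
            self.gp = np.asarray(self.gp, dtype=float)
            if self.gp.shape != (len(self.sites), 3):
                raise ValueError("gp must have shape (n_sites, 3)")
            sums = self.gp.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-6):
                raise ValueError("gp triples must sum to 1 (±1e-6)")

    @property
    def n_sites(self) -> int:
        return len(self.dosage)

    @property
    def called(self) -> np.ndarray:
        """Boolean mask of non-missing calls."""
        return self.dosage != MISSING

    def subset(self, mask_or_index: np.ndarray) -> "SampleCallset":
        """Return a new callset restricted to the given sites (shared order)."""
        sites = self.sites.iloc[mask_or_index] if np.asarray(mask_or_index).dtype != bool else self.sites.loc[mask_or_index]
        sites = sites.reset_index(drop=True)
        gp = None if self.gp is None else self.gp[mask_or_index]
        return SampleCallset(self.sample_id, sites, self.dosage[mask_or_index], gp)


@dataclass(frozen=True)
class Interval:
    """0-based half-open genomic interval with an optional payload."""

    chrom: str
    start: int
    end: int
    payload: object = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


def merge_intervals(intervals: Sequence[Interval], touching: bool = True) -> list[Interval]:
    """Union of intervals per chromosome; touching intervals merge when asked."""
    out: list[Interval] = []
    by_chrom: dict[str, list[Interval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom in by_chrom:
        ivs = sorted(by_chrom[chrom], key=lambda v: (v.start, v.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            joins = iv.start <= cur_e if touching else iv.start < cur_e
            if joins:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(Interval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        out.append(Interval(chrom, cur_s, cur_e))
    out.sort(key=lambda v: (v.chrom, v.start))
    return out


class GeneticMap:
    """Monotone bp → cumulative-cM lookup, piecewise linear between anchors.

    Beyond the terminal anchors the map extrapolates as a constant (the
    terminal anchor's cM value), so every physical position has a defined
    genetic position.
    """

    def __init__(self, anchors: dict[str, tuple[np.ndarray, np.ndarray]]):
        self.anchors: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (bp, cm) in anchors.items():
            bp = np.asarray(bp, dtype=float)
            cm = np.asarray(cm, dtype=float)
            if len(bp) < 2:
                raise ValueError(f"chromosome {chrom}: need >= 2 anchors")
            if (np.diff(bp) <= 0).any():
                raise ValueError(f"chromosome {chrom}: anchor positions must strictly increase")
            if (np.diff(cm) < 0).any():
                raise ValueError(f"chromosome {chrom}: cM must be non-decreasing")
            self.anchors[chrom] = (bp, cm)

    @classmethod
    def uniform(cls, chrom_lengths: dict[str, int], cm_per_mb: float = 1.0) -> "GeneticMap":
        """Constant-rate map: cm_per_mb centimorgans per megabase."""
        return cls(
            {
                c: (np.array([0.0, float(L)]), np.array([0.0, L * cm_per_mb / 1e6]))
                for c, L in chrom_lengths.items()
            }
        )

    def chroms(self) -> list[str]:
        return list(self.anchors)

    def cm(self, chrom: str, pos) -> np.ndarray | float:
        """Interpolate cumulative cM at physical position(s) ``pos``."""
        if chrom not in self.anchors:
            raise KeyError(f"chromosome {chrom!r} absent from genetic map")
        bp, cm = self.anchors[chrom]
        res = np.interp(np.asarray(pos, dtype=float), bp, cm)
        return float(res) if np.isscalar(pos) or np.ndim(pos) == 0 else res

    def bp(self, chrom: str, cm_pos) -> np.ndarray | float:
        """Approximate inverse lookup (cM → bp); flat stretches map to their left edge."""
        if chrom not in self.anchors:
            raise KeyError(f"chromosome {chrom!r} absent from genetic map")
        bp, cm = self.anchors[chrom]
        res = np.interp(np.asarray(cm_pos, dtype=float), cm, bp)
        return float(res) if np.isscalar(cm_pos) or np.ndim(cm_pos) == 0 else res


@dataclass
class RohSegment:
    """A run of homozygosity: [start, end) plus provenance and quality."""

    sample: str
    chrom: str
    start: int
    end: int
    n_snps: int
    source: str  # windowscan | hmm | merged
    quality: Optional[float] = None
    contributing_count: Optional[int] = None
    contributing_lengths: Optional[tuple[int, ...]] = None

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> Interval:
        return Interval(self.chrom, self.start, self.end)


@dataclass
class IbdSegment:
    """A pairwise identity-by-descent segment in bp and cM coordinates."""

    sample_a: str
    sample_b: str
    chrom: str
    start_bp: int
    end_bp: int
    lod: Optional[float] = None
    start_cm: Optional[float] = None
    end_cm: Optional[float] = None

    @property
    def pair(self) -> frozenset:
        return frozenset((self.sample_a, self.sample_b))

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp

    @property
    def length_cm(self) -> float:
        if self.start_cm is None or self.end_cm is None:
            raise ValueError("cM coordinates not set; attach a genetic map first")
        return self.end_cm - self.start_cm

    def with_cm(self, gmap: GeneticMap) -> "IbdSegment":
        return IbdSegment(
            self.sample_a,
            self.sample_b,
            self.chrom,
            self.start_bp,
            self.end_bp,
            self.lod,
            float(gmap.cm(self.chrom, self.start_bp)),
            float(gmap.cm(self.chrom, self.end_bp)),
        )
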