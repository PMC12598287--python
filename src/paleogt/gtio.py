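"""Readers/writers for VCF, BED, genetic-map and IBD-table formats, plus the
elementary genotype transforms (GP filtering, MAF tranches, substitution
classes, map interpolation helpers).

VCF handling is a thin domain layer over :mod:`pysam`: only biallelic SNV
records with a GT FORMAT field are consumed; everything else is skipped and
counted.  Panel minor-allele frequency is taken from the INFO key ``PMAF``
when present, otherwise computed from the sample genotypes in the file.
"""
from __future__ import annotations

import logging
import math
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .types import (
    MISSING,
    GeneticMap,
    Interval,
    IbdSegment,
    SampleCallset,
    make_site_table,
    validate_site_table,
)

logger = logging.getLogger(__name__)

#: GP thresholds conventionally swept when assessing imputation quality.
GP_THRESHOLDS = (0.7, 0.8, 0.9, 0.95, 0.99)

#: Minor-allele-frequency tranche edges (fractions), left-open right-closed.
TRANCHE_EDGES = (0.0, 0.01, 0.02, 0.05, 0.10, 0.20, 0.50)
TRANCHE_LABELS = ("(0,1]", "(1,2]", "(2,5]", "(5,10]", "(10,20]", "(20,50]")
MONOMORPHIC = "monomorphic"

_PURINES = {"A", "G"}
_TRANSITION_PAIRS = ({"A", "G"}, {"C", "T"})


# ---------------------------------------------------------------------------
# elementary transforms
# ---------------------------------------------------------------------------

def classify_substitution(ref: str, alt: str) -> str:
    """Return ``"transition"`` for A<->G / C<->T, else ``"transversion"``."""
    ref, alt = ref.upper(), alt.upper()
    for allele in (ref, alt):
        if allele not in "ACGT" or len(allele) != 1:
            raise ValueError(f"non-ACGT allele {allele!r}")
    if ref == alt:
        raise ValueError("ref and alt must differ")
    return "transition" if {ref, alt} in _TRANSITION_PAIRS else "transversion"


def is_transition(ref: Sequence[str], alt: Sequence[str]) -> np.ndarray:
    """Vectorised transition indicator over paired allele arrays."""
    ref = np.char.upper(np.asarray(ref, dtype=str))
    alt = np.char.upper(np.asarray(alt, dtype=str))
    return ((np.isin(ref, ("A", "G"))) & (np.isin(alt, ("A", "G")))) | (
        (np.isin(ref, ("C", "T"))) & (np.isin(alt, ("C", "T")))
    )


def maf_tranche(maf: float) -> str:
    """Assign a MAF to its tranche label; 0 maps to ``"monomorphic"``.

    Tranches are left-open/right-closed in percent: (0,1], (1,2], (2,5],
    (5,10], (10,20], (20,50].  A MAF of exactly 5% therefore falls in (2,5].
    """
    if not (0.0 <= maf <= 0.5):
        raise ValueError(f"maf {maf} outside [0, 0.5]")
    if maf == 0.0:
        return MONOMORPHIC
    for lo, hi, label in zip(TRANCHE_EDGES[:-1], TRANCHE_EDGES[1:], TRANCHE_LABELS):
        if lo < maf <= hi:
            return label
    raise AssertionError("unreachable")


def maf_tranches(maf: np.ndarray) -> np.ndarray:
    """Vectorised :func:`maf_tranche` over an array of MAF values."""
    maf = np.asarray(maf, dtype=float)
    if ((maf < 0) | (maf > 0.5)).any():
        raise ValueError("maf outside [0, 0.5]")
    idx = np.searchsorted(np.asarray(TRANCHE_EDGES[1:]), maf, side="left")
    labels = np.asarray(TRANCHE_LABELS, dtype=object)
    out = np.where(maf == 0.0, MONOMORPHIC, labels[np.clip(idx, 0, len(TRANCHE_LABELS) - 1)])
    return out.astype(object)


def apply_gp_filter(callset: SampleCallset, threshold: float) -> SampleCallset:
    """Set to missing every call whose max genotype probability is below
    ``threshold`` or whose recorded genotype is not the GP argmax.

    The argmax guard is a consistency check: an imputation engine emits the
    argmax genotype, so a disagreement (possible in hand-edited files) is
    treated as unreliable and dropped.  Calls without GP are dropped under
    any positive threshold.  The operation is idempotent at fixed threshold.
    """
    if threshold <= 0:
        return SampleCallset(callset.sample_id, callset.sites, callset.dosage.copy(),
                             None if callset.gp is None else callset.gp.copy())
    dosage = callset.dosage.copy()
    if callset.gp is None:
        dosage[:] = MISSING
        return SampleCallset(callset.sample_id, callset.sites, dosage, None)
    maxgp = callset.gp.max(axis=1)
    argmax = callset.gp.argmax(axis=1)
    keep = (maxgp >= threshold - 1e-12) & (argmax == dosage) & (dosage != MISSING)
    dosage[~keep] = MISSING
    return SampleCallset(callset.sample_id, callset.sites, dosage, callset.gp.copy())


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str) -> tuple[pd.DataFrame, list[SampleCallset]]:
    """Read a VCF into a site table and one :class:`SampleCallset` per sample.

    Only biallelic SNVs are kept; the number skipped is logged.  ``PMAF`` in
    INFO supplies the panel ALT frequency; when absent it is computed from
    the file's own genotypes.  Raises on files with no GT field or unsorted
    records.
    """
    vf = pysam.VariantFile(path)
    if "GT" not in vf.header.formats:
        raise ValueError(f"{path}: no GT FORMAT field in header")
    samples = list(vf.header.samples)
    chroms: list[str] = []
    pos: list[int] = []
    ref: list[str] = []
    alt: list[str] = []
    pmaf: list[float] = []
    dosages: list[list[int]] = [[] for _ in samples]
    gps: list[list[Optional[tuple]]] = [[] for _ in samples]
    has_pmaf = "PMAF" in vf.header.info
    n_skipped = 0
    last: dict[str, int] = {}
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1 or len(rec.ref) != 1 or len(rec.alts[0]) != 1:
            n_skipped += 1
            continue
        if rec.chrom in last and rec.pos <= last[rec.chrom]:
            raise ValueError(f"{path}: unsorted record at {rec.chrom}:{rec.pos}")
        last[rec.chrom] = rec.pos
        chroms.append(rec.chrom)
        pos.append(rec.pos)
        ref.append(rec.ref)
        alt.append(rec.alts[0])
        pmaf.append(rec.info.get("PMAF", math.nan) if has_pmaf else math.nan)
        for i, s in enumerate(samples):
            call = rec.samples[s]
            gt = call.get("GT")
            if gt is None or any(a is None for a in gt):
                dosages[i].append(MISSING)
            else:
                dosages[i].append(int(sum(gt)))
            gp = call.get("GP")
            gps[i].append(tuple(gp) if gp is not None and gp[0] is not None else None)
    vf.close()
    if n_skipped:
        logger.info("read_vcf(%s): skipped %d non-biallelic-SNV records", path, n_skipped)

    alt_freq = np.asarray(pmaf, dtype=float)
    need = np.isnan(alt_freq)
    if need.any():
        dos = np.asarray(dosages, dtype=np.int8)  # samples x sites
        called = dos != MISSING
        with np.errstate(invalid="ignore"):
            emp = np.where(called, dos, 0).sum(axis=0) / (2.0 * np.maximum(called.sum(axis=0), 1))
        emp[called.sum(axis=0) == 0] = 0.0
        alt_freq = np.where(need, emp, alt_freq)
    sites = make_site_table(chroms, pos, ref, alt, alt_freq)
    sites.attrs["n_skipped"] = n_skipped

    callsets = []
    for i, s in enumerate(samples):
        gp_rows = gps[i]
        if any(g is not None for g in gp_rows):
            gp = np.full((len(sites), 3), np.nan)
            for j, g in enumerate(gp_rows):
                gp[j] = g if g is not None else (1 / 3, 1 / 3, 1 / 3)
            gp /= gp.sum(axis=1, keepdims=True)  # undo float32/rounding drift
        else:
            gp = None
        callsets.append(SampleCallset(s, sites, np.asarray(dosages[i], dtype=np.int8), gp))
    return sites, callsets


def write_vcf(
    sites: pd.DataFrame,
    callsets: Sequence[SampleCallset],
    path: str,
    chrom_lengths: Optional[dict[str, int]] = None,
) -> None:
    """Write a VCF 4.2 file with GT (+ GP where available) and INFO/PMAF."""
    validate_site_table(sites)
    for cs in callsets:
        if len(cs.dosage) != len(sites):
            raise ValueError(f"callset {cs.sample_id}: site list mismatch")
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=PMAF,Number=1,Type=Float,Description="Panel ALT allele frequency">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=GP,Number=G,Type=Float,Description="Genotype probabilities">')
    lengths = dict(chrom_lengths or {})
    for chrom, grp in sites.groupby("chrom", sort=False):
        lengths.setdefault(chrom, int(grp["pos"].max()) + 1)
    for chrom, L in lengths.items():
        header.add_line(f"##contig=<ID={chrom},length={L}>")
    for cs in callsets:
        header.add_sample(cs.sample_id)
    out = pysam.VariantFile(path, "w", header=header)
    gt_map = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}
    for j in range(len(sites)):
        row = sites.iloc[j]
        rec = out.new_record(
            contig=row["chrom"],
            start=int(row["pos"]) - 1,
            stop=int(row["pos"]),
            alleles=(row["ref"], row["alt"]),
        )
        rec.info["PMAF"] = float(row["alt_freq"])
        for cs in callsets:
            rec.samples[cs.sample_id]["GT"] = gt_map[int(cs.dosage[j])]
            rec.samples[cs.sample_id].phased = False
            if cs.gp is not None:
                rec.samples[cs.sample_id]["GP"] = tuple(round(float(x), 4) for x in cs.gp[j])
        out.write(rec)
    out.close()


# ---------------------------------------------------------------------------
# BED / genetic map / IBD tables
# ---------------------------------------------------------------------------

def read_bed(path: str) -> list[Interval]:
    """Parse BED3/BED6 into intervals (payload = column 4/5 when present)."""
    out: list[Interval] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: malformed BED line")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-integer coordinates") from exc
            payload = parts[3] if len(parts) > 3 else None
            out.append(Interval(parts[0], start, end, payload))
    return out


def write_bed(intervals: Iterable[Interval], path: str, score: bool = False) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            if iv.payload is not None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.payload}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_map(path: str) -> GeneticMap:
    """Read a 3-column whitespace-separated map: chrom, pos_bp, cum_cM."""
    df = pd.read_csv(path, sep=r"\s+", header=None, names=["chrom", "pos", "cm"], comment="#")
    anchors = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        anchors[str(chrom)] = (grp["pos"].to_numpy(float), grp["cm"].to_numpy(float))
    return GeneticMap(anchors)


def write_map(gmap: GeneticMap, path: str) -> None:
    with open(path, "w") as fh:
        for chrom, (bp, cm) in gmap.anchors.items():
            for b, c in zip(bp, cm):
                fh.write(f"{chrom}\t{int(b)}\t{c:.6f}\n")


IBD_COLUMNS = ("sample1", "hap1", "sample2", "hap2", "chrom", "start_bp", "end_bp", "lod")


def read_ibd_table(path: str) -> list[IbdSegment]:
    """Read an 8-column RefinedIBD-style tab-separated segment table."""
    out: list[IbdSegment] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 8:
                raise ValueError(f"{path}:{ln}: expected 8 tab-separated columns")
            try:
                out.append(
                    IbdSegment(
                        sample_a=parts[0],
                        sample_b=parts[2],
                        chrom=parts[4],
                        start_bp=int(parts[5]),
                        end_bp=int(parts[6]),
                        lod=float(parts[7]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: malformed IBD record") from exc
    return out


def write_ibd_table(segments: Iterable[IbdSegment], path: str) -> None:
    with open(path, "w") as fh:
        for s in segments:
            fh.write(
                f"{s.sample_a}\t1\t{s.sample_b}\t1\t{s.chrom}\t{s.start_bp}\t{s.end_bp}\t"
                f"{s.lod if s.lod is not None else 'NA'}\n"
            )
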