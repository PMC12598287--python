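"""Synthetic-data generation for the analysis pipeline.

The generator emulates the statistical structure the downstream analyses
assume, without any external dataset:

* a phased haplotype *panel* with linkage disequilibrium, built by
  Li–Stephens-style mosaic copying from a small set of founder haplotypes,
  with a Beta-law allele-frequency spectrum (excess of rare alleles);
* *truth* diploid individuals as fresh mosaics over the panel, with planted
  autozygous (ROH) and pairwise shared (IBD) segments;
* an *imputed* callset under a MAF- and coverage-dependent error model with
  calibrated genotype probabilities (correct calls draw higher max-GP than
  wrong calls, so GP thresholds trade recovery against accuracy);
* *pseudohaploid* calls from Poisson read sampling (the representation a
  low-coverage ancient genome would get without imputation);
* noisy RefinedIBD-style segment tables across repeated runs, with boundary
  jitter, sub-0.6 cM splits, and decoy negatives.

All generators are driven by an explicit seed and are reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .gtio import MONOMORPHIC, TRANCHE_LABELS, maf_tranches
from .types import MISSING, GeneticMap, SampleCallset, make_site_table

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# panel
# ---------------------------------------------------------------------------

@dataclass
class PanelConfig:
    """Parameters of the mosaic haplotype panel.

    Defaults are a desk-scale stand-in for a livestock reference panel:
    two 50 Mb chromosomes at 1 cM/Mb with 50k sites each, 200 haplotypes
    copied from 20 founders, and a U-shaped Beta(0.3, 0.3) frequency law
    giving a realistic excess of rare variants.
    """

    n_founders: int = 20
    n_haplotypes: int = 200
    n_sites: int = 100_000
    chrom_lengths: dict = field(
        default_factory=lambda: {"chr1": 50_000_000, "chr2": 50_000_000}
    )
    founder_freq_alpha: float = 0.3
    founder_freq_beta: float = 0.3
    switch_rate_per_cm: float = 0.1
    cm_per_mb: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_founders < 2:
            raise ValueError("need at least 2 founders")
        if self.n_haplotypes < self.n_founders:
            raise ValueError("n_haplotypes must be >= n_founders")
        if self.n_sites <= 0 or any(L <= 0 for L in self.chrom_lengths.values()):
            raise ValueError("all counts must be positive")


@dataclass
class Panel:
    sites: pd.DataFrame
    haplotypes: np.ndarray  # (n_haplotypes, n_sites) int8
    gmap: GeneticMap
    chrom_lengths: dict
    config: PanelConfig

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]


def _site_positions(rng: np.random.Generator, chrom_lengths: dict, n_sites: int):
    total = sum(chrom_lengths.values())
    chroms, positions = [], []
    remaining = n_sites
    items = list(chrom_lengths.items())
    for i, (chrom, L) in enumerate(items):
        n = remaining if i == len(items) - 1 else int(round(n_sites * L / total))
        n = min(n, remaining)
        pos = np.unique(rng.integers(1, L + 1, size=int(n * 1.2) + 8))
        while len(pos) < n:  # rare: top up after dedup
            pos = np.unique(np.concatenate([pos, rng.integers(1, L + 1, size=n)]))
        pos = np.sort(rng.choice(pos, size=n, replace=False))
        chroms.extend([chrom] * n)
        positions.append(pos)
        remaining -= n
    return np.asarray(chroms, dtype=object), np.concatenate(positions)


def _mosaic_haplotypes(
    rng: np.random.Generator,
    donors: np.ndarray,
    n_out: int,
    cm_pos: np.ndarray,
    chrom_codes: np.ndarray,
    switch_rate_per_cm: float,
) -> np.ndarray:
    """Copy ``n_out`` haplotypes from ``donors`` with recombination-driven
    donor switches (probability = rate x adjacent-site cM distance, capped
    at 1; a forced switch at every chromosome boundary)."""
    n_sites = donors.shape[1]
    d_cm = np.diff(cm_pos)
    new_chrom = np.diff(chrom_codes) != 0
    p_switch = np.minimum(switch_rate_per_cm * np.where(new_chrom, 0.0, d_cm), 1.0)
    out = np.empty((n_out, n_sites), dtype=np.int8)
    n_donors = donors.shape[0]
    for h in range(n_out):
        switch = np.empty(n_sites, dtype=bool)
        switch[0] = True
        switch[1:] = (rng.random(n_sites - 1) < p_switch) | new_chrom
        seg_id = np.cumsum(switch) - 1
        donor_ids = rng.integers(0, n_donors, size=seg_id[-1] + 1)
        out[h] = donors[donor_ids[seg_id], np.arange(n_sites)]
    return out


def simulate_panel(config: PanelConfig) -> Panel:
    """Generate the haplotype panel and its site table (MAF from the panel)."""
    gmap = GeneticMap.uniform(config.chrom_lengths, config.cm_per_mb)
    total_cm = sum(gmap.cm(c, L) for c, L in config.chrom_lengths.items())
    if total_cm <= 0:
        raise ValueError("degenerate genetic map: zero total cM")
    rng = np.random.default_rng(config.seed)
    chroms, pos = _site_positions(rng, config.chrom_lengths, config.n_sites)
    n = len(pos)
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    p = rng.beta(config.founder_freq_alpha, config.founder_freq_beta, size=n)
    founders = (rng.random((config.n_founders, n)) < p).astype(np.int8)
    chrom_codes = pd.factorize(chroms)[0]
    cm_pos = np.concatenate(
        [gmap.cm(c, pos[chroms == c]) for c in dict.fromkeys(chroms)]
    )
    n_extra = config.n_haplotypes - config.n_founders
    if n_extra > 0:
        extras = _mosaic_haplotypes(
            rng, founders, n_extra, cm_pos, chrom_codes, config.switch_rate_per_cm
        )
        haps = np.vstack([founders, extras])
    else:
        haps = founders
    alt_freq = haps.mean(axis=0)
    sites = make_site_table(chroms, pos, _BASES[ref_idx], _BASES[alt_idx], alt_freq)
    sites["cm"] = cm_pos
    return Panel(sites, haps, gmap, dict(config.chrom_lengths), config)


# ---------------------------------------------------------------------------
# truth diploids with planted segments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedSegment:
    """A segment planted in the truth data: an autozygous run (ROH, one
    sample) or a shared haplotype tract (IBD, two samples).  Coordinates are
    0-based half-open bp."""

    kind: str  # "ROH" | "IBD"
    samples: tuple
    chrom: str
    start: int
    end: int
    donor_hap: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in ("ROH", "IBD"):
            raise ValueError(f"unknown segment kind {self.kind!r}")
        n_expect = 1 if self.kind == "ROH" else 2
        if len(self.samples) != n_expect:
            raise ValueError(f"{self.kind} segment needs {n_expect} sample(s)")
        if self.start >= self.end:
            raise ValueError("empty planted segment")


@dataclass
class TruthSet:
    callsets: list
    haplotypes: dict  # sample_id -> (hap1, hap2) int8 arrays
    manifest: list  # list[PlantedSegment]
    panel: Panel


def _site_mask(sites: pd.DataFrame, chrom: str, start: int, end: int) -> np.ndarray:
    pos0 = sites["pos"].to_numpy() - 1
    return (sites["chrom"].to_numpy() == chrom) & (pos0 >= start) & (pos0 < end)


def simulate_truth(
    panel: Panel,
    n_individuals: int,
    roh_plan: Sequence[PlantedSegment] = (),
    ibd_plan: Sequence[PlantedSegment] = (),
    seed: int = 0,
    sample_prefix: str = "ind",
) -> TruthSet:
    """Draw diploid truth individuals and plant the requested segments.

    Each individual is two fresh mosaic haplotypes over the panel.  Inside a
    planted ROH the second haplotype is overwritten by the first (exact
    homozygosity).  Inside a planted IBD tract both members of the pair have
    their first haplotype overwritten by a common donor haplotype.
    """
    rng = np.random.default_rng(seed)
    sites = panel.sites
    chrom_codes = pd.factorize(sites["chrom"].to_numpy())[0]
    cm_pos = sites["cm"].to_numpy()
    sample_ids = [f"{sample_prefix}{i}" for i in range(n_individuals)]

    per_sample_roh: dict[str, list[PlantedSegment]] = {}
    for seg in roh_plan:
        per_sample_roh.setdefault(seg.samples[0], []).append(seg)
    for s, segs in per_sample_roh.items():
        segs = sorted((x for x in segs), key=lambda x: (x.chrom, x.start))
        for a, b in zip(segs, segs[1:]):
            if a.chrom == b.chrom and b.start < a.end:
                raise ValueError(f"overlapping ROH plans for sample {s}")

    haps = {}
    for s in sample_ids:
        pair = _mosaic_haplotypes(
            rng, panel.haplotypes, 2, cm_pos, chrom_codes, panel.config.switch_rate_per_cm
        )
        haps[s] = (pair[0], pair[1])

    manifest: list[PlantedSegment] = []
    for seg in roh_plan:
        h1, h2 = haps[seg.samples[0]]
        m = _site_mask(sites, seg.chrom, seg.start, seg.end)
        h2[m] = h1[m]
        manifest.append(seg)
    for seg in ibd_plan:
        donor = seg.donor_hap
        if donor is None:
            donor = int(rng.integers(0, panel.n_haplotypes))
        m = _site_mask(sites, seg.chrom, seg.start, seg.end)
        for s in seg.samples:
            haps[s][0][m] = panel.haplotypes[donor][m]
        manifest.append(
            PlantedSegment(seg.kind, seg.samples, seg.chrom, seg.start, seg.end, donor)
        )

    callsets = [
        SampleCallset(s, sites, (haps[s][0] + haps[s][1]).astype(np.int8)) for s in sample_ids
    ]
    return TruthSet(callsets, haps, manifest, panel)


# ---------------------------------------------------------------------------
# imputation error model
# ---------------------------------------------------------------------------

def _default_p_wrong() -> dict:
    # per tranche: (p_wrong_het, p_wrong_hom) before coverage scaling;
    # rarer alleles impute worse, het errors dominate
    return {
        "(0,1]": (0.25, 0.080),
        "(1,2]": (0.15, 0.050),
        "(2,5]": (0.08, 0.030),
        "(5,10]": (0.05, 0.020),
        "(10,20]": (0.04, 0.015),
        "(20,50]": (0.03, 0.012),
        MONOMORPHIC: (0.25, 0.080),
    }


@dataclass
class ErrorModel:
    """MAF- and coverage-dependent imputation error model.

    A call at a site in tranche *t* with truth class *c* (het / hom) is wrong
    with probability ``p_wrong[t][c] * exp(-coverage_decay_k * coverage)``.
    Wrong hets become the major-allele homozygote; wrong homs become het with
    probability 0.8, else the opposite homozygote.  The max genotype
    probability of a call is ``0.5 + 0.5 * Beta(a, b)`` with separate Beta
    laws for correct and wrong calls (correct stochastically larger), so
    stricter GP thresholds preferentially drop wrong calls.
    """

    p_wrong: dict = field(default_factory=_default_p_wrong)
    coverage_decay_k: float = 2.0 * np.log(2.0)  # error halves per +0.5x
    gp_correct: tuple = (30.0, 1.0)
    gp_wrong: tuple = (4.0, 2.0)
    miss_rate: float = 0.02

    def __post_init__(self) -> None:
        for t, (ph, pm) in self.p_wrong.items():
            if not (0 <= ph <= 1 and 0 <= pm <= 1):
                raise ValueError(f"p_wrong[{t}] outside [0,1]")
        mc = self.gp_correct[0] / sum(self.gp_correct)
        mw = self.gp_wrong[0] / sum(self.gp_wrong)
        if mc <= mw:
            raise ValueError("gp_correct must stochastically dominate gp_wrong")

    @classmethod
    def uniform(cls, p_het: float, p_hom: float, **kw) -> "ErrorModel":
        """Same error rates in every tranche — handy for calibration studies."""
        pw = {t: (p_het, p_hom) for t in list(TRANCHE_LABELS) + [MONOMORPHIC]}
        return cls(p_wrong=pw, **kw)

    @classmethod
    def zero(cls) -> "ErrorModel":
        return cls.uniform(0.0, 0.0, miss_rate=0.0)

    def decay(self, coverage: float) -> float:
        return float(np.exp(-self.coverage_decay_k * coverage))

    def effective_p_wrong(self, tranche: str, gt_class: str, coverage: float) -> float:
        """Post-decay error probability for a stratum; gt_class in {het, hom}."""
        ph, pm = self.p_wrong[tranche]
        base = ph if gt_class == "het" else pm
        return min(base * self.decay(coverage), 1.0)


def simulate_imputed(
    truth: SampleCallset,
    error_model: ErrorModel,
    coverage: float,
    seed: int = 0,
) -> SampleCallset:
    """Corrupt a truth callset under the error model and attach GP triples."""
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng(seed)
    sites = truth.sites
    n = len(sites)
    tr = maf_tranches(sites["maf"].to_numpy())
    known = set(error_model.p_wrong)
    bad = set(np.unique(tr)) - known
    if bad:
        raise ValueError(f"unknown tranche(s) {sorted(bad)} in error model")
    p_het = np.array([error_model.p_wrong[t][0] for t in tr])
    p_hom = np.array([error_model.p_wrong[t][1] for t in tr])
    decay = error_model.decay(coverage)

    td = truth.dosage
    called = td != MISSING
    is_het = td == 1
    p_w = np.minimum(np.where(is_het, p_het, p_hom) * decay, 1.0)
    wrong = (rng.random(n) < p_w) & called

    alt_freq = sites["alt_freq"].to_numpy()
    major_hom = np.where(alt_freq < 0.5, 0, 2).astype(np.int8)  # ties -> hom-alt

    emitted = td.copy()
    wh = wrong & is_het
    emitted[wh] = major_hom[wh]
    whom = wrong & ~is_het & called
    to_het = rng.random(n) < 0.8
    emitted[whom & to_het] = 1
    flip = whom & ~to_het
    emitted[flip] = 2 - td[flip]

    a_c, b_c = error_model.gp_correct
    a_w, b_w = error_model.gp_wrong
    maxgp = 0.5 + 0.5 * np.where(
        wrong, rng.beta(a_w, b_w, size=n), rng.beta(a_c, b_c, size=n)
    )
    # runner-up class: the truth class when the call is wrong; otherwise the
    # most plausible alternative (major hom for a het call, het for a hom call)
    runner = np.where(wrong, td, np.where(emitted == 1, major_hom, 1)).astype(np.int8)
    runner = np.where(runner == emitted, (emitted + 1) % 3, runner).astype(np.int8)
    third = (3 - emitted - runner).astype(np.int8)

    gp = np.full((n, 3), 1.0 / 3.0)
    rows = np.flatnonzero(called)
    rest = 1.0 - maxgp
    gp[rows, emitted[rows]] = maxgp[rows]
    gp[rows, runner[rows]] = 0.9 * rest[rows]
    gp[rows, third[rows]] = 0.1 * rest[rows]

    dropped = rng.random(n) < error_model.miss_rate
    out = emitted.copy()
    out[dropped | ~called] = MISSING
    gp[dropped | ~called] = 1.0 / 3.0
    return SampleCallset(truth.sample_id, sites, out, gp)


def pseudohaploidize(truth: SampleCallset, coverage: float, seed: int = 0) -> SampleCallset:
    """Poisson-depth single-allele sampling: depth 0 is missing; otherwise one
    allele is drawn uniformly from the diploid genotype and recorded as the
    corresponding homozygous dosage."""
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng(seed)
    n = truth.n_sites
    depth = rng.poisson(coverage, size=n)
    pick_alt = rng.random(n) < 0.5
    td = truth.dosage
    out = np.where(td == 1, np.where(pick_alt, 2, 0), td).astype(np.int8)
    out[(depth == 0) | (td == MISSING)] = MISSING
    return SampleCallset(truth.sample_id, truth.sites, out)


# ---------------------------------------------------------------------------
# IBD segment tables
# ---------------------------------------------------------------------------

from .types import IbdSegment  # noqa: E402  (late import avoids cycle at module load)


def emit_ibd_tables(
    manifest: Sequence[PlantedSegment],
    gmap: GeneticMap,
    chrom_lengths: dict,
    n_runs: int = 3,
    split_prob: float = 0.3,
    jitter_cm: float = 0.2,
    lod_scale: float = 3.0,
    decoy_pairs: Sequence[tuple] = (),
    n_decoys_per_pair: int = 2,
    seed: int = 0,
) -> list[list[IbdSegment]]:
    """Emit noisy per-run IBD tables from the planted-segment manifest.

    Each planted tract appears in every run with uniform boundary jitter of
    up to ``jitter_cm`` per endpoint, and with probability ``split_prob`` is
    broken into two pieces separated by a gap < 0.6 cM (so downstream gap
    merging can reconstitute it).  Decoy negatives — segments shorter than
    3 cM with good LOD, and >=3 cM segments with LOD < 3 — are planted on
    ``decoy_pairs`` only, so positives and negatives never mix on one pair.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rng = np.random.default_rng(seed)
    runs: list[list[IbdSegment]] = []
    ibd_tracts = [m for m in manifest if m.kind == "IBD"]
    for _ in range(n_runs):
        table: list[IbdSegment] = []
        for seg in ibd_tracts:
            L = chrom_lengths[seg.chrom]
            c0 = gmap.cm(seg.chrom, seg.start) + rng.uniform(-jitter_cm, jitter_cm)
            c1 = gmap.cm(seg.chrom, seg.end) + rng.uniform(-jitter_cm, jitter_cm)
            b0 = int(np.clip(gmap.bp(seg.chrom, c0), 0, L - 2))
            b1 = int(np.clip(gmap.bp(seg.chrom, c1), b0 + 1, L))
            a, b = seg.samples
            lod = 3.0 + rng.exponential(lod_scale)
            if rng.random() < split_prob and (c1 - c0) > 1.5:
                mid = rng.uniform(c0 + 0.3 * (c1 - c0), c0 + 0.7 * (c1 - c0))
                gap = rng.uniform(0.05, 0.55)  # < 0.6 cM by construction
                m0 = int(gmap.bp(seg.chrom, mid))
                m1 = int(min(gmap.bp(seg.chrom, mid + gap), L))
                table.append(IbdSegment(a, b, seg.chrom, b0, m0, lod))
                table.append(IbdSegment(a, b, seg.chrom, m1, b1, lod))
            else:
                table.append(IbdSegment(a, b, seg.chrom, b0, b1, lod))
        for (a, b) in decoy_pairs:
            for _ in range(n_decoys_per_pair):
                chrom = list(chrom_lengths)[int(rng.integers(0, len(chrom_lengths)))]
                L = chrom_lengths[chrom]
                total_cm = gmap.cm(chrom, L)
                # short but confidently scored
                len_s = rng.uniform(0.5, min(2.5, 0.5 * total_cm))
                c0 = rng.uniform(0, total_cm - len_s)
                table.append(
                    IbdSegment(a, b, chrom, int(gmap.bp(chrom, c0)),
                               int(gmap.bp(chrom, c0 + len_s)),
                               3.0 + rng.exponential(lod_scale))
                )
                # long (where the chromosome allows) but weakly scored
                hi = min(8.0, 0.8 * total_cm)
                len_l = rng.uniform(min(4.0, 0.5 * hi), hi)
                c0 = rng.uniform(0, total_cm - len_l)
                table.append(
                    IbdSegment(a, b, chrom, int(gmap.bp(chrom, c0)),
                               int(gmap.bp(chrom, c0 + len_l)),
                               rng.uniform(0.2, 2.9))
                )
        runs.append(table)
    return runs
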