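"""Runs-of-homozygosity calling.

Two complementary callers are provided, mirroring the two standard tools of
the field, plus the fusion rule that mitigates their opposing biases:

* :func:`windowscan_roh` — a plink-style scanning-window caller.  Every
  window of ``window_snp`` consecutive SNPs is scored homozygous-compatible
  ("hit") when it has at most ``window_het`` heterozygotes and
  ``window_missing`` missing calls; a SNP passes when the fraction of hit
  windows covering it reaches ``window_threshold``; maximal passing runs are
  trimmed to homozygous non-missing ends, split at large physical gaps, and
  filtered by SNP count, physical length and SNP density.

* :func:`hmm_roh` — a two-state (autozygous / Hardy–Weinberg) hidden Markov
  model over called genotypes, with genotype-error emissions parameterised
  by a Phred score, distance-scaled transitions, a Viterbi segmentation,
  and a per-segment quality from forward–backward posteriors.

* :func:`fuse_roh` — long HMM segments (> 4 Mb by default) are unioned into
  the window-scan profile: the scan caller under-calls long ROHs at low SNP
  density while the HMM over-calls short ones, so the fusion keeps the scan
  caller's short-ROH specificity and the HMM's long-ROH sensitivity.

An exact Mann–Whitney U test (:func:`mwu_groups`) supports the comparison of
per-group cumulative ROH amounts at the tiny sample sizes typical of ancient
panels, where the normal approximation is unusable.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import MISSING, RohSegment, SampleCallset, merge_intervals, Interval

logger = logging.getLogger(__name__)


@dataclass
class WindowScanParams:
    """Scanning-window caller parameters (plink --homozyg dialect)."""

    window_snp: int = 50
    window_het: int = 1
    window_missing: int = 5
    window_threshold: float = 0.05
    min_snp: int = 200
    min_kb: float = 500.0
    max_density_kb_per_snp: float = 50.0
    max_gap_kb: float = 100.0

    def __post_init__(self) -> None:
        if self.window_het >= self.window_snp:
            raise ValueError("window_het must be < window_snp")
        for name in ("window_snp", "min_snp", "min_kb", "max_density_kb_per_snp", "max_gap_kb"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class HmmParams:
    """Two-state autozygosity HMM parameters.

    ``err_phred`` is the genotype error on the Phred scale (30 -> 1e-3);
    ``af_default`` fills in sites with unknown panel frequency; transition
    rates are per bp and capped at 0.49 after distance scaling.
    """

    err_phred: float = 30.0
    af_default: float = 0.4
    t_hw2az: float = 6.7e-8
    t_az2hw: float = 5e-9
    min_snp: int = 200
    min_qual: float = 10.0
    min_kb: float = 500.0


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, stop) index pairs (stop exclusive)."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(len(mask))
    return list(zip(starts, stops))


def _segment(sample: str, chrom: str, pos: np.ndarray, i: int, j: int, source: str,
             quality: Optional[float] = None) -> RohSegment:
    # inclusive SNP span [i, j] -> 0-based half-open [pos_i - 1, pos_j)
    return RohSegment(
        sample=sample,
        chrom=chrom,
        start=int(pos[i]) - 1,
        end=int(pos[j]),
        n_snps=j - i + 1,
        source=source,
        quality=quality,
    )


def windowscan_roh(callset: SampleCallset, params: Optional[WindowScanParams] = None) -> list[RohSegment]:
    """Scanning-window ROH caller for a single sample (sorted sites)."""
    p = params or WindowScanParams()
    out: list[RohSegment] = []
    chrom_arr = callset.sites["chrom"].to_numpy()
    pos_all = callset.sites["pos"].to_numpy()
    for chrom in pd.unique(chrom_arr):
        m = chrom_arr == chrom
        dos = callset.dosage[m]
        pos = pos_all[m]
        n = len(dos)
        w = p.window_snp
        if n < w:
            logger.info("windowscan_roh: %s has %d < %d SNPs; skipped", chrom, n, w)
            continue
        het = (dos == 1).astype(np.int64)
        mis = (dos == MISSING).astype(np.int64)
        ch = np.concatenate([[0], np.cumsum(het)])
        cm = np.concatenate([[0], np.cumsum(mis)])
        n_win = n - w + 1
        hit = ((ch[w:] - ch[:-w]) <= p.window_het) & ((cm[w:] - cm[:-w]) <= p.window_missing)
        # windows covering SNP j: indices [max(0, j-w+1), min(j, n_win-1)]
        chit = np.concatenate([[0], np.cumsum(hit.astype(np.int64))])
        j = np.arange(n)
        lo = np.maximum(0, j - w + 1)
        hi = np.minimum(j, n_win - 1)
        n_cov = hi - lo + 1
        n_hit = chit[hi + 1] - chit[lo]
        passing = n_hit.astype(float) / n_cov >= p.window_threshold - 1e-12
        hom = (dos == 0) | (dos == 2)
        for a, b in _runs(passing):
            for (i0, j0) in _split_at_gaps(pos, a, b - 1, p.max_gap_kb * 1000):
                i, jj = _trim_to_hom(hom, i0, j0)
                if i is None:
                    continue
                seg = _segment(callset.sample_id, chrom, pos, i, jj, "windowscan")
                kb = seg.length_bp / 1000.0
                if (
                    seg.n_snps >= p.min_snp
                    and kb >= p.min_kb
                    and kb / seg.n_snps <= p.max_density_kb_per_snp
                ):
                    out.append(seg)
    return out


def _split_at_gaps(pos: np.ndarray, i: int, j: int, max_gap_bp: float):
    """Split inclusive SNP-index run [i, j] wherever adjacent SNPs are more
    than ``max_gap_bp`` apart."""
    pieces = []
    start = i
    for k in range(i, j):
        if pos[k + 1] - pos[k] > max_gap_bp:
            pieces.append((start, k))
            start = k + 1
    pieces.append((start, j))
    return pieces


def _trim_to_hom(hom: np.ndarray, i: int, j: int):
    while i <= j and not hom[i]:
        i += 1
    while j >= i and not hom[j]:
        j -= 1
    return (None, None) if i > j else (i, j)


# ---------------------------------------------------------------------------
# HMM caller
# ---------------------------------------------------------------------------

_AZ, _HW = 0, 1


def _hmm_inputs(dos: np.ndarray, pos: np.ndarray, freqs: np.ndarray, p: HmmParams):
    """Log-emission and log-transition arrays over called sites only."""
    called = dos != MISSING
    dos, pos, freqs = dos[called], pos[called], freqs[called]
    if not (0.0 < p.af_default < 1.0):
        raise ValueError("af_default outside (0,1)")
    if ((freqs < 0) | (freqs > 1)).any():
        raise ValueError("site frequency outside [0,1]")
    # unknown or degenerate (monomorphic) frequencies fall back to the default
    usable = ~np.isnan(freqs) & (freqs > 0) & (freqs < 1)
    af = np.where(usable, freqs, p.af_default)
    e = 10 ** (-p.err_phred / 10.0)
    is_het = dos == 1
    p_het_hw = 2 * af * (1 - af) * (1 - e) + (1 - 2 * af * (1 - af)) * e
    log_emit = np.empty((len(dos), 2))
    log_emit[:, _AZ] = np.where(is_het, math.log(e), math.log1p(-e))
    log_emit[:, _HW] = np.where(is_het, np.log(p_het_hw), np.log1p(-p_het_hw))
    d = np.diff(pos).astype(float)
    p_hw2az = np.minimum(p.t_hw2az * d, 0.49)
    p_az2hw = np.minimum(p.t_az2hw * d, 0.49)
    # log_trans[k, a, b] = log P(state_{k+1}=b | state_k=a)
    log_trans = np.empty((len(d), 2, 2))
    log_trans[:, _AZ, _AZ] = np.log1p(-p_az2hw)
    log_trans[:, _AZ, _HW] = np.log(p_az2hw)
    log_trans[:, _HW, _AZ] = np.log(p_hw2az)
    log_trans[:, _HW, _HW] = np.log1p(-p_hw2az)
    return called, dos, pos, log_emit, log_trans


def viterbi_path(log_emit: np.ndarray, log_trans: np.ndarray) -> np.ndarray:
    """Maximum-probability state path for a 2-state chain (uniform start)."""
    n = log_emit.shape[0]
    delta = log_emit[0] + math.log(0.5)
    back = np.zeros((n, 2), dtype=np.int8)
    for k in range(1, n):
        cand = delta[:, None] + log_trans[k - 1]  # [from, to]
        back[k] = np.argmax(cand, axis=0)
        delta = cand[back[k], [0, 1]] + log_emit[k]
    path = np.empty(n, dtype=np.int8)
    path[-1] = int(np.argmax(delta))
    for k in range(n - 1, 0, -1):
        path[k - 1] = back[k, path[k]]
    return path


def forward_backward(log_emit: np.ndarray, log_trans: np.ndarray) -> np.ndarray:
    """Per-site posterior state probabilities (rows sum to 1)."""
    n = log_emit.shape[0]
    fwd = np.empty((n, 2))
    fwd[0] = log_emit[0] + math.log(0.5)
    for k in range(1, n):
        a = fwd[k - 1][:, None] + log_trans[k - 1]
        fwd[k] = log_emit[k] + np.logaddexp(a[0], a[1])
    bwd = np.zeros((n, 2))
    for k in range(n - 2, -1, -1):
        a = log_trans[k] + log_emit[k + 1] + bwd[k + 1]
        bwd[k] = np.logaddexp(a[:, 0], a[:, 1])
    post = fwd + bwd
    post -= post.max(axis=1, keepdims=True)
    post = np.exp(post)
    post /= post.sum(axis=1, keepdims=True)
    return post


def hmm_roh(
    callset: SampleCallset,
    site_freqs: Optional[np.ndarray] = None,
    params: Optional[HmmParams] = None,
) -> list[RohSegment]:
    """HMM ROH caller; ``site_freqs`` is the panel ALT frequency per site
    (defaults to the site table's ``alt_freq``; NaN falls back to
    ``af_default``).  Segment quality is ``-10 log10(1 - median posterior)``
    over the segment's sites, from forward–backward."""
    p = params or HmmParams()
    if site_freqs is None:
        site_freqs = callset.sites["alt_freq"].to_numpy()
    out: list[RohSegment] = []
    chrom_arr = callset.sites["chrom"].to_numpy()
    pos_all = callset.sites["pos"].to_numpy()
    for chrom in pd.unique(chrom_arr):
        m = chrom_arr == chrom
        dos = callset.dosage[m]
        if (dos != MISSING).sum() < 2:
            continue
        _, dos_c, pos_c, log_emit, log_trans = _hmm_inputs(
            dos, pos_all[m], np.asarray(site_freqs, float)[m], p
        )
        path = viterbi_path(log_emit, log_trans)
        post_az = forward_backward(log_emit, log_trans)[:, _AZ]
        for a, b in _runs(path == _AZ):
            med = float(np.median(post_az[a:b]))
            qual = -10.0 * math.log10(max(1.0 - med, 1e-12))
            seg = _segment(callset.sample_id, chrom, pos_c, a, b - 1, "hmm", qual)
            if (
                seg.n_snps >= p.min_snp
                and seg.quality > p.min_qual
                and seg.length_bp / 1000.0 >= p.min_kb
            ):
                out.append(seg)
    return out


# ---------------------------------------------------------------------------
# fusion and summaries
# ---------------------------------------------------------------------------

def fuse_roh(
    windowscan_segs: Sequence[RohSegment],
    hmm_segs: Sequence[RohSegment],
    long_threshold_bp: float = 4e6,
) -> list[RohSegment]:
    """Union long HMM segments (strictly > ``long_threshold_bp``) into the
    window-scan profile; touching/overlapping intervals merge.  Each fused
    segment records how many inputs it absorbed and their collapsed lengths."""
    selected = [s for s in hmm_segs if s.length_bp > long_threshold_bp]
    inputs = list(windowscan_segs) + selected
    if not inputs:
        return []
    samples = {s.sample for s in inputs}
    if len(samples) > 1:
        raise ValueError("fuse_roh expects segments of a single sample")
    sample = samples.pop()
    merged = merge_intervals([s.interval for s in inputs], touching=True)
    out = []
    for iv in merged:
        members = [s for s in inputs if s.chrom == iv.chrom and s.start < iv.end and iv.start < s.end]
        out.append(
            RohSegment(
                sample=sample,
                chrom=iv.chrom,
                start=iv.start,
                end=iv.end,
                n_snps=max(s.n_snps for s in members),
                source="merged",
                contributing_count=len(members),
                contributing_lengths=tuple(s.length_bp for s in members),
            )
        )
    return out


DEFAULT_BINS_MB = (0.5, 1.0, 2.0, 4.0, 8.0, math.inf)


def roh_summary(segments: Sequence[RohSegment], bins_mb: Sequence[float] = DEFAULT_BINS_MB) -> pd.DataFrame:
    """Per-sample cumulative Mb per length bin (left-open right-closed on the
    bin edges) plus the grand total; segments shorter than the first edge go
    to an explicit ``under`` bin."""
    edges = list(bins_mb)
    labels = [f"({edges[i]},{edges[i+1]}]" for i in range(len(edges) - 1)]
    rows: dict[str, dict[str, float]] = {}
    for s in segments:
        mb = s.length_bp / 1e6
        if mb <= edges[0]:
            label = "under"
        else:
            idx = int(np.searchsorted(edges, mb, side="left")) - 1
            label = labels[min(idx, len(labels) - 1)]
        rows.setdefault(s.sample, {k: 0.0 for k in ["under"] + labels})
        rows[s.sample][label] += mb
    out = []
    for sample, bins in rows.items():
        rec = {"sample": sample, **bins}
        rec["total_mb"] = sum(bins.values())
        out.append(rec)
    return pd.DataFrame(out, columns=["sample", "under"] + labels + ["total_mb"])


def downsample_sites(callset: SampleCallset, n: int, seed: int = 0) -> SampleCallset:
    """Uniform random subset of ``n`` non-missing sites, order preserved."""
    idx = np.flatnonzero(callset.dosage != MISSING)
    if n > len(idx):
        raise ValueError(f"requested {n} sites but only {len(idx)} are non-missing")
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(idx, size=n, replace=False))
    return callset.subset(keep)


# ---------------------------------------------------------------------------
# exact Mann-Whitney U
# ---------------------------------------------------------------------------

def mwu_counts(n: int, m: int) -> list[int]:
    """Exact null distribution of U for group sizes (n, m): ``counts[u]`` is
    the number of labelings with U = u, i.e. the coefficients of the Gaussian
    binomial [n+m choose n]_q.  Computed by integer DP (no overflow)."""
    if n < 0 or m < 0:
        raise ValueError("group sizes must be non-negative")
    top = n * m
    c = [0] * (top + 1)
    c[0] = 1
    # product over i = 1..n of (1 - q^(m+i)) / (1 - q^i), truncated at q^top
    # (safe: higher-order terms never feed back into lower coefficients)
    for i in range(1, n + 1):
        for u in range(i, top + 1):  # series 1/(1 - q^i)
            c[u] += c[u - i]
        for u in range(top, m + i - 1, -1):  # factor (1 - q^(m+i))
            c[u] -= c[u - (m + i)]
    return c


def mwu_groups(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[int, float]:
    """Directional exact Mann–Whitney test.

    U counts the pairs with ``a < b``; the one-tailed p-value is
    ``P(U' <= U)`` under the uniform-permutation null, from the exact
    distribution.  Ties across groups are refused (cumulative-Mb inputs are
    effectively continuous, so a tie signals a data problem)."""
    a = [float(x) for x in group_a]
    b = [float(x) for x in group_b]
    if not a or not b:
        raise ValueError("both groups must be non-empty")
    if set(a) & set(b):
        raise ValueError("tied values across groups are not supported")
    u = sum(1 for x in a for y in b if x < y)
    counts = mwu_counts(len(a), len(b))
    p = Fraction(sum(counts[: u + 1]), sum(counts))
    return u, float(p)


def mwu_pvalue(u: int, n: int, m: int) -> float:
    """Exact one-tailed ``P(U' <= u)`` for group sizes (n, m)."""
    counts = mwu_counts(n, m)
    if not (0 <= u <= n * m):
        raise ValueError(f"u must lie in [0, {n * m}]")
    return float(Fraction(sum(counts[: u + 1]), sum(counts)))
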