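"""Naive reference implementations and random-instance generators used to
validate the package's optimised code paths.

Everything here is deliberately slow and literal — explicit loops,
exhaustive path enumeration, direct recomputation — and shares no code with
the implementations it checks, so exact agreement on random instances is
strong evidence of correctness.
"""
from __future__ import annotations

import itertools
import math

import numpy as np


def brute_windowscan(dosage, pos, params):
    """Naive scanning-window ROH caller over one chromosome.

    Returns (start0, end, n_snps) tuples with 0-based half-open coordinates.
    ``dosage`` uses -1 for missing; ``pos`` is 1-based and sorted.
    """
    dosage = list(dosage)
    pos = list(pos)
    n = len(dosage)
    w = params.window_snp
    if n < w:
        return []
    hits = []
    for i in range(n - w + 1):
        window = dosage[i : i + w]
        hits.append(
            sum(1 for d in window if d == 1) <= params.window_het
            and sum(1 for d in window if d == -1) <= params.window_missing
        )
    passing = []
    for j in range(n):
        cov = [i for i in range(len(hits)) if i <= j <= i + w - 1]
        frac = sum(1 for i in cov if hits[i]) / len(cov)
        passing.append(frac >= params.window_threshold - 1e-12)
    runs = []
    j = 0
    while j < n:
        if passing[j]:
            k = j
            while k + 1 < n and passing[k + 1]:
                k += 1
            runs.append((j, k))
            j = k + 1
        else:
            j += 1
    out = []
    for (a, b) in runs:
        pieces, start = [], a
        for t in range(a, b):
            if pos[t + 1] - pos[t] > params.max_gap_kb * 1000:
                pieces.append((start, t))
                start = t + 1
        pieces.append((start, b))
        for (i, jj) in pieces:
            while i <= jj and dosage[i] not in (0, 2):
                i += 1
            while jj >= i and dosage[jj] not in (0, 2):
                jj -= 1
            if i > jj:
                continue
            n_snps = jj - i + 1
            length = pos[jj] - pos[i] + 1
            kb = length / 1000.0
            if (
                n_snps >= params.min_snp
                and kb >= params.min_kb
                and kb / n_snps <= params.max_density_kb_per_snp
            ):
                out.append((pos[i] - 1, pos[jj], n_snps))
    return out


def exhaustive_hmm_best_path(dosage, pos, af, params):
    """Best 2-state path by brute-force enumeration of all 2^L paths
    (state 0 = autozygous, 1 = Hardy-Weinberg; uniform start)."""
    dosage = np.asarray(dosage)
    pos = np.asarray(pos, dtype=float)
    af = np.asarray(af, dtype=float)
    L = len(dosage)
    assert L <= 14, "exhaustive search only for tiny instances"
    e = 10 ** (-params.err_phred / 10.0)
    p_het_hw = 2 * af * (1 - af) * (1 - e) + (1 - 2 * af * (1 - af)) * e
    le = np.empty((L, 2))
    for k in range(L):
        if dosage[k] == 1:
            le[k] = (math.log(e), math.log(p_het_hw[k]))
        else:
            le[k] = (math.log(1 - e), math.log(1 - p_het_hw[k]))
    d = np.diff(pos)
    p_hw2az = np.minimum(params.t_hw2az * d, 0.49)
    p_az2hw = np.minimum(params.t_az2hw * d, 0.49)
    lt = np.empty((L - 1, 2, 2))
    lt[:, 0, 0] = np.log(1 - p_az2hw)
    lt[:, 0, 1] = np.log(p_az2hw)
    lt[:, 1, 0] = np.log(p_hw2az)
    lt[:, 1, 1] = np.log(1 - p_hw2az)
    best, best_lp = None, -np.inf
    for path in itertools.product((0, 1), repeat=L):
        lp = math.log(0.5) + le[0, path[0]]
        for k in range(1, L):
            lp += lt[k - 1, path[k - 1], path[k]] + le[k, path[k]]
        if lp > best_lp:
            best_lp, best = lp, path
    return np.array(best), best_lp


def mwu_enumerate_p(u, n, m):
    """P(U' <= u) by exhaustive enumeration of all C(n+m, n) labelings of
    the ranks 0..n+m-1 (group A gets the chosen ranks; U counts a < b)."""
    total = 0
    at_most = 0
    ranks = range(n + m)
    for a_ranks in itertools.combinations(ranks, n):
        a_set = set(a_ranks)
        u_stat = sum(1 for x in a_ranks for y in ranks if y not in a_set and x < y)
        total += 1
        if u_stat <= u:
            at_most += 1
    return at_most / total


def direct_jackknife(values, block_codes, n_blocks):
    """Leave-one-block estimates by literal recomputation."""
    values = np.asarray(values, float)
    block_codes = np.asarray(block_codes)
    return np.array(
        [values[block_codes != j].mean() for j in range(n_blocks)]
    )


# ---------------------------------------------------------------------------
# random-instance generators for oracle sweeps
# ---------------------------------------------------------------------------

def random_windowscan_instance(rng):
    """A random <=500-SNP chromosome with blocky genotypes (so homozygous
    stretches occur) and a randomised caller parameterisation; returns
    (dosage, pos, params_kwargs)."""
    n = int(rng.integers(30, 501))
    spacing = rng.integers(500, 4000, size=n)
    pos = np.cumsum(spacing)
    dosage = np.empty(n, dtype=np.int8)
    i = 0
    while i < n:
        L = int(rng.integers(5, 120))
        kind = rng.random()
        if kind < 0.5:
            block = rng.choice([0, 2], size=L)
        elif kind < 0.8:
            block = rng.choice([0, 1, 2], size=L)
        else:
            block = rng.choice([0, 2, -1], size=L, p=[0.45, 0.45, 0.1])
        dosage[i : i + len(block[: n - i])] = block[: n - i]
        i += L
    params = dict(
        window_snp=int(rng.integers(10, 40)),
        window_het=int(rng.integers(0, 3)),
        window_missing=int(rng.integers(0, 5)),
        window_threshold=float(rng.choice([0.02, 0.05, 0.1])),
        min_snp=int(rng.integers(10, 60)),
        min_kb=float(rng.integers(5, 60)),
        max_density_kb_per_snp=50.0,
        max_gap_kb=float(rng.integers(20, 200)),
    )
    return dosage, pos, params


def random_hmm_instance(rng, max_sites=12):
    """A random tiny HMM instance: genotypes, positions, frequencies, and a
    randomised parameterisation; returns (dosage, pos, af, params_kwargs)."""
    L = int(rng.integers(2, max_sites + 1))
    dosage = rng.choice([0, 1, 2], size=L, p=[0.4, 0.2, 0.4]).astype(np.int8)
    pos = np.cumsum(rng.integers(200, 500_000, size=L))
    af = rng.uniform(0.05, 0.95, size=L)
    params = dict(
        err_phred=float(rng.uniform(10, 40)),
        t_hw2az=10 ** rng.uniform(-9, -6),
        t_az2hw=10 ** rng.uniform(-10, -7),
    )
    return dosage, pos, af, params
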