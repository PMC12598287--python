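"""Post-processing of pairwise IBD segment tables: combining repeated
detection runs, merging gapped segments in genetic-map (cM) space, binary
relatedness classification, and group-level relatedness summaries.

Segment *detection* is out of scope — the tables come from an external
detector (or the simulator); everything here consumes its output.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .types import GeneticMap, IbdSegment, Interval

#: chr18 starts with a putative assembly artifact (huge apparent
#: recombination rate); excluded by default in real-data runs.
DEFAULT_EXCLUDE = (Interval("chr18", 0, 2_000_000),)

PairKey = frozenset


@dataclass
class RelatednessCriteria:
    """A pair is related when it shares at least ``min_segments`` IBD segments
    each longer than ``min_segment_cm`` (strict), whose summed length reaches
    ``min_total_cm`` (inclusive)."""

    min_segments: int = 3
    min_segment_cm: float = 3.0
    min_total_cm: float = 21.0

    def __post_init__(self) -> None:
        if min(self.min_segments, self.min_segment_cm, self.min_total_cm) <= 0:
            raise ValueError("all criteria must be positive")


def _clip_excluded(seg: IbdSegment, exclude: Sequence[Interval]) -> Optional[IbdSegment]:
    """Truncate a segment against exclusion regions; drop it if swallowed."""
    s, e = seg.start_bp, seg.end_bp
    for r in exclude:
        if r.chrom != seg.chrom or e <= r.start or s >= r.end:
            continue
        # keep the larger remaining flank
        left = (s, min(e, r.start))
        right = (max(s, r.end), e)
        s, e = max((left, right), key=lambda t: t[1] - t[0])
        if e - s <= 0:
            return None
    if (s, e) == (seg.start_bp, seg.end_bp):
        return seg
    return IbdSegment(seg.sample_a, seg.sample_b, seg.chrom, s, e, seg.lod)


def combine_runs(
    run_tables: Sequence[Sequence[IbdSegment]],
    gmap: GeneticMap,
    lod_min: float = 3.0,
    len_min_cm: float = 3.0,
    exclude: Sequence[Interval] = (),
) -> Dict[PairKey, list[IbdSegment]]:
    """Combine repeated detection runs into per-pair segment sets.

    Records with LOD below ``lod_min`` are dropped before anything else, and
    exclusion regions are clipped out.  Surviving segments are unioned per
    (pair, chromosome) across runs; each union segment is then measured on
    the genetic map and kept only if at least ``len_min_cm`` long.  The LOD
    carried by a union segment is the maximum among its contributors.
    """
    if not run_tables:
        raise ValueError("need at least one run table")
    by_key: Dict[tuple, list[IbdSegment]] = {}
    for table in run_tables:
        for seg in table:
            if seg.lod is not None and seg.lod < lod_min:
                continue
            clipped = _clip_excluded(seg, exclude)
            if clipped is None:
                continue
            by_key.setdefault((clipped.pair, clipped.chrom), []).append(clipped)
    out: Dict[PairKey, list[IbdSegment]] = {}
    for (pair, chrom), segs in by_key.items():
        segs.sort(key=lambda s: (s.start_bp, s.end_bp))
        merged: list[list] = []
        for s in segs:
            if merged and s.start_bp <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], s.end_bp)
                merged[-1][2] = max(merged[-1][2], s.lod or 0.0)
            else:
                merged.append([s.start_bp, s.end_bp, s.lod or 0.0])
        a, b = sorted(pair)
        for (s0, s1, lod) in merged:
            seg = IbdSegment(a, b, chrom, s0, s1, lod).with_cm(gmap)
            if seg.length_cm >= len_min_cm:
                out.setdefault(pair, []).append(seg)
    for pair in out:
        out[pair].sort(key=lambda s: (s.chrom, s.start_bp))
    return out


def merge_pair_segments(
    segments: Sequence[IbdSegment],
    max_gap_cm: float = 0.6,
) -> list[IbdSegment]:
    """Merge consecutive same-chromosome segments of one pair whose cM gap is
    strictly below ``max_gap_cm``; a gap of exactly ``max_gap_cm`` does not
    merge."""
    out: list[IbdSegment] = []
    by_chrom: Dict[tuple, list[IbdSegment]] = {}
    for s in segments:
        by_chrom.setdefault((s.pair, s.chrom), []).append(s)
    for (_, _), segs in sorted(by_chrom.items(), key=lambda kv: (sorted(kv[0][0]), kv[0][1])):
        segs = sorted(segs, key=lambda s: s.start_cm)
        cur = segs[0]
        for s in segs[1:]:
            # strict <, with an epsilon so a gap of exactly max_gap_cm never
            # merges through interpolation round-off
            if s.start_cm - cur.end_cm < max_gap_cm - 1e-9:
                cur = IbdSegment(
                    cur.sample_a, cur.sample_b, cur.chrom,
                    cur.start_bp, max(cur.end_bp, s.end_bp),
                    max(cur.lod or 0.0, s.lod or 0.0),
                    cur.start_cm, max(cur.end_cm, s.end_cm),
                )
            else:
                out.append(cur)
                cur = s
        out.append(cur)
    return out


def classify_related(
    pair_segments: Sequence[IbdSegment],
    criteria: Optional[RelatednessCriteria] = None,
) -> bool:
    """Binary relatedness call for one pair from its (post-merge) segments."""
    c = criteria or RelatednessCriteria()
    qualifying = [s for s in pair_segments if s.length_cm > c.min_segment_cm]
    return len(qualifying) >= c.min_segments and sum(
        s.length_cm for s in qualifying
    ) >= c.min_total_cm


def normalized_relatedness(
    group_samples: Sequence[str],
    pair_related: Dict[PairKey, bool],
    pair_fraction: bool = False,
) -> float:
    """Within-group relatedness summary for groups of at least three samples.

    Default (individual fraction): the share of group members with at least
    one related partner inside the group — 1 means every individual has a
    relative in the group, 0 means none does.  ``pair_fraction=True`` instead
    returns related pairs over all pairs.
    """
    group = list(group_samples)
    if len(group) < 3:
        raise ValueError("normalized relatedness requires a group of >= 3 samples")
    members = set(group)
    if pair_fraction:
        n_pairs = len(group) * (len(group) - 1) // 2
        n_rel = sum(
            1 for pair, rel in pair_related.items() if rel and pair <= members and len(pair) == 2
        )
        return n_rel / n_pairs
    has_relative = {s: False for s in group}
    for pair, rel in pair_related.items():
        if rel and len(pair) == 2 and pair <= members:
            for s in pair:
                has_relative[s] = True
    return sum(has_relative.values()) / len(group)


def between_group_ibd(
    groups: Dict[str, Sequence[str]],
    pair_segments: Dict[PairKey, Sequence[IbdSegment]],
) -> pd.DataFrame:
    """Symmetric matrix of cumulative shared IBD (cM) between groups; the
    diagonal holds within-group totals.  Groups must be disjoint."""
    names = list(groups)
    seen: set = set()
    for g in names:
        s = set(groups[g])
        if s & seen:
            raise ValueError("groups must be disjoint")
        seen |= s
    member_of = {s: g for g in names for s in groups[g]}
    mat = pd.DataFrame(0.0, index=names, columns=names)
    for pair, segs in pair_segments.items():
        if len(pair) != 2:
            continue
        a, b = sorted(pair)
        ga, gb = member_of.get(a), member_of.get(b)
        if ga is None or gb is None:
            continue
        total = sum(s.length_cm for s in segs)
        mat.loc[ga, gb] += total
        if ga != gb:
            mat.loc[gb, ga] += total
    return mat


def pair_table(pair_segments: Dict[PairKey, Sequence[IbdSegment]]) -> pd.DataFrame:
    """Tidy per-pair summary: segment count, cumulative cM, max segment."""
    rows = []
    for pair, segs in pair_segments.items():
        a, b = sorted(pair)
        lens = [s.length_cm for s in segs]
        rows.append(
            {
                "sample_a": a,
                "sample_b": b,
                "n_segments": len(segs),
                "total_cm": sum(lens),
                "max_cm": max(lens) if lens else 0.0,
            }
        )
    return pd.DataFrame(rows, columns=["sample_a", "sample_b", "n_segments", "total_cm", "max_cm"])
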