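"""Evaluation metrics: island read coverage, base-pair overlap fractions,
and cumulative motif occurrence along ranked peaks."""

from __future__ import annotations

import logging
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from .io_formats import ReadTable, RegionCall

logger = logging.getLogger(__name__)

Interval = Tuple[str, int, int]


def _merge_intervals(intervals: Sequence[Interval]) -> List[Interval]:
    """Sort and merge overlapping/adjacent intervals per chromosome."""
    out: List[Interval] = []
    for chrom in sorted({c for c, _, _ in intervals}):
        sub = sorted((s, e) for c, s, e in intervals if c == chrom)
        cur_s, cur_e = sub[0]
        for s, e in sub[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return out


def _regions_to_intervals(regions) -> List[Interval]:
    if isinstance(regions, pd.DataFrame):
        return list(zip(regions["chrom"], regions["start"], regions["end"]))
    return [(r.chrom, r.start, r.end) for r in regions]


def island_read_coverage(islands, reads: ReadTable) -> float:
    """Fraction of reads whose midpoint lies inside a called island.

    Used to match operating points between callers: a caller covering the
    same read mass with fewer, longer islands is preferable for diffuse
    marks.
    """
    if len(reads) == 0:
        raise ValueError("no reads supplied")
    merged = _merge_intervals(_regions_to_intervals(islands)) if len(islands) else []
    if not merged:
        return 0.0
    mids = reads.assign(mid=(reads["start"] + reads["end"]) // 2)
    inside = 0
    for chrom, sub in mids.groupby("chrom"):
        starts = np.array([s for c, s, e in merged if c == chrom])
        ends = np.array([e for c, s, e in merged if c == chrom])
        if len(starts) == 0:
            continue
        m = sub["mid"].to_numpy(np.int64)
        k = np.searchsorted(starts, m, side="right") - 1
        valid = k >= 0
        inside += int((m[valid] < ends[k[valid]]).sum())
    return inside / len(reads)


def _overlap_bp(start: int, end: int, features: Sequence[Tuple[int, int]]) -> int:
    total = 0
    for fs, fe in features:
        total += max(0, min(end, fe) - max(start, fs))
    return total


def overlap_fraction(islands, features) -> float:
    """Mean per-island fraction of bases intersecting a feature set.

    Islands with zero feature overlap are filtered out first; each
    remaining island contributes (overlapping bp) / (island bp), and the
    unweighted mean of these ratios is returned.  Note the measure is
    island-centric: swapping islands and features changes the answer.
    Returns 0 (with a warning) when no island overlaps any feature.
    """
    feats = _merge_intervals(_regions_to_intervals(features)) if len(features) else []
    by_chrom: dict = {}
    for chrom, s, e in feats:
        by_chrom.setdefault(chrom, []).append((s, e))
    ratios = []
    for chrom, s, e in _regions_to_intervals(islands):
        ov = _overlap_bp(s, e, by_chrom.get(chrom, []))
        if ov > 0:
            ratios.append(ov / (e - s))
    if not ratios:
        logger.warning("no island overlaps any feature; overlap fraction reported as 0")
        return 0.0
    return float(np.mean(ratios))


def cumulative_motif_rate(
    ranked_peaks: Sequence[RegionCall],
    motif_hits,
    flank: int = 150,
) -> np.ndarray:
    """Cumulative fraction of summit-proximal motif matches along the ranking.

    Peak r counts as a match when the window [summit - flank,
    summit + flank] intersects at least one motif interval; the curve
    value at rank r is (matches among the top r) / r.  Peaks must carry
    summits (TF mode).
    """
    hits = _merge_intervals(_regions_to_intervals(motif_hits)) if len(motif_hits) else []
    by_chrom: dict = {}
    for chrom, s, e in hits:
        by_chrom.setdefault(chrom, []).append((s, e))
    matched = []
    for peak in ranked_peaks:
        if peak.summit is None:
            raise ValueError("cumulative_motif_rate requires peaks with summits")
        lo, hi = peak.summit - flank, peak.summit + flank + 1
        matched.append(_overlap_bp(lo, hi, by_chrom.get(peak.chrom, [])) > 0)
    if not matched:
        return np.empty(0)
    return np.cumsum(matched) / np.arange(1, len(matched) + 1)


def base_overlap_stats(called, truth) -> Tuple[int, int, int]:
    """(called bp, truth bp, intersection bp) over merged interval sets."""
    called_m = _merge_intervals(_regions_to_intervals(called)) if len(called) else []
    truth_m = _merge_intervals(_regions_to_intervals(truth)) if len(truth) else []
    called_bp = sum(e - s for _, s, e in called_m)
    truth_bp = sum(e - s for _, s, e in truth_m)
    inter = 0
    by_chrom: dict = {}
    for chrom, s, e in truth_m:
        by_chrom.setdefault(chrom, []).append((s, e))
    for chrom, s, e in called_m:
        inter += _overlap_bp(s, e, by_chrom.get(chrom, []))
    return called_bp, truth_bp, inter
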