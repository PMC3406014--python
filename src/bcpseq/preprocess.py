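"""Read-to-count transformation.

Raw aligned reads become the model's observation sequence in two flavours:

* **TF mode** — reads are shifted towards the fragment centre by half the
  estimated plus/minus strand offset; per-base coverage of the shifted
  reads is intrinsically piecewise constant, and each maximal run of equal
  coverage becomes one block with its common count as the observation.
  Block widths are therefore data-driven.
* **HM mode** — reads are extended from their 5' end to the expected
  fragment length; coverage is averaged over fixed windows (default 200 bp,
  roughly one nucleosome unit) and rounded to the nearest integer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .io_formats import ReadTable

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 200
DEFAULT_FRAGMENT_LENGTH = 200


@dataclass
class CountTrack:
    """Per-block integer observations for one chromosome.

    ``edges`` has length ``n_blocks + 1``; block *t* spans
    ``[edges[t], edges[t+1])`` and carries count ``counts[t]``.  Blocks
    tile ``[0, span)`` contiguously.  In TF mode adjacent blocks always
    carry different counts (runs are maximal); in HM mode all blocks have
    width ``window`` except possibly the last.
    """

    chrom: str
    edges: np.ndarray
    counts: np.ndarray
    mode: str
    window: Optional[int] = None

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.edges.ndim != 1 or len(self.edges) != len(self.counts) + 1:
            raise ValueError("edges must have length n_blocks + 1")
        if len(self.counts) == 0:
            raise ValueError("track must contain at least one block")
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("blocks must have positive width and be sorted")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.mode not in ("tf", "hm"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def n_blocks(self) -> int:
        return len(self.counts)

    @property
    def span(self) -> int:
        return int(self.edges[-1])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.edges)


def deduplicate(reads: ReadTable) -> ReadTable:
    """Retain at most one read per identical (chrom, start, end, strand).

    Collapsing exact duplicates guards against spurious PCR amplification
    towers.  Input order is preserved.
    """
    if len(reads) == 0:
        return reads
    return reads.drop_duplicates(subset=["chrom", "start", "end", "strand"]).reset_index(drop=True)


def _five_prime_positions(reads: ReadTable) -> Tuple[np.ndarray, np.ndarray]:
    """5' end positions per strand: plus reads at ``start``, minus at ``end - 1``."""
    plus = reads.loc[reads["strand"] == "+", "start"].to_numpy(np.int64)
    minus = (reads.loc[reads["strand"] == "-", "end"].to_numpy(np.int64)) - 1
    return plus, minus


def _local_maxima(density: np.ndarray) -> np.ndarray:
    """Centres of maximal equal-value runs that exceed both neighbouring runs.

    Plateau-aware: smoothing turns a point spike into a flat-topped run,
    and taking the run centre keeps the maximum at the spike position
    instead of the plateau edge.
    """
    n = len(density)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    change = np.nonzero(np.diff(density))[0] + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [n]])
    vals = density[starts]
    left_ok = np.concatenate([[True], vals[1:] > vals[:-1]])
    right_ok = np.concatenate([vals[:-1] > vals[1:], [True]])
    mask = left_ok & right_ok & (vals > 0)
    return ((starts + ends - 1) // 2)[mask].astype(np.int64)


def _smooth(density: np.ndarray, width: int) -> np.ndarray:
    kernel = np.ones(width) / width
    return np.convolve(density.astype(np.float64), kernel, mode="same")


def estimate_shift(
    reads: ReadTable,
    max_pair_distance: int = 500,
    n_top: int = 1000,
    min_pairs: int = 10,
    fragment_length: int = DEFAULT_FRAGMENT_LENGTH,
    smooth_width: int = 21,
) -> int:
    """Estimate the TF read shift from the plus/minus strand offset.

    Sequenced reads sit at fragment ends, so 5'-end densities around a
    binding site form a bimodal profile: a plus-strand mode upstream and a
    minus-strand mode roughly one fragment length downstream.  The shift
    that re-centres reads on the fragment midpoint is half that offset.

    Procedure: smooth both strands' 5'-end densities with a
    ``smooth_width`` bp boxcar (so isolated background reads do not rank
    as maxima after duplicate removal flattens true pile-ups); take the
    ``n_top`` highest plus-strand local maxima; pair each with the
    highest-density minus-strand local maximum at most
    ``max_pair_distance`` bp downstream (nearest on ties — pairing to the
    strongest rather than the nearest maximum avoids a downward bias of
    half the site jitter); return ``round(median(pair distance) / 2)``.
    With fewer than ``min_pairs`` pairable maxima the estimate falls back
    to ``fragment_length // 2`` with a logged warning.
    """
    plus, minus = _five_prime_positions(reads)
    if len(plus) == 0 or len(minus) == 0:
        logger.warning(
            "shift estimation needs both strands; falling back to fragment_length/2 = %d",
            fragment_length // 2,
        )
        return fragment_length // 2
    # pad past the last 5' end so smoothing plateaus are not clipped at the edge
    span = int(max(plus.max(), minus.max())) + smooth_width + 1
    plus_density = _smooth(np.bincount(plus, minlength=span), smooth_width)
    minus_density = _smooth(np.bincount(minus, minlength=span), smooth_width)
    plus_peaks = _local_maxima(plus_density)
    minus_peaks = _local_maxima(minus_density)
    if len(plus_peaks) > n_top:
        order = np.argsort(plus_density[plus_peaks], kind="stable")[::-1]
        plus_peaks = np.sort(plus_peaks[order[:n_top]])
    distances = []
    for p in plus_peaks:
        lo = np.searchsorted(minus_peaks, p + 1)
        hi = np.searchsorted(minus_peaks, p + max_pair_distance, side="right")
        if lo < hi:
            window = minus_peaks[lo:hi]
            best = window[np.argmax(minus_density[window])]
            distances.append(int(best - p))
    if len(distances) < min_pairs:
        logger.warning(
            "only %d pairable strand maxima (<%d); falling back to fragment_length/2 = %d",
            len(distances), min_pairs, fragment_length // 2,
        )
        return fragment_length // 2
    # round half away from zero
    return int(np.floor(np.median(distances) / 2.0 + 0.5))


def shift_reads(reads: ReadTable, shift: int) -> ReadTable:
    """Shift plus-strand reads +shift and minus-strand reads -shift bp.

    Reads that would cross position 0 are translated to start at 0 with
    their width preserved.  Used both to build the TF count track and to
    count reads in called regions, so observations and regions share one
    coordinate frame.
    """
    if shift < 0:
        raise ValueError("shift must be non-negative")
    out = reads.copy()
    is_plus = (out["strand"] == "+").to_numpy()
    delta = np.where(is_plus, shift, -shift)
    starts = out["start"].to_numpy(np.int64) + delta
    ends = out["end"].to_numpy(np.int64) + delta
    width = ends - starts
    starts = np.maximum(starts, 0)
    out["start"] = starts
    out["end"] = starts + width
    return out.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)


def _coverage_diff(starts: np.ndarray, ends: np.ndarray, span: int) -> np.ndarray:
    """Coverage difference array over [0, span); cumsum gives per-base depth."""
    diff = np.zeros(span + 1, dtype=np.int64)
    np.add.at(diff, np.clip(starts, 0, span), 1)
    np.add.at(diff, np.clip(ends, 0, span), -1)
    return diff


def build_tf_track(reads: ReadTable, shift: int, span: Optional[int] = None) -> CountTrack:
    """Block the per-base coverage of shifted reads into a TF CountTrack.

    Plus-strand reads are shifted ``+shift`` and minus-strand reads
    ``-shift`` (clipped at 0) so the read-density mode falls at the
    fragment centre.  Maximal runs of equal coverage become blocks; zero
    blocks are kept so the track tiles ``[0, span)``.
    """
    if shift < 0:
        raise ValueError("shift must be non-negative")
    if len(reads) == 0:
        return CountTrack(chrom="", edges=np.array([0, max(span or 1, 1)]), counts=np.array([0]), mode="tf")
    chrom = reads["chrom"].iloc[0]
    shifted = shift_reads(reads, shift)
    starts = shifted["start"].to_numpy(np.int64)
    ends = shifted["end"].to_numpy(np.int64)
    track_span = int(span) if span is not None else int(ends.max())
    diff = _coverage_diff(starts, ends, track_span)
    coverage = np.cumsum(diff[:-1])
    change = np.nonzero(np.diff(coverage))[0] + 1
    edges = np.concatenate([[0], change, [track_span]])
    counts = coverage[edges[:-1]]
    return CountTrack(chrom=chrom, edges=edges, counts=counts, mode="tf")


def extend_reads(reads: ReadTable, fragment_length: int) -> Tuple[np.ndarray, np.ndarray]:
    """Extend each read from its 5' end to ``fragment_length`` in strand direction."""
    starts = reads["start"].to_numpy(np.int64)
    ends = reads["end"].to_numpy(np.int64)
    is_plus = (reads["strand"] == "+").to_numpy()
    ext_start = np.where(is_plus, starts, ends - fragment_length)
    ext_end = np.where(is_plus, starts + fragment_length, ends)
    ext_start = np.maximum(ext_start, 0)
    return ext_start, ext_end


def build_hm_track(
    reads: ReadTable,
    fragment_length: int = DEFAULT_FRAGMENT_LENGTH,
    window: int = DEFAULT_WINDOW,
    span: Optional[int] = None,
) -> CountTrack:
    """Window-average the coverage of fragment-extended reads (HM mode).

    Each read is extended from its 5' end to ``fragment_length``; the
    per-base coverage is averaged over consecutive ``window``-bp windows
    starting at position 0 and rounded to the nearest integer (half away
    from zero).  The last window may be shorter than ``window``.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if len(reads) == 0:
        return CountTrack(
            chrom="", edges=np.array([0, max(span or window, 1)]), counts=np.array([0]),
            mode="hm", window=window,
        )
    read_len = int((reads["end"] - reads["start"]).max())
    if fragment_length < read_len:
        raise ValueError(f"fragment_length {fragment_length} < read length {read_len}")
    chrom = reads["chrom"].iloc[0]
    ext_start, ext_end = extend_reads(reads, fragment_length)
    track_span = int(span) if span is not None else int(ext_end.max())
    diff = _coverage_diff(ext_start, ext_end, track_span)
    coverage = np.cumsum(diff[:-1]).astype(np.float64)
    n_blocks = int(np.ceil(track_span / window))
    window_edges = np.minimum(np.arange(n_blocks + 1, dtype=np.int64) * window, track_span)
    sums = np.add.reduceat(coverage, window_edges[:-1])
    widths = np.diff(window_edges)
    means = sums / widths
    counts = np.floor(means + 0.5).astype(np.int64)  # half away from zero
    return CountTrack(chrom=chrom, edges=window_edges, counts=counts, mode="hm", window=window)


def split_by_chrom(reads: ReadTable):
    """Yield (chrom, sub-table) in lexicographic chromosome order."""
    for chrom, sub in reads.groupby("chrom", sort=True):
        yield chrom, sub.reset_index(drop=True)
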