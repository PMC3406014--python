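"""Synthetic data: model-generated count tracks and BED read sets.

Two layers of simulation support the test pyramid:

* :func:`simulate_track` draws directly from the generative model
  (Bernoulli change points, Gamma levels, Poisson counts) and is the
  ground truth for inference-recovery tests;
* :func:`simulate_reads` emits stranded sequencing reads from a
  piecewise-constant fragment-density profile — enriched segments over a
  uniform background — reproducing the plus/minus bimodal offset around
  sites that the shift estimator must recover, plus a matched uniform
  input control.

One integer seed controls all randomness; identical seeds give
byte-identical BED output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io_formats import ReadTable, reads_from_arrays
from .model import ModelParams
from .preprocess import CountTrack


@dataclass(frozen=True)
class SimProfile:
    """Piecewise-constant enrichment profile for read simulation.

    ``segments`` are disjoint (start, end, density) triples with density
    in expected fragments per bp; everywhere else fragment starts arrive
    at ``background_density``.  Control samples ignore the segments.
    """

    chrom: str = "chrSim"
    chrom_span: int = 2_000_000
    segments: Tuple[Tuple[int, int, float], ...] = ()
    background_density: float = 0.005
    fragment_length: int = 200
    read_length: int = 36

    def __post_init__(self) -> None:
        prev_end = 0
        for start, end, dens in sorted(self.segments):
            if not (0 <= start < end <= self.chrom_span):
                raise ValueError("segment outside chromosome span")
            if start < prev_end:
                raise ValueError("segments must be disjoint")
            if dens <= 0:
                raise ValueError("segment density must be positive")
            prev_end = end
        if self.background_density <= 0:
            raise ValueError("background density must be positive")


def simulate_track(
    n: int, params: ModelParams, seed: int, window: int = 200
) -> Tuple[np.ndarray, CountTrack]:
    """Draw (lambda sequence, CountTrack) from the generative model.

    Block 1 starts a segment; each later boundary changes level with
    probability p, drawing the new level from Gamma(alpha, beta); counts
    are Poisson given the level.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    changes = np.empty(n, dtype=bool)
    changes[0] = True
    changes[1:] = rng.random(n - 1) < params.p
    n_seg = int(changes.sum())
    levels = rng.gamma(shape=params.alpha, scale=1.0 / params.beta, size=n_seg)
    lam = levels[np.cumsum(changes) - 1]
    counts = rng.poisson(lam)
    edges = np.arange(n + 1, dtype=np.int64) * window
    return lam, CountTrack("chrSim", edges, counts, "hm", window)


def _density_pieces(profile: SimProfile, is_control: bool):
    """Non-overlapping (start, end, density) pieces covering the whole span."""
    pieces: List[Tuple[int, int, float]] = []
    pos = 0
    segs = () if is_control else tuple(sorted(profile.segments))
    for start, end, dens in segs:
        if start > pos:
            pieces.append((pos, start, profile.background_density))
        pieces.append((start, end, dens))
        pos = end
    if pos < profile.chrom_span:
        pieces.append((pos, profile.chrom_span, profile.background_density))
    return pieces


def simulate_reads(
    profile: SimProfile, n_reads: int, is_control: bool, seed: int
) -> ReadTable:
    """Sample stranded reads from fragment positions drawn along the profile.

    A fragment start is drawn proportional to the local density (uniform
    background only for controls); the read is the first
    ``read_length`` bp of the fragment on the plus strand or the last on
    the minus strand (Bernoulli 1/2), so plus and minus 5' ends straddle
    sites one fragment length apart.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    rng = np.random.default_rng(seed)
    pieces = _density_pieces(profile, is_control)
    mass = np.array([(e - s) * d for s, e, d in pieces])
    piece_idx = rng.choice(len(pieces), size=n_reads, p=mass / mass.sum())
    starts = np.array([pieces[k][0] for k in piece_idx])
    widths = np.array([pieces[k][1] - pieces[k][0] for k in piece_idx])
    frag_start = starts + rng.integers(0, widths)
    frag_start = np.minimum(frag_start, profile.chrom_span - profile.fragment_length)
    frag_start = np.maximum(frag_start, 0)
    is_plus = rng.random(n_reads) < 0.5
    read_start = np.where(
        is_plus, frag_start, frag_start + profile.fragment_length - profile.read_length
    )
    read_end = read_start + profile.read_length
    strand = np.where(is_plus, "+", "-")
    return reads_from_arrays(
        np.full(n_reads, profile.chrom, dtype=object), read_start, read_end, strand
    )


def default_hm_profile(
    seed: int,
    chrom_span: int = 2_000_000,
    n_segments: int = 10,
    min_len: int = 5_000,
    max_len: int = 50_000,
    fold: float = 5.0,
    background_density: float = 0.005,
) -> SimProfile:
    """Broad-island regime: enriched segments of 5-50 kb at ``fold`` x background.

    Defaults emulate diffuse histone-mark domains (tens of kb) over a
    background giving a mean count of about one fragment per 200 bp
    window.  Segment placement is random but non-overlapping with at
    least 20 kb spacing, reproducible from the seed.
    """
    rng = np.random.default_rng(seed)
    gap = 20_000
    segments = []
    pos = gap
    for _ in range(n_segments):
        length = int(rng.integers(min_len, max_len + 1))
        max_start = (chrom_span - gap - length) - (n_segments - len(segments) - 1) * (
            max_len + gap
        )
        if max_start <= pos:
            break
        start = int(rng.integers(pos, max_start))
        segments.append((start, start + length, fold * background_density))
        pos = start + length + gap
    return SimProfile(
        chrom_span=chrom_span,
        segments=tuple(segments),
        background_density=background_density,
    )


def default_tf_profile(
    seed: int,
    chrom_span: int = 2_000_000,
    n_sites: int = 50,
    site_halfwidth: int = 10,
    site_fragments: float = 50.0,
    background_density: float = 0.001,
) -> SimProfile:
    """Punctate-peak regime: point-source binding sites over sparse background.

    Each site is a narrow window of fragment starts (+-``site_halfwidth``
    bp of jitter) carrying ``site_fragments`` expected fragments, so
    plus/minus 5' ends form the sharp bimodal pattern one fragment length
    apart that the shift estimator exploits.
    """
    rng = np.random.default_rng(seed)
    positions = np.sort(
        rng.choice(
            np.arange(5_000, chrom_span - 5_000, 2_000), size=n_sites, replace=False
        )
    )
    site_density = site_fragments / (2 * site_halfwidth)
    segments = tuple(
        (int(c - site_halfwidth), int(c + site_halfwidth), site_density)
        for c in positions
    )
    return SimProfile(
        chrom_span=chrom_span,
        segments=segments,
        background_density=background_density,
    )


def expected_read_counts(profile: SimProfile, is_control: bool) -> float:
    """Expected number of fragments implied by the profile densities."""
    return sum((e - s) * d for s, e, d in _density_pieces(profile, is_control))


def truth_intervals(profile: SimProfile) -> pd.DataFrame:
    """Enriched segments as a DataFrame of intervals (the truth set)."""
    return pd.DataFrame(
        {
            "chrom": [profile.chrom] * len(profile.segments),
            "start": [s for s, _, _ in profile.segments],
            "end": [e for _, e, _ in profile.segments],
        }
    )
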