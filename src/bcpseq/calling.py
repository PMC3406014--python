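"""Region calling from the posterior-mean track, with input-control validation.

The posterior mean is a smoothed, approximately piecewise-constant read
density, so calling reduces to a cut line: blocks whose posterior mean
exceeds the upper quantile of a Poisson fitted to the global mean count
become candidates.  HM mode keeps maximal above-threshold runs as
candidate islands; TF mode additionally locates a summit and grows a
sub-area while neighbouring posterior means differ by less than one.
Candidates are then validated by a one-sided Poisson test of the observed
ChIP read count against the rate expected from the input control in the
matched region, and the empirical FDR is obtained by swapping the roles
of the two samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from . import hyper, model, preprocess
from .bcmix import BcmixConfig
from .io_formats import ReadTable, RegionCall, score_from_pvalue
from .model import ModelParams, PosteriorTrack
from .preprocess import CountTrack

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CallConfig:
    """Pipeline settings; fixed hyperparameters override estimation."""

    mode: str = "hm"
    window: int = 200
    fragment_length: int = 200
    hm_quantile: float = 0.90
    tf_quantile: float = 0.99
    pvalue_cutoff: float = 1e-3
    alpha: Optional[float] = None
    beta: Optional[float] = None
    p: Optional[float] = None
    bcmix: BcmixConfig = field(default_factory=BcmixConfig)
    exact: bool = False
    scale_control: bool = True
    shift: Optional[int] = None
    max_pair_distance: int = 500
    n_top: int = 1000

    def __post_init__(self) -> None:
        if self.mode not in ("tf", "hm"):
            raise ValueError(f"mode must be 'tf' or 'hm', got {self.mode!r}")
        for q in (self.hm_quantile, self.tf_quantile):
            if not 0.0 < q < 1.0:
                raise ValueError("quantiles must lie in (0, 1)")
        if self.p is not None and not 0.0 < self.p < 1.0:
            raise ValueError("p must lie in (0, 1)")


def poisson_quantile(mean: float, q: float) -> int:
    """Smallest integer k with Poisson(mean) CDF at k >= q."""
    if mean <= 0:
        raise ValueError("mean must be positive")
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie in (0, 1)")
    return int(stats.poisson.ppf(q, mean))


def _above_threshold_runs(values: np.ndarray, threshold: float) -> List[Tuple[int, int]]:
    """Maximal runs of blocks with value strictly above threshold (half-open block index ranges)."""
    above = values > threshold
    if not above.any():
        return []
    d = np.diff(above.astype(np.int8))
    starts = list(np.nonzero(d == 1)[0] + 1)
    ends = list(np.nonzero(d == -1)[0] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(values))
    return list(zip(starts, ends))


def _cut_line(counts: CountTrack, q: float) -> int:
    """Threshold C: the q-quantile of Poisson(global mean block count).

    Floored at 1 so that a near-empty background (mean count << 1, where
    the quantile degenerates to 0) cannot turn the whole chromosome into
    one candidate — the posterior mean is strictly positive everywhere.
    """
    return max(poisson_quantile(float(np.mean(counts.counts)), q), 1)


def segment_hm(post: PosteriorTrack, counts: CountTrack, q: float = 0.90) -> List[RegionCall]:
    """Candidate islands: maximal runs of blocks with posterior mean above
    the q-quantile of Poisson(global mean block count)."""
    threshold = _cut_line(counts, q)
    regions = []
    for b0, b1 in _above_threshold_runs(post.values, threshold):
        regions.append(
            RegionCall(
                chrom=counts.chrom,
                start=int(counts.edges[b0]),
                end=int(counts.edges[b1]),
                mean_level=float(np.mean(post.values[b0:b1])),
            )
        )
    return regions


def call_tf_peaks(post: PosteriorTrack, counts: CountTrack, q: float = 0.99) -> List[RegionCall]:
    """Candidate TF peaks with summit and sub-area.

    Within each maximal above-threshold area the block with the largest
    posterior mean (leftmost on ties) defines the summit (its midpoint).
    The sub-area grows from that block in both directions while the
    difference of adjacent posterior means stays strictly below one; it
    approximates the true enrichment footprint used for control matching.
    """
    if counts.mode != "tf":
        raise ValueError("call_tf_peaks requires a TF-mode track")
    threshold = _cut_line(counts, q)
    regions = []
    lam = post.values
    for b0, b1 in _above_threshold_runs(lam, threshold):
        k = b0 + int(np.argmax(lam[b0:b1]))
        lo = k
        while lo > b0 and abs(lam[lo - 1] - lam[lo]) < 1.0:
            lo -= 1
        hi = k
        while hi < b1 - 1 and abs(lam[hi + 1] - lam[hi]) < 1.0:
            hi += 1
        summit = int((counts.edges[k] + counts.edges[k + 1]) // 2)
        regions.append(
            RegionCall(
                chrom=counts.chrom,
                start=int(counts.edges[b0]),
                end=int(counts.edges[b1]),
                mean_level=float(np.mean(lam[b0:b1])),
                summit=summit,
                sub_start=int(counts.edges[lo]),
                sub_end=int(counts.edges[hi + 1]),
            )
        )
    return regions


def count_reads_in(reads: ReadTable, start: int, end: int) -> int:
    """Number of reads whose midpoint falls in [start, end)."""
    if len(reads) == 0:
        return 0
    mid = (reads["start"].to_numpy(np.int64) + reads["end"].to_numpy(np.int64)) // 2
    return int(((mid >= start) & (mid < end)).sum())


def input_filter(
    candidates: Sequence[RegionCall],
    chip_counts: Sequence[int],
    control_reads: ReadTable,
    mode: str,
    pvalue_cutoff: float = 1e-3,
    scale: float = 1.0,
    genome_span: Optional[int] = None,
) -> List[RegionCall]:
    """Validate candidates against the input control with a Poisson test.

    For each candidate the null expectation lambda0 is the control read
    density in the matched region, scaled by the library-size ratio and
    the candidate length.  HM mode matches the candidate region itself;
    TF mode takes the larger of the control density in the sub-area and
    the average density over summit-centred windows spanning one to five
    candidate widths, to absorb local background variation.  The p-value
    is the upper-tail Poisson probability of the observed ChIP count;
    candidates below ``pvalue_cutoff`` are retained with score
    -log10(p).  When the local control count is zero, lambda0 falls back
    to the genome-wide control density (floor) so empty control windows
    cannot yield p = 0.
    """
    if len(candidates) != len(chip_counts):
        raise ValueError("chip_counts must align with candidates")
    n_control = len(control_reads)
    if genome_span is None:
        genome_span = int(control_reads["end"].max()) if n_control else 1
    global_density = n_control / max(genome_span, 1)
    if n_control == 0:
        logger.warning("control sample empty; applying minimal lambda0 floor")
        global_density = 1.0 / max(genome_span, 1)
    mid = (
        (control_reads["start"].to_numpy(np.int64) + control_reads["end"].to_numpy(np.int64)) // 2
        if n_control
        else np.empty(0, np.int64)
    )
    mid = np.sort(mid)

    def density(chrom_mid: np.ndarray, start: int, end: int) -> float:
        start = max(start, 0)
        if end <= start:
            return 0.0
        cnt = np.searchsorted(chrom_mid, end) - np.searchsorted(chrom_mid, start)
        return cnt / (end - start)

    validated = []
    for cand, obs in zip(candidates, chip_counts):
        if mode == "tf":
            width = cand.length
            rate = density(mid, cand.sub_start, cand.sub_end)
            flank_rates = [
                density(mid, cand.summit - k * width, cand.summit + k * width)
                for k in range(1, 6)
            ]
            rate = max(rate, float(np.mean(flank_rates)))
        else:
            rate = density(mid, cand.start, cand.end)
        if rate <= 0.0:
            rate = global_density
        lam0 = rate * scale * cand.length
        pvalue = float(stats.poisson.sf(obs - 1, lam0))  # P(X >= obs)
        if pvalue < pvalue_cutoff:
            validated.append(
                replace(
                    cand,
                    pvalue=pvalue,
                    score=score_from_pvalue(pvalue),
                    chip_count=int(obs),
                    lambda0=lam0,
                )
            )
    return validated


# ---------------------------------------------------------------------------
# pipeline orchestration (per-chromosome model, genome-wide hyperparameters)


def run_sample(
    chip: ReadTable,
    control: ReadTable,
    config: CallConfig,
) -> Tuple[List[RegionCall], List[PosteriorTrack], ModelParams, Dict]:
    """Full pipeline: preprocess, estimate hyperparameters, smooth, call, validate.

    Chromosomes are processed independently in lexicographic order;
    (alpha, beta) and p are estimated once from the pooled genome-wide
    blocks.  Returns (validated regions, posterior tracks, resolved
    parameters, run info for logging).
    """
    chip = preprocess.deduplicate(chip)
    control = preprocess.deduplicate(control)
    if len(chip) == 0:
        raise ValueError("ChIP sample contains no reads")

    info: Dict = {"mode": config.mode}
    tracks: List[CountTrack] = []
    chrom_reads: Dict[str, ReadTable] = {}
    shift = None
    if config.mode == "tf":
        shift = config.shift
        if shift is None:
            shift = preprocess.estimate_shift(
                chip,
                max_pair_distance=config.max_pair_distance,
                n_top=config.n_top,
                fragment_length=config.fragment_length,
            )
        info["shift"] = shift
    if config.mode == "tf":
        # regions are called in shifted coordinates, so validation counts
        # must use the same frame for both samples
        chip = preprocess.shift_reads(chip, shift)
        control = preprocess.shift_reads(control, shift) if len(control) else control
    for chrom, sub in preprocess.split_by_chrom(chip):
        chrom_reads[chrom] = sub
        if config.mode == "tf":
            tracks.append(preprocess.build_tf_track(sub, 0))
        else:
            tracks.append(
                preprocess.build_hm_track(sub, config.fragment_length, config.window)
            )

    pooled = np.concatenate([t.counts for t in tracks])
    if config.alpha is not None and config.beta is not None:
        alpha, beta = float(config.alpha), float(config.beta)
    else:
        alpha, beta = hyper.estimate_alpha_beta(pooled)
    bcmix = None if config.exact else config.bcmix
    if config.p is not None:
        p = float(config.p)
    else:
        p = hyper.estimate_p(tracks, alpha, beta, bcmix=config.bcmix)
    params = ModelParams(alpha, beta, p)
    info.update(alpha=alpha, beta=beta, p=p)

    scale = (len(chip) / len(control)) if (config.scale_control and len(control)) else 1.0
    info["scale"] = scale
    genome_span = int(
        max(
            chip["end"].max(),
            control["end"].max() if len(control) else 0,
        )
    )

    all_regions: List[RegionCall] = []
    posts: List[PosteriorTrack] = []
    q = config.tf_quantile if config.mode == "tf" else config.hm_quantile
    for track in tracks:
        post = model.posterior_means(track, params, bcmix)
        posts.append(post)
        if config.mode == "tf":
            cands = call_tf_peaks(post, track, q)
        else:
            cands = segment_hm(post, track, q)
        sub = chrom_reads[track.chrom]
        chip_counts = [count_reads_in(sub, c.start, c.end) for c in cands]
        ctrl = control[control["chrom"] == track.chrom].reset_index(drop=True)
        all_regions.extend(
            input_filter(
                cands,
                chip_counts,
                ctrl,
                config.mode,
                pvalue_cutoff=config.pvalue_cutoff,
                scale=scale,
                genome_span=genome_span,
            )
        )
    info["threshold_quantile"] = q
    info["n_candidates_validated"] = len(all_regions)
    return all_regions, posts, params, info


def empirical_fdr(
    chip: ReadTable,
    control: ReadTable,
    config: CallConfig,
) -> Tuple[Optional[float], "np.ndarray"]:
    """Empirical FDR by sample inversion.

    Runs the pipeline with (chip, control) to obtain the test peaks and
    with (control, chip) to obtain negative peaks; the overall FDR is
    negatives / tests.  The rank curve reports, for test peaks sorted by
    ascending p-value, FDR(r) = (#negatives scoring at least the rank-r
    score) / r.  Returns (overall FDR or None if no test peaks, array of
    rows (rank, score, fdr)).
    """
    test_peaks, _, _, _ = run_sample(chip, control, config)
    try:
        neg_peaks, _, _, _ = run_sample(control, chip, config)
    except ValueError:
        neg_peaks = []
    if not test_peaks:
        logger.warning("no test peaks called; empirical FDR undefined")
        return None, np.empty((0, 3))
    test_scores = np.sort([r.score for r in test_peaks])[::-1]
    neg_scores = np.sort([r.score for r in neg_peaks])[::-1]
    rows = []
    for r, s in enumerate(test_scores, start=1):
        n_neg = int(np.searchsorted(-neg_scores, -s, side="right"))
        rows.append((r, s, n_neg / r))
    overall = len(neg_peaks) / len(test_peaks)
    return overall, np.asarray(rows)
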