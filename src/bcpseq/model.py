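"""Infinite-state Poisson-Gamma change-point smoother.

Generative model for per-block counts y_1..y_n:

* the rate sequence lambda_t is piecewise constant; block 1 always starts
  a segment and each later boundary carries an independent Bernoulli(p)
  change indicator;
* at a change the new level is drawn afresh from Gamma(alpha, beta)
  (shape/rate, prior mean alpha/beta) — a continuous state space, unlike
  finite-state HMM segmenters;
* y_t | lambda_t ~ Poisson(lambda_t), independent across blocks.

Conjugacy makes everything closed-form: the posterior of lambda_t given
all data is a mixture of Gamma((alpha + segment sum), (beta + segment
length)) laws over candidate segments [i, j] containing t, and the
posterior mean is the corresponding weighted average — a dynamically
windowed scan statistic in which every window size participates with a
data-driven weight.

The forward/backward passes run through a numba kernel
(:mod:`bcpseq._kernels`); this module assembles them into smoothed
posterior means, either exactly (O(n^2)) or under the bounded-complexity
mixture approximation (near-linear; see :mod:`bcpseq.bcmix`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.special import gammaln

from ._kernels import filter_kernel
from .bcmix import BcmixConfig
from .preprocess import CountTrack


@dataclass(frozen=True)
class ModelParams:
    """Hyperparameters: Gamma prior shape/rate and change probability."""

    alpha: float
    beta: float
    p: float

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError("alpha must be > 0")
        if not self.beta > 0:
            raise ValueError("beta must be > 0")
        if not 0.0 < self.p < 1.0:
            raise ValueError("p must lie strictly in (0, 1)")

    @property
    def prior_mean(self) -> float:
        return self.alpha / self.beta


@dataclass(frozen=True)
class SegmentPosterior:
    """Posterior and evidence of one shared rate over blocks i..j (0-based, inclusive)."""

    i: int
    j: int
    shape: float
    rate: float
    log_marginal: float

    @property
    def mean(self) -> float:
        return self.shape / self.rate


@dataclass
class FilterState:
    """Per-step posterior weights over change-point hypotheses.

    ``support[t]`` lists candidate indices (most recent change i <= t for
    the forward pass; last block j >= t of the current segment for the
    backward pass), padded with -1; ``log_weights[t]`` are the matching
    normalised log weights.  ``log_prefix[t]`` is the accumulated log
    normaliser: for the forward pass log P(y_0..y_t), for the backward
    pass log P(y_t..y_{n-1} | a change at t).  ``loglik`` is the total
    data log marginal likelihood (approximate when pruning is active).
    """

    direction: str
    support: np.ndarray
    log_weights: np.ndarray
    log_prefix: np.ndarray
    loglik: float

    def weights_at(self, t: int) -> dict:
        """Weight map {index: posterior weight} at step t (for inspection/tests)."""
        row = self.support[t]
        valid = row >= 0
        return dict(zip(row[valid].tolist(), np.exp(self.log_weights[t][valid]).tolist()))


@dataclass
class PosteriorTrack:
    """Smoothed posterior-mean read density aligned to a CountTrack."""

    chrom: str
    edges: np.ndarray
    values: np.ndarray
    loglik: float = np.nan

    @property
    def n_blocks(self) -> int:
        return len(self.values)


def _prefix_sums(counts: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """(S, T): S[k] = sum of counts[:k]; T[k] = sum of lgamma(y+1) over counts[:k]."""
    y = np.asarray(counts, dtype=np.float64)
    S = np.concatenate([[0.0], np.cumsum(y)])
    T = np.concatenate([[0.0], np.cumsum(gammaln(y + 1.0))])
    return S, T


def _log_marginal_grid(params: ModelParams, S, T, i, j):
    """Vectorised log evidence of segments [i, j] (inclusive, broadcastable)."""
    seg_sum = S[j + 1] - S[i]
    seg_len = (j - i + 1).astype(np.float64) if hasattr(j - i, "astype") else float(j - i + 1)
    shape = params.alpha + seg_sum
    rate = params.beta + seg_len
    return (
        params.alpha * np.log(params.beta)
        - gammaln(params.alpha)
        + gammaln(shape)
        - shape * np.log(rate)
        - (T[j + 1] - T[i])
    )


def segment_evidence(params: ModelParams, counts: np.ndarray, i: int, j: int) -> SegmentPosterior:
    """Closed-form posterior and log evidence for one shared rate over y_i..y_j.

    The marginal of a segment under Gamma(alpha, beta) is

        m(i, j) = beta^alpha / Gamma(alpha)
                  * Gamma(alpha + S_ij) / (beta + L)^(alpha + S_ij)
                  / prod(y_u!)

    with S_ij the segment count sum and L its length; all arithmetic in
    log space.  Indices are 0-based and inclusive.
    """
    counts = np.asarray(counts)
    n = len(counts)
    if not (0 <= i <= j < n):
        raise IndexError(f"segment [{i}, {j}] out of range for n={n}")
    S, T = _prefix_sums(counts)
    logm = float(_log_marginal_grid(params, S, T, np.int64(i), np.int64(j)))
    seg_sum = float(S[j + 1] - S[i])
    return SegmentPosterior(
        i=i, j=j,
        shape=params.alpha + seg_sum,
        rate=params.beta + (j - i + 1),
        log_marginal=logm,
    )


def _resolve_bcmix(bcmix: Optional[BcmixConfig]) -> Tuple[bool, int, int]:
    if bcmix is None or not bcmix.enabled:
        return False, 0, 0
    return True, bcmix.k_total, bcmix.m_recent


def _run_kernel(counts, params: ModelParams, bcmix, store: bool):
    prune_on, k, m = _resolve_bcmix(bcmix)
    y = np.ascontiguousarray(counts, dtype=np.int64)
    return filter_kernel(y, params.alpha, params.beta, params.p, k, m, prune_on, store)


def forward_filter(track: CountTrack, params: ModelParams, bcmix: Optional[BcmixConfig] = None) -> FilterState:
    """Posterior weights over the most recent change index i <= t given y_1..y_t."""
    support, logw, lognorm = _run_kernel(track.counts, params, bcmix, True)
    prefix = np.cumsum(lognorm)
    return FilterState("forward", support, logw, prefix, float(prefix[-1]))


def backward_filter(track: CountTrack, params: ModelParams, bcmix: Optional[BcmixConfig] = None) -> FilterState:
    """Mirror-image filter on the reversed sequence, reported in original coordinates.

    ``support[t]`` holds candidate segment-end indices j >= t and
    ``log_prefix[t]`` = log P(y_t..y_{n-1} | a change at t): the model is
    direction-exchangeable, so the reversed recursion is the same kernel.
    """
    n = track.n_blocks
    support, logw, lognorm = _run_kernel(track.counts[::-1], params, bcmix, True)
    support = support[::-1].copy()
    valid = support >= 0
    support[valid] = n - 1 - support[valid]
    logw = logw[::-1].copy()
    suffix = np.cumsum(lognorm)[::-1].copy()
    return FilterState("backward", support, logw, suffix, float(suffix[0]))


def log_likelihood(track: CountTrack, params: ModelParams, bcmix: Optional[BcmixConfig] = None) -> float:
    """Marginal log-likelihood of the track, accumulated from filter normalisers.

    Exact when ``bcmix`` is None/disabled (quadratic in n); with pruning
    active it is the bounded-complexity approximation.
    """
    _, _, lognorm = _run_kernel(track.counts, params, bcmix, False)
    return float(np.sum(lognorm))


def _posterior_means_exact(track: CountTrack, params: ModelParams) -> PosteriorTrack:
    """Exact smoother by summation over every candidate segment [i, j].

    The posterior probability that the segment containing block t spans
    [i, j] factorises as

        w_ij = a_i * (1-p)^(j-i) * m(i, j) * c_{j+1}

    with a_i the evidence of the prefix ending in a change at i and
    c_{j+1} that of the suffix starting with a change at j+1, both read
    off the exact forward/backward normalisers.  For each i the weights
    over j are accumulated onto blocks via a difference array, giving
    O(n^2) total work.
    """
    n = track.n_blocks
    y = track.counts
    S, T = _prefix_sums(y)
    _, _, f_lognorm = _run_kernel(y, params, None, False)
    _, _, b_lognorm_rev = _run_kernel(y[::-1], params, None, False)
    Lf = np.cumsum(f_lognorm)               # log P(y_0..y_t)
    Lb = np.cumsum(b_lognorm_rev)[::-1]     # log P(y_t..y_{n-1} | change at t)
    loglik = float(Lf[-1])
    log_p = np.log(params.p)
    log_q = np.log1p(-params.p)
    # log a_i: change at i given the past; block 0 starts a segment surely
    log_a = np.empty(n)
    log_a[0] = 0.0
    if n > 1:
        log_a[1:] = log_p + Lf[:-1]
    # log c_{j+1}: suffix evidence after a change at j+1
    log_c = np.empty(n)
    log_c[n - 1] = 0.0
    if n > 1:
        log_c[: n - 1] = log_p + Lb[1:]

    num_diff = np.zeros(n + 1)
    den_diff = np.zeros(n + 1)
    j_all = np.arange(n, dtype=np.int64)
    for i in range(n):
        j = j_all[i:]
        logm = _log_marginal_grid(params, S, T, np.int64(i), j)
        logw = log_a[i] + (j - i) * log_q + logm + log_c[j] - loglik
        w = np.exp(logw)
        mu = (params.alpha + (S[j + 1] - S[i])) / (params.beta + (j - i + 1.0))
        wm = w * mu
        num_diff[i] += wm.sum()
        den_diff[i] += w.sum()
        num_diff[i + 1 : n + 1] -= wm
        den_diff[i + 1 : n + 1] -= w
    num = np.cumsum(num_diff[:n])
    den = np.cumsum(den_diff[:n])
    values = num / den
    return PosteriorTrack(track.chrom, track.edges, values, loglik)


_CHUNK = 512


def _posterior_means_bcmix(track: CountTrack, params: ModelParams, bcmix: BcmixConfig) -> PosteriorTrack:
    """Smoother over the pruned forward and backward hypothesis sets.

    At block t the candidate segments are pairs (i, j) with i from the
    forward support and j from the backward support; the smoothing weight
    combines the two filter weights with an evidence ratio that removes
    the doubly counted block t:

        w_ij(t) ∝ F_it * G_jt * m(i, j) / (m(i, t) * m(t, j))
    """
    n = track.n_blocks
    S, T = _prefix_sums(track.counts)
    fwd = forward_filter(track, params, bcmix)
    bwd = backward_filter(track, params, bcmix)
    values = np.empty(n)
    t_all = np.arange(n, dtype=np.int64)
    for lo in range(0, n, _CHUNK):
        hi = min(lo + _CHUNK, n)
        t = t_all[lo:hi, None, None]                      # (c,1,1)
        i = fwd.support[lo:hi, :, None]                   # (c,kf,1)
        j = bwd.support[lo:hi, None, :]                   # (c,1,kb)
        log_F = fwd.log_weights[lo:hi, :, None] + fwd.log_prefix[lo:hi, None, None]
        log_G = bwd.log_weights[lo:hi, None, :] + bwd.log_prefix[lo:hi, None, None]
        i_safe = np.minimum(np.maximum(i, 0), t)
        j_safe = np.maximum(j, t)
        logw = (
            log_F
            + log_G
            + _log_marginal_grid(params, S, T, i_safe, j_safe)
            - _log_marginal_grid(params, S, T, i_safe, t)
            - _log_marginal_grid(params, S, T, t, j_safe)
        )
        logw = np.where((i >= 0) & (j >= 0), logw, -np.inf)
        mx = logw.max(axis=(1, 2), keepdims=True)
        w = np.exp(logw - mx)
        mu = (params.alpha + (S[j_safe + 1] - S[i_safe])) / (params.beta + (j_safe - i_safe + 1.0))
        values[lo:hi] = (w * mu).sum(axis=(1, 2)) / w.sum(axis=(1, 2))
    return PosteriorTrack(track.chrom, track.edges, values, fwd.loglik)


def posterior_means(
    track: CountTrack,
    params: ModelParams,
    bcmix: Optional[BcmixConfig] = None,
) -> PosteriorTrack:
    """Posterior mean rate per block given the whole sequence.

    lambda_hat_t is the evidence-weighted average of segment posterior
    means shape_ij/rate_ij over all candidate segments [i, j] containing
    t.  With ``bcmix`` None or disabled the exact O(n^2) smoother is
    used; otherwise the bounded-complexity approximation.
    """
    prune_on, _, _ = _resolve_bcmix(bcmix)
    if prune_on:
        return _posterior_means_bcmix(track, params, bcmix)
    return _posterior_means_exact(track, params)
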