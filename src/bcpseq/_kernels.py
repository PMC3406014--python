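"""Numba kernels for the sequential change-point filter.

The forward filter maintains, per block t, posterior weights over the
most-recent change index i <= t.  Each hypothesis carries the running
Gamma posterior (shape = alpha + sum of segment counts, rate = beta +
segment length); the one-step predictive is the negative-binomial form of
the Poisson-Gamma marginal.  All weights are propagated in log space.

Pruning (bounded-complexity mixture) keeps the ``m_recent`` most recent
hypotheses plus the largest-weight remainder, renormalising after each
prune, so a genome-wide pass runs in O(n * k) instead of O(n^2).
"""

import math

import numpy as np
from numba import njit


@njit(cache=True)
def _log_predictive(shape, rate, y, lgamma_y1):
    """log P(y | segment posterior Gamma(shape, rate)) - negative binomial."""
    return (
        math.lgamma(shape + y)
        - math.lgamma(shape)
        + shape * math.log(rate)
        - (shape + y) * math.log(rate + 1.0)
        - lgamma_y1
    )


@njit(cache=True)
def filter_kernel(y, alpha, beta, p, k_total, m_recent, prune_on, store):
    """Sequential forward filter over counts ``y``.

    Returns ``(support, log_weights, step_lognorm)`` where row t of
    ``support``/``log_weights`` lists candidate most-recent-change indices
    (padded with -1) and their normalised log posterior weights, and
    ``step_lognorm[t]`` is the log one-step normaliser, so the cumulative
    sum is the running data log-likelihood.  With ``store=False`` the
    per-step weights are not recorded (only normalisers), which is what
    the exact O(n^2) smoother needs.
    """
    n = y.shape[0]
    cap = n if not prune_on else k_total
    if store:
        support = np.full((n, cap), -1, np.int64)
        log_weights = np.full((n, cap), -np.inf, np.float64)
    else:
        support = np.full((1, 1), -1, np.int64)
        log_weights = np.full((1, 1), -np.inf, np.float64)
    step_lognorm = np.empty(n, np.float64)

    idx = np.empty(cap + 1, np.int64)
    lw = np.empty(cap + 1, np.float64)
    sh = np.empty(cap + 1, np.float64)
    rt = np.empty(cap + 1, np.float64)
    cand = np.empty(cap + 1, np.float64)
    keep = np.empty(cap + 1, np.bool_)

    log_p = math.log(p)
    log_q = math.log1p(-p)
    cnt = 0
    for t in range(n):
        yt = float(y[t])
        lgy1 = math.lgamma(yt + 1.0)
        # continuing hypotheses
        for a in range(cnt):
            cand[a] = log_q + lw[a] + _log_predictive(sh[a], rt[a], yt, lgy1)
        # fresh-segment hypothesis i = t (certain at t = 0)
        new_lw = _log_predictive(alpha, beta, yt, lgy1)
        if t > 0:
            new_lw += log_p
        cand[cnt] = new_lw
        m = cnt + 1
        # normalise via log-sum-exp
        mx = cand[0]
        for a in range(1, m):
            if cand[a] > mx:
                mx = cand[a]
        s = 0.0
        for a in range(m):
            s += math.exp(cand[a] - mx)
        lognorm = mx + math.log(s)
        step_lognorm[t] = lognorm
        for a in range(cnt):
            lw[a] = cand[a] - lognorm
            sh[a] += yt
            rt[a] += 1.0
        idx[cnt] = t
        lw[cnt] = cand[cnt] - lognorm
        sh[cnt] = alpha + yt
        rt[cnt] = beta + 1.0
        cnt = m

        if prune_on and cnt > k_total:
            # always keep the m_recent most recent (tail of idx, which is
            # ordered); among the rest keep the largest weights, ties
            # resolved towards the more recent index.
            n_old = cnt - m_recent
            n_keep_old = k_total - m_recent
            for a in range(cnt):
                keep[a] = a >= n_old
            for _ in range(n_keep_old):
                best = -1
                best_lw = -np.inf
                for a in range(n_old):
                    if not keep[a] and (lw[a] > best_lw or (lw[a] == best_lw and best >= 0 and idx[a] > idx[best])):
                        best = a
                        best_lw = lw[a]
                if best >= 0:
                    keep[best] = True
            # compact, preserving index order, and renormalise
            w = 0
            tot = 0.0
            for a in range(cnt):
                if keep[a]:
                    idx[w] = idx[a]
                    lw[w] = lw[a]
                    sh[w] = sh[a]
                    rt[w] = rt[a]
                    tot += math.exp(lw[a])
                    w += 1
            log_tot = math.log(tot)
            for a in range(w):
                lw[a] -= log_tot
            cnt = w

        if store:
            for a in range(cnt):
                support[t, a] = idx[a]
                log_weights[t, a] = lw[a]
    return support, log_weights, step_lognorm
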