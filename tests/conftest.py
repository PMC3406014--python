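"""Shared fixtures and the brute-force enumeration oracle.

The oracle sums over all 2^(n-1) change-indicator configurations of a
track: each configuration contributes its Bernoulli prior times the
product of closed-form Poisson-Gamma segment evidences.  It is the
normative reference for the filter weights, posterior means and marginal
likelihood of small tracks, and is deliberately independent of the
recursive implementation it checks.
"""

import itertools

import numpy as np
import pytest
from scipy.special import gammaln

from bcpseq.preprocess import CountTrack


def oracle_log_marginal(y, i, j, alpha, beta):
    """Closed-form segment evidence log m(y_i..y_j), 0-based inclusive."""
    y = np.asarray(y, dtype=float)
    s = y[i : j + 1].sum()
    length = j - i + 1
    return (
        alpha * np.log(beta)
        - gammaln(alpha)
        + gammaln(alpha + s)
        - (alpha + s) * np.log(beta + length)
        - gammaln(y[i : j + 1] + 1).sum()
    )


def enumerate_posterior(y, alpha, beta, p):
    """Full posterior by enumeration of change configurations.

    Returns (log_likelihood, lambda_hat, forward_weights) where
    forward_weights[t] is a dict {i: P(most recent change <= t is at i |
    y_0..y_t)} computed by enumerating prefixes independently.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)

    def config_terms(m):
        """(log weight, segment bounds) for every configuration of y[:m]."""
        terms = []
        for cfg in itertools.product([0, 1], repeat=m - 1):
            bounds = [0] + [t + 1 for t, c in enumerate(cfg) if c] + [m]
            logw = sum(np.log(p) if c else np.log1p(-p) for c in cfg)
            logw += sum(
                oracle_log_marginal(y, bounds[k], bounds[k + 1] - 1, alpha, beta)
                for k in range(len(bounds) - 1)
            )
            terms.append((logw, bounds))
        return terms

    terms = config_terms(n)
    logws = np.array([t[0] for t in terms])
    mx = logws.max()
    norm = np.exp(logws - mx)
    loglik = mx + np.log(norm.sum())
    weights = norm / norm.sum()
    lam_hat = np.zeros(n)
    for w, (_, bounds) in zip(weights, terms):
        for k in range(len(bounds) - 1):
            i, j = bounds[k], bounds[k + 1] - 1
            mu = (alpha + y[i : j + 1].sum()) / (beta + (j - i + 1))
            lam_hat[i : j + 1] += w * mu

    forward = []
    for m in range(1, n + 1):
        sub = config_terms(m)
        lw = np.array([t[0] for t in sub])
        wn = np.exp(lw - lw.max())
        wn /= wn.sum()
        weights_i = {}
        for w, (_, bounds) in zip(wn, sub):
            i = bounds[-2]  # start of the segment containing block m-1
            weights_i[i] = weights_i.get(i, 0.0) + w
        forward.append(weights_i)
    return loglik, lam_hat, forward


def make_track(y, window=100):
    y = np.asarray(y, dtype=np.int64)
    edges = np.arange(len(y) + 1, dtype=np.int64) * window
    return CountTrack("chrT", edges, y, "hm", window)


@pytest.fixture(scope="session")
def hm_dataset():
    """Simulated broad-mark dataset: (profile, chip, control) at seed 7."""
    from bcpseq import simulate

    profile = simulate.default_hm_profile(seed=7)
    n_chip = int(round(simulate.expected_read_counts(profile, False)))
    n_ctrl = int(round(simulate.expected_read_counts(profile, True)))
    chip = simulate.simulate_reads(profile, n_chip, is_control=False, seed=7)
    control = simulate.simulate_reads(profile, n_ctrl, is_control=True, seed=8)
    return profile, chip, control


@pytest.fixture(scope="session")
def tf_dataset():
    """Simulated punctate-peak dataset: (profile, chip, control) at seed 5."""
    from bcpseq import simulate

    profile = simulate.default_tf_profile(seed=5)
    n_chip = int(round(simulate.expected_read_counts(profile, False)))
    n_ctrl = int(round(simulate.expected_read_counts(profile, True)))
    chip = simulate.simulate_reads(profile, n_chip, is_control=False, seed=5)
    control = simulate.simulate_reads(profile, n_ctrl, is_control=True, seed=6)
    return profile, chip, control
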