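"""Empirical-Bayes hyperparameter estimation.

Marginally each block count is negative binomial (Poisson mixed over the
Gamma prior), with mean m = alpha/beta and variance v = m + m/beta, and
the counts are exchangeable — so (alpha, beta) come from the method of
moments.  The change probability p is then chosen by maximising the
marginal log-likelihood over a logarithmic grid, which is cheap because
the likelihood has a closed filtering form.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence, Tuple

import numpy as np

from . import model
from .bcmix import BcmixConfig
from .preprocess import CountTrack

logger = logging.getLogger(__name__)


def estimate_alpha_beta(counts: np.ndarray) -> Tuple[float, float]:
    """Method-of-moments Gamma prior from pooled block counts.

    Solves m = alpha/beta, v = alpha/beta + alpha/beta**2 with the sample
    mean and unbiased sample variance: beta = m/(v - m), alpha = m*beta.
    Requires overdispersion (v > m); otherwise falls back to a prior with
    mean m and unit variance (alpha = m^2, beta = m) with a warning.
    """
    y = np.asarray(counts, dtype=np.float64)
    if y.size < 2:
        raise ValueError("need at least two blocks to estimate moments")
    m = float(y.mean())
    v = float(y.var(ddof=1))
    if m <= 0:
        logger.warning("all-zero counts; using default prior alpha=beta=1")
        return 1.0, 1.0
    if v <= m:
        logger.warning(
            "counts not overdispersed (mean=%.4g, var=%.4g); "
            "falling back to unit-variance prior", m, v,
        )
        return m * m, m
    beta = m / (v - m)
    return m * beta, beta


def default_p_grid(max_p: float = 0.5) -> np.ndarray:
    """Logarithmic grid {j * 10^-i : j in 1..9, i in 1..7} ∩ (0, max_p], ascending."""
    vals = sorted(
        j * 10.0 ** (-i)
        for i in range(1, 8)
        for j in range(1, 10)
        if 0.0 < j * 10.0 ** (-i) <= max_p
    )
    return np.array(vals)


def estimate_p(
    tracks,
    alpha: float,
    beta: float,
    grid: Optional[Sequence[float]] = None,
    bcmix: Optional[BcmixConfig] = BcmixConfig(),
) -> float:
    """Grid-search MLE of the change probability given (alpha, beta).

    ``tracks`` is one CountTrack or a sequence of them; log-likelihoods
    are summed across tracks (chromosomes are independent).  Returns the
    grid value with the highest total log-likelihood; on ties the
    smallest such p wins (the grid is scanned in ascending order).
    """
    if isinstance(tracks, CountTrack):
        tracks = [tracks]
    grid = default_p_grid() if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty grid")
    if np.any((grid <= 0) | (grid >= 1)):
        raise ValueError("grid values must lie in (0, 1)")
    best_p, best_ll = None, -np.inf
    for p in grid:
        ll = sum(
            model.log_likelihood(t, model.ModelParams(alpha, beta, float(p)), bcmix)
            for t in tracks
        )
        if ll > best_ll:
            best_p, best_ll = float(p), ll
    logger.info("grid-search p = %g (log-likelihood %.4f)", best_p, best_ll)
    return best_p
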