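"""Bounded-complexity mixture (BCMIX) truncation.

The exact filter carries one hypothesis per possible change location, so
its mixture grows linearly with position and the whole pass is quadratic.
Capping the mixture at ``k_total`` components — always retaining the
``m_recent`` most recent change candidates plus the largest-weight older
ones — keeps genome-wide smoothing near-linear while leaving the
posterior means essentially unchanged (the discarded hypotheses carry
vanishing weight).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict


@dataclass(frozen=True)
class BcmixConfig:
    """Mixture budget: ``k_total`` hypotheses kept, ``m_recent`` of them
    reserved for the most recent change candidates."""

    k_total: int = 20
    m_recent: int = 10
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.k_total < 2:
            raise ValueError("k_total must be >= 2")
        if not 1 <= self.m_recent < self.k_total:
            raise ValueError("require 1 <= m_recent < k_total")


EXACT = BcmixConfig(k_total=2, m_recent=1, enabled=False)


def prune(weights: Dict[int, float], config: BcmixConfig) -> Dict[int, float]:
    """Truncate a normalised weight map over change indices.

    If the support already fits the budget the map is returned unchanged.
    Otherwise the ``m_recent`` largest (most recent) indices are always
    retained, the remaining ``k_total - m_recent`` slots go to the
    largest-weight other indices (ties kept towards the more recent
    index), and the survivors are renormalised to sum to 1.
    """
    if not config.enabled or len(weights) <= config.k_total:
        return dict(weights)
    indices = sorted(weights)
    recent = set(indices[-config.m_recent:])
    rest = [i for i in indices if i not in recent]
    # sort by (weight, index) descending: ties favour the more recent index
    rest.sort(key=lambda i: (weights[i], i), reverse=True)
    kept = recent | set(rest[: config.k_total - config.m_recent])
    total = sum(weights[i] for i in kept)
    return {i: weights[i] / total for i in sorted(kept)}
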