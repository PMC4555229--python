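"""Combination-therapy scoring: resistant-culture proportions and ranking.

Each experimental arm grows ``n`` independent mutator cultures under the
primary drug plus a candidate blocking compound and records the fraction
that still develop resistance.  The summary statistic is the binomial
proportion with its standard error, ``se = sqrt(p(1-p)/n)``, displayed the
way such tables are printed: "74 ± 7%" (integer percent, round half up),
with the ± part omitted when the SE is exactly zero (p = 0 or 1).
Lower resistant fraction = more effective combination.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

__all__ = ["ProportionEstimate", "resistance_proportion", "rank_combinations"]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class ProportionEstimate:
    p_hat: float
    n: int
    se: float

    @property
    def display(self) -> str:
        pct = _round_half_up(self.p_hat * 100)
        if self.se == 0.0:
            return f"{pct}%"
        return f"{pct} ± {_round_half_up(self.se * 100)}%"


def resistance_proportion(
    n: int, *, count: int | None = None, fraction: float | None = None
) -> ProportionEstimate:
    """Resistant fraction ± SE of proportion for one arm of ``n`` cultures.

    Provide either ``count`` (resistant cultures out of n) or ``fraction``
    (a pooled proportion, which need not be a multiple of 1/n).
    """
    if n <= 0:
        raise ValueError(f"n must be >= 1, got {n}")
    if (count is None) == (fraction is None):
        raise ValueError("provide exactly one of count= or fraction=")
    if count is not None:
        if not (0 <= count <= n):
            raise ValueError(f"count must lie in [0, n], got {count}")
        p = count / n
    else:
        p = float(fraction)
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"fraction must lie in [0, 1], got {p}")
    se = math.sqrt(p * (1.0 - p) / n)
    return ProportionEstimate(p_hat=p, n=n, se=se)


def rank_combinations(
    arms: Sequence[tuple[str, ProportionEstimate]],
) -> pd.DataFrame:
    """Rank arms ascending by resistant fraction (ties broken by label).

    Rank 1 = most effective regimen (fewest resistant cultures).
    """
    if not arms:
        raise ValueError("need at least one arm")
    ordered = sorted(arms, key=lambda a: (a[1].p_hat, a[0]))
    return pd.DataFrame(
        {
            "rank": range(1, len(ordered) + 1),
            "arm": [label for label, _ in ordered],
            "p_hat": [est.p_hat for _, est in ordered],
            "n": [est.n for _, est in ordered],
            "se": [est.se for _, est in ordered],
            "display": [est.display for _, est in ordered],
        }
    )
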