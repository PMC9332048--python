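"""Two-proportion U test for transcriptome support of predicted promoters.

Given m1 supported loci among n1 tested predictions and m2 supported loci
among n2 random control positions, the pooled two-proportion statistic

    U = (m1/n1 - m2/n2) / sqrt( p (1 - p) (1/n1 + 1/n2) ),   p = (m1+m2)/(n1+n2)

is approximately standard normal under H0: equal support rates; the decision
is two-sided with no continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class SupportCounts:
    m1: int  # supported predictions
    n1: int  # predictions tested
    m2: int  # supported random positions
    n2: int  # random positions tested

    def __post_init__(self) -> None:
        for m, n in ((self.m1, self.n1), (self.m2, self.n2)):
            if n <= 0:
                raise ValueError("group sizes must be positive")
            if not 0 <= m <= n:
                raise ValueError("counts must satisfy 0 <= m <= n")


def u_statistic(counts: SupportCounts | tuple[int, int, int, int]) -> float:
    """Pooled two-proportion statistic; undefined when the pooled rate is 0 or 1."""
    c = counts if isinstance(counts, SupportCounts) else SupportCounts(*counts)
    pooled = (c.m1 + c.m2) / (c.n1 + c.n2)
    if pooled <= 0.0 or pooled >= 1.0:
        raise ValueError("pooled proportion is 0 or 1: U is undefined")
    diff = c.m1 / c.n1 - c.m2 / c.n2
    se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / c.n1 + 1.0 / c.n2))
    return float(diff / se)


def decide(u: float, alpha: float = 0.05) -> dict:
    """Two-sided normal test: reject H0 (equal rates) iff |U| > z_{1-alpha/2}."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    critical = float(stats.norm.ppf(1.0 - alpha / 2.0))
    reject = abs(u) > critical
    return {
        "U": float(u),
        "critical": critical,
        "alpha": alpha,
        "decision": "reject H0" if reject else "fail to reject H0",
        "reject": bool(reject),
    }
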