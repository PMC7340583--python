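"""Quantitative mating-efficiency statistics from colony counts.

After a timed filter mating, cells are titered on double selection
(diploids only) and single selection (diploids plus haploids of the tested
mating type). Mating efficiency of a replicate is diploids / total; a
condition is summarized as mean ± s.d. over replicates and compared to a
baseline condition with Welch's t-test on the per-replicate efficiencies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .stats import star_code, welch_t


@dataclass
class MatingCount:
    """Colony counts of one mating replicate.

    diploids: colonies on double selection (−ura −leu); total: colonies on
    single selection (−ura; diploids plus MATa haploids).
    """

    replicate_id: int | str
    diploids: int
    total: int

    def __post_init__(self):
        if self.total <= 0:
            raise ValueError("total colony count must be positive")
        if not 0 <= self.diploids <= self.total:
            raise ValueError("diploids must lie in [0, total]")


@dataclass
class MatingResult:
    """Replicate-level mating efficiency summary for one condition."""

    group: str
    efficiencies: np.ndarray
    mean: float
    sd: float
    n: int
    baseline: str | None = None
    t_statistic: float | None = None
    p_value: float | None = None
    star: str | None = None

    def to_row(self) -> dict:
        return {
            "group": self.group,
            "mean": self.mean,
            "sd": self.sd,
            "n": self.n,
            "baseline": self.baseline,
            "p_vs_baseline": self.p_value,
            "stars": self.star,
        }


def mating_efficiency(count: MatingCount) -> float:
    """Diploid colonies divided by total colonies, a fraction in [0, 1]."""
    return count.diploids / count.total


def summarize_mating(
    counts: Sequence[MatingCount],
    baseline: Sequence[MatingCount] | None = None,
    group: str = "group",
    baseline_name: str = "baseline",
) -> MatingResult:
    """Mean ± s.d. efficiency over replicates, with a Welch test vs baseline.

    Sample s.d. uses the n−1 denominator. Requires at least 2 replicates in
    each group; Welch-test errors (e.g. both groups with zero variance)
    propagate.
    """
    if len(counts) < 2:
        raise ValueError("need at least 2 replicates")
    eff = np.array([mating_efficiency(c) for c in counts], dtype=float)
    result = MatingResult(
        group=group,
        efficiencies=eff,
        mean=float(eff.mean()),
        sd=float(eff.std(ddof=1)),
        n=int(eff.size),
    )
    if baseline is not None:
        if len(baseline) < 2:
            raise ValueError("baseline needs at least 2 replicates")
        base_eff = [mating_efficiency(c) for c in baseline]
        t, _, p = welch_t(eff, base_eff)
        result.baseline = baseline_name
        result.t_statistic = t
        result.p_value = p
        result.star = star_code(p)
    return result
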