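"""Tester-vs-reference field statistics and the shared Welch t machinery.

Within one field of view the tester and reference strains share exposure
settings, so the ratio of group means of per-cell mean wall mCherry is a
normalized expression level. Group location is compared with a two-sided
Mann–Whitney U test (exact null for small groups, midrank/tie-corrected
normal approximation for large ones). The Welch t-test (unequal variances,
Welch–Satterthwaite degrees of freedom) backs the replicate-level
comparisons of the mating assay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps


@dataclass
class FieldComparison:
    """Per-field tester-vs-reference summary."""

    field_id: str
    n_reference: int
    n_tester: int
    mean_reference: float
    sd_reference: float
    mean_tester: float
    sd_tester: float
    normalized_ratio: float  # tester mean / reference mean
    u_statistic: float  # Mann–Whitney U of the tester group
    p_value: float  # two-sided
    star: str = "n.s."
    method: str = "auto"

    def to_row(self) -> dict:
        return {
            "field_id": self.field_id,
            "n_reference": self.n_reference,
            "n_tester": self.n_tester,
            "mean_reference": self.mean_reference,
            "sd_reference": self.sd_reference,
            "mean_tester": self.mean_tester,
            "sd_tester": self.sd_tester,
            "normalized_ratio": self.normalized_ratio,
            "U": self.u_statistic,
            "p_value": self.p_value,
            "star": self.star,
            "method": self.method,
        }


def _group_values(records, identity: str) -> np.ndarray:
    return np.array(
        [r.mean_wall_mcherry for r in records if r.identity == identity], dtype=float
    )


def mann_whitney(
    tester: Sequence[float], reference: Sequence[float], method: str = "auto"
) -> tuple[float, float]:
    """Two-sided Mann–Whitney U (midranks for ties), U for the tester group.

    method="auto" uses the exact null when both groups have <= 20
    observations and the tie-corrected normal approximation above that;
    "exact"/"asymptotic" force a branch.
    """
    tester = np.asarray(tester, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if tester.size == 0 or reference.size == 0:
        raise ValueError("both groups must be non-empty")
    if method == "auto":
        method = "exact" if max(tester.size, reference.size) <= 20 else "asymptotic"
    res = sps.mannwhitneyu(tester, reference, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_strains(
    records: Sequence,
    min_n: int = 80,
    field_id: str | None = None,
    method: str = "auto",
) -> FieldComparison:
    """Tester-vs-reference comparison of per-cell mean wall mCherry.

    Uses only classified cells. Raises when either group is empty; group
    sizes below ``min_n`` (the acquisition aimed for n > 80 per group)
    produce a warning, not an error.
    """
    ref = _group_values(records, "reference")
    tst = _group_values(records, "tester")
    if ref.size == 0 or tst.size == 0:
        raise ValueError(
            f"need both strains: {ref.size} reference, {tst.size} tester cells"
        )
    if min(ref.size, tst.size) < min_n:
        warnings.warn(
            f"group size below min_n={min_n}: reference n={ref.size}, "
            f"tester n={tst.size}",
            stacklevel=2,
        )
    u, p = mann_whitney(tst, ref, method=method)
    mean_ref = float(ref.mean())
    mean_tst = float(tst.mean())
    return FieldComparison(
        field_id=field_id or getattr(records[0], "field_id", "") or "",
        n_reference=int(ref.size),
        n_tester=int(tst.size),
        mean_reference=mean_ref,
        sd_reference=float(ref.std(ddof=1)) if ref.size > 1 else 0.0,
        mean_tester=mean_tst,
        sd_tester=float(tst.std(ddof=1)) if tst.size > 1 else 0.0,
        normalized_ratio=mean_tst / mean_ref,
        u_statistic=u,
        p_value=p,
        star=star_code(p),
        method=method,
    )


def welch_t(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test, two-sided.

    t = (m_a - m_b) / sqrt(s_a^2/n_a + s_b^2/n_b), with Welch–Satterthwaite
    degrees of freedom; p from Student's t distribution.

    Raises when a group has fewer than 2 values or both variances are zero
    (the statistic is undefined).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        raise ValueError("both groups have zero variance; Welch t undefined")
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(min(p, 1.0))


def star_code(p: float) -> str:
    """Figure-legend significance code: *** <0.001, ** <0.01, * <0.05, else n.s.

    All inequalities are strict (p = 0.05 exactly is "n.s.").
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value must lie in [0, 1]; got {p}")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."
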