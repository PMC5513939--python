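"""qPCR relative quantification and two-group comparison statistics.

Relative quantity follows the comparative-Ct scheme with perfect doubling:
ΔCt = Ct(target) − Ct(reference) per sample, ΔΔCt = ΔCt − mean ΔCt of the
calibrator group, RQ = 2^(−ΔΔCt).

The two-sample t-test defaults to the classical equal-variance (Student)
form with a Welch option.  The rank-sum test uses the exact permutation
distribution of the rank sum (computed by dynamic programming) for small
tie-free samples and a tie- and continuity-corrected normal approximation
otherwise.  Bonferroni adjustment multiplies by the number of comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "relative_quantity",
    "t_test_two_tailed",
    "rank_sum_test",
    "bonferroni",
    "DegenerateVarianceError",
]


class DegenerateVarianceError(ValueError):
    """Raised when a t-test is requested on constant, unequal samples."""


@dataclass(frozen=True)
class GroupComparison:
    method: str
    statistic: float
    p: float
    adjusted_p: float | None = None


def relative_quantity(
    measurements: pd.DataFrame, calibrator_group: str
) -> pd.DataFrame:
    """Per-sample RQ = 2^(−ΔΔCt), normalized to the calibrator-group mean ΔCt.

    ``measurements`` needs columns sample_id, group, ct_target, ct_reference.
    Returns a copy with delta_ct, delta_delta_ct and rq columns appended.
    """
    required = {"sample_id", "group", "ct_target", "ct_reference"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    df = measurements.copy()
    for col in ("ct_target", "ct_reference"):
        if not np.isfinite(df[col].to_numpy(dtype=float)).all():
            raise ValueError(f"non-finite Ct values in {col}")
    df["delta_ct"] = df["ct_target"] - df["ct_reference"]
    calibrator = df.loc[df["group"] == calibrator_group, "delta_ct"]
    if calibrator.empty:
        raise ValueError(f"calibrator group {calibrator_group!r} is empty")
    df["delta_delta_ct"] = df["delta_ct"] - calibrator.mean()
    df["rq"] = 2.0 ** (-df["delta_delta_ct"])
    return df


def t_test_two_tailed(
    x: Sequence[float], y: Sequence[float], welch: bool = False
) -> GroupComparison:
    """Two-sample two-tailed t-test (Student by default, Welch on request)."""
    xa, ya = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(xa) < 2 or len(ya) < 2:
        raise ValueError("each sample needs >= 2 observations")
    vx, vy = xa.var(ddof=1), ya.var(ddof=1)
    if vx == 0 and vy == 0:
        if xa.mean() == ya.mean():
            return GroupComparison("student_t_two_tailed", 0.0, 1.0)
        raise DegenerateVarianceError("both samples constant with unequal means")
    t, p = sps.ttest_ind(xa, ya, equal_var=not welch)
    method = "welch_t_two_tailed" if welch else "student_t_two_tailed"
    return GroupComparison(method, float(t), float(p))


def _rank_sum_distribution(n: int, n_x: int) -> np.ndarray:
    """Counts of subsets of {1..n} of size n_x by rank sum (index = sum)."""
    max_sum = n * (n + 1) // 2
    # ways[j][s] = number of size-j subsets with sum s
    ways = np.zeros((n_x + 1, max_sum + 1), dtype=np.float64)
    ways[0][0] = 1.0
    for r in range(1, n + 1):
        for j in range(min(n_x, r), 0, -1):
            ways[j, r:] += ways[j - 1, : max_sum + 1 - r]
    return ways[n_x]


def rank_sum_test(
    x: Sequence[float], y: Sequence[float], exact_limit: int = 10
) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum test on the rank sum of ``x``.

    Exact when both samples have at most ``exact_limit`` observations and no
    value is tied; otherwise a normal approximation with tie and continuity
    corrections.  Exact two-sided p is twice the smaller tail, capped at 1.
    """
    xa, ya = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(xa) < 1 or len(ya) < 1:
        raise ValueError("each sample needs >= 1 observation")
    pooled = np.concatenate([xa, ya])
    n, n_x = len(pooled), len(xa)
    ranks = sps.rankdata(pooled)
    w = float(ranks[:n_x].sum())
    has_ties = len(np.unique(pooled)) < n

    if not has_ties and n_x <= exact_limit and len(ya) <= exact_limit:
        dist = _rank_sum_distribution(n, n_x)
        total = dist.sum()
        wi = int(round(w))
        lower = dist[: wi + 1].sum() / total
        upper = dist[wi:].sum() / total
        p = min(1.0, 2.0 * min(lower, upper))
        return GroupComparison("rank_sum_exact", w, float(p))

    mu = n_x * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / (n * (n - 1)) if n > 1 else 0.0
    var = n_x * len(ya) / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return GroupComparison("rank_sum_normal", w, 1.0)
    z = (w - mu - math.copysign(0.5, w - mu)) / math.sqrt(var) if w != mu else 0.0
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return GroupComparison("rank_sum_normal", w, float(p))


def bonferroni(p_values: Sequence[float]) -> list[float]:
    """Bonferroni adjustment: min(1, p * m) for m comparisons."""
    ps = list(p_values)
    for p in ps:
        if not 0 < p <= 1:
            raise ValueError("p-values must be in (0, 1]")
    m = len(ps)
    return [min(1.0, p * m) for p in ps]
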