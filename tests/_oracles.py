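"""Independent brute-force oracles.

These deliberately re-derive expected results from first principles
(enumeration, exhaustive search, direct rule application) and share no code
with the package implementation they check.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction


def hypergeom_tail_exact(N: int, K: int, n: int, k: int) -> Fraction:
    """P(X >= k) by exact rational enumeration of the hypergeometric pmf."""
    total = math.comb(N, n)
    acc = Fraction(0)
    for i in range(k, min(K, n) + 1):
        acc += Fraction(math.comb(K, i) * math.comb(N - K, n - i), total)
    return acc


def rank_sum_two_sided_exact(x: list[float], y: list[float]) -> Fraction:
    """Two-sided exact rank-sum p by enumerating every group labeling.

    p = 2 * min(P(W <= w), P(W >= w)) capped at 1, where W is the rank sum
    of the first sample.  Assumes no ties.
    """
    pooled = sorted(x + y)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(ranks[v] for v in x)
    n, n_x = len(pooled), len(x)
    lower = upper = 0
    total = 0
    for combo in itertools.combinations(range(1, n + 1), n_x):
        w = sum(combo)
        total += 1
        if w <= w_obs:
            lower += 1
        if w >= w_obs:
            upper += 1
    return min(Fraction(1), 2 * Fraction(min(lower, upper), total))


def find_core_naive(utr: str, core: str) -> list[int]:
    """All (overlapping) start positions of ``core`` in ``utr`` by sliding window."""
    return [i for i in range(len(utr) - len(core) + 1) if utr[i : i + len(core)] == core]


def cascade_oracle(
    rpm1,
    rpm2,
    rpm_mouse,
    groups1,
    groups2,
    groups_mouse,
    seeds_by_id: dict[str, str],
    min_rpm: float = 5.0,
    both_change: float = 0.50,
    single_fold: float = 2.0,
    no_change_band: float = 0.20,
    mouse_change: float = 0.25,
    pseudocount: float = 0.5,
) -> set[str]:
    """Evaluate the selection rules per miRNA, straight from their text.

    Tables are pandas DataFrames (miRNA x sample); groups map sample ->
    'case'/'control'; ``seeds_by_id`` gives the 7-nt seed of every catalog
    miRNA (used for the paralog rule).
    """

    def mean_rpm(table, mid):
        return sum(table.loc[mid]) / len(table.columns)

    def group_mean(table, groups, mid, label):
        cols = [s for s in table.columns if groups[s] == label]
        return sum(table.loc[mid, s] for s in cols) / len(cols)

    def fc_of(table, groups, mid):
        up = group_mean(table, groups, mid, "case") + pseudocount
        down = group_mean(table, groups, mid, "control") + pseudocount
        return up / down

    def changed(fc, frac):
        return fc >= 1 + frac or fc <= 1 / (1 + frac)

    seed_counts: dict[str, int] = {}
    for seed in seeds_by_id.values():
        seed_counts[seed] = seed_counts.get(seed, 0) + 1

    selected = set()
    candidates = set(rpm1.index) & set(rpm2.index) & set(rpm_mouse.index)
    for mid in candidates:
        if not (
            mean_rpm(rpm1, mid) > min_rpm
            and mean_rpm(rpm2, mid) > min_rpm
            and mean_rpm(rpm_mouse, mid) > min_rpm
        ):
            continue
        f1 = fc_of(rpm1, groups1, mid)
        f2 = fc_of(rpm2, groups2, mid)
        fm = fc_of(rpm_mouse, groups_mouse, mid)
        both = changed(f1, both_change) and changed(f2, both_change)
        extreme1 = f1 >= single_fold or f1 <= 1 / single_fold
        extreme2 = f2 >= single_fold or f2 <= 1 / single_fold
        single = (extreme1 and not changed(f2, no_change_band)) or (
            extreme2 and not changed(f1, no_change_band)
        )
        if not (both or single):
            continue
        if not changed(fm, mouse_change):
            continue
        if not ((f1 > 1 and f2 > 1 and fm > 1) or (f1 < 1 and f2 < 1 and fm < 1)):
            continue
        if seed_counts[seeds_by_id[mid]] > 1:
            continue
        selected.add(mid)
    return selected
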