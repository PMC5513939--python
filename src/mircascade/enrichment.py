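"""Down-regulation filtering, target intersection and hypergeometric enrichment.

The enrichment statistic is the upper tail of the hypergeometric
distribution: the probability of drawing at least ``k`` annotated genes in a
query of size ``n`` from a universe of ``N`` genes of which ``K`` carry the
annotation.  The tail is evaluated in log space so that large universes do
not overflow.  Raw p-values are ranked; a Benjamini-Hochberg column is
carried along as a clearly-labelled extra but never used for ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "EnrichmentResult",
    "filter_downregulated",
    "intersect_targets",
    "hypergeom_tail",
    "bh_adjust",
    "enrich",
    "results_to_frame",
]


@dataclass(frozen=True)
class GeneSet:
    """A named gene set (GO term, pathway, ...).  Members must be nonempty."""

    term_id: str
    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.term_id!r} must be nonempty")

    @property
    def member_set(self) -> frozenset[str]:
        return frozenset(self.members)


@dataclass(frozen=True)
class EnrichmentResult:
    """Overlap counts and upper-tail hypergeometric p for one gene set."""

    term_id: str
    name: str
    N: int
    K: int
    n: int
    k: int
    p: float
    bh_q: float | None = None
    rank: int | None = None


def filter_downregulated(ratios: Mapping[str, float] | pd.Series, cutoff: float = 0.8) -> set[str]:
    """Genes whose treated/untreated expression ratio is strictly below ``cutoff``.

    A ratio of exactly ``cutoff`` is excluded.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    series = pd.Series(ratios, dtype=float)
    if series.index.duplicated().any():
        raise ValueError("duplicate gene ids in ratio table")
    if (series <= 0).any() or not np.isfinite(series).all():
        raise ValueError("expression ratios must be finite and > 0")
    return set(series.index[series < cutoff])


def intersect_targets(down: Iterable[str], predicted_targets: Iterable[str]) -> set[str]:
    """Intersect down-regulated genes with a predicted-target gene list."""
    down_set, target_set = set(down), set(predicted_targets)
    result = down_set & target_set
    logger.info(
        "intersect_targets: %d down-regulated ∩ %d predicted targets -> %d genes",
        len(down_set),
        len(target_set),
        len(result),
    )
    return result


def _log_binom(a: float, b: float) -> float:
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts annotated genes in a size-``n`` draw without replacement from a
    universe of ``N`` genes containing ``K`` annotated ones.  Computed in log
    space; returns a value in (0, 1].
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"infeasible parameters N={N}, K={K}, n={n}")
    lo, hi = max(0, n + K - N), min(K, n)
    if not lo <= k <= hi:
        raise ValueError(f"infeasible k={k} for N={N}, K={K}, n={n} (support [{lo}, {hi}])")
    if k <= lo:
        return 1.0
    denom = _log_binom(N, n)
    log_terms = [
        _log_binom(K, i) + _log_binom(N - K, n - i) - denom for i in range(k, hi + 1)
    ]
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values (step-up, monotone-enforced)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    if m == 0:
        return []
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    ranked = np.minimum(ranked, 1.0)
    out = np.empty(m)
    out[order] = ranked
    return out.tolist()


def enrich(
    query: Iterable[str],
    gene_sets: Sequence[GeneSet],
    universe: Iterable[str],
    top_n: int = 10,
    return_all: bool = False,
) -> list[EnrichmentResult]:
    """Rank gene sets by upper-tail hypergeometric p for their query overlap.

    Query genes outside the universe are dropped with a warning; set members
    are intersected with the universe.  Sets with no member in the universe
    are skipped.  Ordering is total: ascending p, ties broken by larger
    overlap ``k``, then lexicographic term id.  The top ``top_n`` results are
    returned unless ``return_all`` is set.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty universe")
    query_set = set(query)
    outside = query_set - universe_set
    if outside:
        logger.warning("enrich: dropping %d query gene(s) outside the universe", len(outside))
        query_set &= universe_set
    N, n = len(universe_set), len(query_set)
    results = []
    for gs in gene_sets:
        members = gs.member_set & universe_set
        K = len(members)
        if K == 0:
            continue
        k = len(members & query_set)
        p = hypergeom_tail(N, K, n, k)
        results.append(EnrichmentResult(gs.term_id, gs.name, N, K, n, k, p))
    results.sort(key=lambda r: (r.p, -r.k, r.term_id))
    qs = bh_adjust([r.p for r in results])
    results = [
        EnrichmentResult(r.term_id, r.name, r.N, r.K, r.n, r.k, r.p, bh_q=q, rank=i + 1)
        for i, (r, q) in enumerate(zip(results, qs))
    ]
    return results if return_all else results[:top_n]


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate enrichment results (one row per term, ranked)."""
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "name": r.name,
                "N": r.N,
                "K": r.K,
                "n": r.n,
                "k": r.k,
                "p": r.p,
                "bh_q": r.bh_q,
                "rank": r.rank,
            }
            for r in results
        ]
    ).set_index("term_id") if results else pd.DataFrame(
        columns=["name", "N", "K", "n", "k", "p", "bh_q", "rank"]
    ).rename_axis("term_id")
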