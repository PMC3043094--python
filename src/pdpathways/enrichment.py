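"""Hypergeometric over-representation of a query gene list against a reference.

For a pathway with K members in a reference universe of N genes and a query
of n genes containing k pathway members, the over-representation p-value is
the inclusive upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).  The
tail is accumulated from log-space pmf terms for numerical stability.  No
multiple-testing correction is applied at this stage; the meta-analysis
corrects the combined p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .models import GeneSetCollection

log = logging.getLogger(__name__)

#: floor applied to reported p-values so downstream log-combination is defined
P_FLOOR = 1e-300

#: below this universe size the tail is computed in exact rational arithmetic;
#: above it, as a stable sum of log-space pmf terms
_EXACT_N_LIMIT = 500


@dataclass(frozen=True)
class EnrichmentResult:
    pathway_id: str
    name: str
    N: int  # reference universe size
    K: int  # pathway members in reference
    n: int  # query size within reference
    k: int  # pathway members in query
    p_value: float


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """Inclusive upper-tail P(X >= k), X ~ Hypergeometric(N, K, n).

    Exact rational arithmetic for small universes; a stable sum of
    log-space pmf terms over [k, min(K, n)] otherwise.  P(X >= 0) = 1
    exactly.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid configuration N={N}, K={K}, n={n}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"impossible overlap k={k} for K={K}, n={n}")
    lo = max(0, n - (N - K))  # smallest achievable overlap
    if k <= lo:
        return 1.0
    hi = min(K, n)
    if N <= _EXACT_N_LIMIT:
        # exact rational tail for small universes
        num = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, hi + 1))
        return float(Fraction(num, comb(N, n)))
    terms = stats.hypergeom.logpmf(np.arange(k, hi + 1), N, K, n)
    return float(min(1.0, np.exp(terms).sum()))


def test_pathways(
    query: set[str],
    reference: set[str],
    pathways: GeneSetCollection,
) -> tuple[list[EnrichmentResult], list[str]]:
    """One EnrichmentResult per pathway with at least one reference member.

    Query genes outside the reference are trimmed with a logged count.
    Pathways with no reference members cannot be tested and are returned
    separately as untested rather than given p = 1.  An empty query yields
    p = 1 everywhere (with a warning).
    """
    if not reference:
        raise ValueError("reference gene list is empty")
    trimmed = query - reference
    if trimmed:
        log.warning(
            "%d query genes are absent from the reference and were trimmed",
            len(trimmed),
        )
    query_in_ref = query & reference
    if not query_in_ref:
        log.warning("query list is empty after trimming; all p-values are 1")
    N, n = len(reference), len(query_in_ref)

    results: list[EnrichmentResult] = []
    untested: list[str] = []
    for pid, name, members in pathways.items():
        K = len(members & reference)
        if K == 0:
            untested.append(pid)
            continue
        k = len(members & query_in_ref)
        p = max(hypergeom_upper_tail(k, N, K, n), P_FLOOR)
        results.append(EnrichmentResult(pid, name, N, K, n, k, p))
    return results, untested


def significant_pathways(results: list[EnrichmentResult], alpha: float) -> set[str]:
    """Pathway ids with p <= alpha (inclusive at the significance level)."""
    return {r.pathway_id for r in results if r.p_value <= alpha}


def results_frame(
    results: list[EnrichmentResult], untested: list[str] | None = None
) -> pd.DataFrame:
    rows = [
        (r.pathway_id, r.name, r.N, r.K, r.n, r.k, r.p_value, True) for r in results
    ]
    if untested:
        rows += [(pid, "", 0, 0, 0, 0, np.nan, False) for pid in untested]
    df = pd.DataFrame(
        rows, columns=["pathway_id", "name", "N", "K", "n", "k", "p_value", "tested"]
    )
    return df.sort_values(["tested", "p_value", "pathway_id"], ascending=[False, True, True]).reset_index(drop=True)
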