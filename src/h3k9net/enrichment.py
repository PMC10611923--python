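"""Hypergeometric over-representation of protein complexes in a query set.

For a query of n proteins drawn from a universe of N, a complex with K
members in the universe, and k of them in the query, the enrichment p-value
is the upper hypergeometric tail P(X >= k). Complexes with fewer than four
members inside the universe are excluded (the catalog floor used for
experimentally verified mammalian complexes). Raw p-values are compared with
the significance cutoff by default, with Benjamini-Hochberg adjusted values
reported alongside.
"""
from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

RESULT_COLUMNS = (
    "term",
    "overlap",
    "term_size",
    "query_size",
    "universe_size",
    "p_value",
    "adjusted_p",
    "significant",
)


def hypergeom_upper_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent parameters: K={K}, n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"overlap k={k} outside 0..min(K={K}, n={n})")
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def overrepresentation(
    query: Iterable[str],
    catalog: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    min_size: int = 4,
    alpha: float = 0.05,
    use_adjusted: bool = False,
) -> pd.DataFrame:
    """Over-representation of every catalog complex in the query set.

    Complex memberships are restricted to the universe first; complexes with
    fewer than ``min_size`` universe members are not tested. ``significant``
    uses the raw p-value against ``alpha`` unless ``use_adjusted``. Rows are
    sorted by p-value, ties by term id.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    query = frozenset(query)
    universe = frozenset(universe)
    if not query <= universe:
        extra = sorted(query - universe)[:5]
        raise ValueError(f"query is not a subset of the universe (e.g. {extra})")
    N, n = len(universe), len(query)
    rows = []
    for term in sorted(catalog):
        members = frozenset(catalog[term]) & universe
        K = len(members)
        if K < min_size:
            continue
        k = len(members & query)
        rows.append((term, k, K, n, N, hypergeom_upper_p(k, K, n, N)))
    result = pd.DataFrame(
        rows, columns=["term", "overlap", "term_size", "query_size", "universe_size", "p_value"]
    )
    if result.empty:
        result["adjusted_p"] = pd.Series(dtype=float)
        result["significant"] = pd.Series(dtype=bool)
        return result[list(RESULT_COLUMNS)]
    result["adjusted_p"] = bh_adjust(result["p_value"])
    basis = result["adjusted_p"] if use_adjusted else result["p_value"]
    result["significant"] = basis <= alpha
    result = result.sort_values(["p_value", "term"], kind="mergesort").reset_index(drop=True)
    return result[list(RESULT_COLUMNS)]
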