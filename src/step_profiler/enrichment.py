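"""Hypergeometric over-representation of a query set against a GMT collection."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .chemoproteomics import benjamini_hochberg
from .errors import ValidationError


@dataclass
class GeneSetCollection:
    """Named gene sets plus a background universe.

    ``sets`` maps set id -> (description, members). Members outside the
    universe are retained here and restricted at test time.
    """

    sets: dict[str, tuple[str, set[str]]]
    universe: set[str]

    def __post_init__(self) -> None:
        if len(self.sets) == 0:
            raise ValidationError("collection has no gene sets")


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n), in log space.

    ``k`` = overlap, ``K`` = set size, ``n`` = query size, ``N`` = universe.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N and K >= 0 and n >= 0):
        raise ValidationError(
            f"inconsistent hypergeometric counts: k={k}, K={K}, n={n}, N={N}"
        )
    if k == 0:
        return 1.0
    support = np.arange(k, min(K, n) + 1)
    log_pmf = stats.hypergeom.logpmf(support, N, K, n)
    return float(min(1.0, np.exp(logsumexp(log_pmf))))


def enrich(
    query: set[str] | list[str],
    collection: GeneSetCollection,
    min_set: int = 5,
    max_set: int = 500,
) -> pd.DataFrame:
    """Over-representation of ``query`` in each collection set, BH-corrected.

    Query and sets are restricted to the universe; sets with restricted size
    outside ``[min_set, max_set]`` are excluded. Returns a DataFrame indexed
    by set id with columns ``description, k, K, n, N, fold_enrichment,
    p_value, p_adj``, sorted by p_value.
    """
    universe = collection.universe
    restricted_query = set(query) & universe
    if not restricted_query:
        raise ValidationError("query has no overlap with the universe")
    N = len(universe)
    n = len(restricted_query)

    rows = []
    for set_id, (description, members) in collection.sets.items():
        restricted = members & universe
        K = len(restricted)
        if not (min_set <= K <= max_set):
            continue
        k = len(restricted_query & restricted)
        fold = (k / n) / (K / N) if K else 0.0
        rows.append((set_id, description, k, K, n, N, fold, hypergeom_tail(k, K, n, N)))
    if not rows:
        raise ValidationError(
            f"no gene set passed the size filter [{min_set}, {max_set}]"
        )
    out = pd.DataFrame(
        rows,
        columns=["set_id", "description", "k", "K", "n", "N", "fold_enrichment", "p_value"],
    ).set_index("set_id")
    out["p_adj"] = benjamini_hochberg(out["p_value"].to_numpy())
    return out.sort_values("p_value", kind="mergesort")
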