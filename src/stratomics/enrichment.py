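"""Over-representation analysis: hypergeometric upper tail + BH adjustment.

For a query of n genes drawn from a universe of N, a term with K members in
the universe, and k genes shared between query and term, the enrichment
p-value is P[X >= k] for X ~ Hypergeometric(N, K, n).  p-values are adjusted
across terms with Benjamini-Hochberg; terms with adjusted p below the
threshold are flagged as retained.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import InputError
from .types import GeneSetCatalog, check_probabilities


def hypergeom_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P[X >= k].

    k: overlap, K: term size in universe, n: query size, N: universe size.
    """
    if min(k, K, n, N) < 0 or N < max(K, n) or k > min(K, n):
        raise InputError(f"impossible hypergeometric parameters k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    arr = check_probabilities(pvalues, "pvalues")
    if arr.size == 0:
        return []
    return list(multipletests(arr, method="fdr_bh")[1])


def enrich(
    query: Iterable[str],
    catalog: GeneSetCatalog,
    padj_thresh: float = 0.05,
) -> pd.DataFrame:
    """One row per term overlapping the query, sorted by p-value.

    The query is silently restricted to the catalog universe (the number of
    discarded symbols is reported in ``table.attrs['discarded']``); duplicate
    query genes are ignored.  Rows with adjusted p below ``padj_thresh`` are
    flagged ``retained``.
    """
    query_set = set(query)
    universe = set(catalog.universe)
    restricted = query_set & universe
    discarded = len(query_set) - len(restricted)
    if not restricted:
        raise InputError("query has no genes in the catalog universe")

    N, n = len(universe), len(restricted)
    rows = []
    for term, (desc, members) in catalog.terms.items():
        mem = members & universe
        k = len(mem & restricted)
        if k < 1:
            continue
        K = len(mem)
        rows.append(
            {
                "term_id": term,
                "description": desc,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "pvalue": hypergeom_p(k, K, n, N),
            }
        )
    table = pd.DataFrame(
        rows, columns=["term_id", "description", "k", "K", "n", "N", "pvalue"]
    )
    if len(table):
        table["padj"] = multipletests(table["pvalue"].to_numpy(), method="fdr_bh")[1]
        table = table.sort_values(["pvalue", "term_id"], kind="mergesort").reset_index(drop=True)
        table["retained"] = table["padj"] < padj_thresh
    else:
        table["padj"] = np.array([], dtype=float)
        table["retained"] = np.array([], dtype=bool)
    table.attrs["discarded"] = discarded
    return table
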