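"""Hypergeometric over-representation analysis with BH FDR control.

Given a query gene set (typically the genes of a displayed subnetwork), a
gene-set collection (GO / KEGG / OMIM-style, all read as GMT) and a gene
universe, each term is tested for enrichment with the upper tail of the
hypergeometric distribution, and p-values are adjusted across the
collection's tested terms with the Benjamini-Hochberg step-up.  Only
over-representation is tested, not depletion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .exceptions import DomainError
from .io import GeneSetCollection, normalize_gene

__all__ = [
    "EnrichmentResult",
    "hypergeom_upper_tail",
    "bh_adjust",
    "enrich",
    "write_enrichment",
]


@dataclass
class EnrichmentResult:
    """One term's over-representation test.

    k = overlap, K = term size in universe, n = query size in universe,
    N = universe size; p is the hypergeometric upper tail P(X >= k) and q
    its BH-adjusted value across the collection.
    """

    term: str
    description: str
    k: int
    K: int
    n: int
    N: int
    p: float
    q: float


def _log_comb(a, b):
    return gammaln(a + 1.0) - gammaln(b + 1.0) - gammaln(a - b + 1.0)


def hypergeom_upper_tail(k, K: int, n: int, N: int):
    """P(X >= k) for X ~ Hypergeometric(N, K, n), stably in log space.

    ``k`` may be an int or an integer array (all entries tested against the
    same K, n, N).  The tail is assembled as a suffix log-sum-exp over the
    exact support, so deep tails (p ~ 1e-100 and below) keep full relative
    precision rather than degrading to 1 - CDF.
    """
    K, n, N = int(K), int(n), int(N)
    if not (0 <= K <= N and 0 <= n <= N):
        raise DomainError(f"require 0 <= K, n <= N; got K={K}, n={n}, N={N}")
    k_arr = np.atleast_1d(np.asarray(k, dtype=np.int64))
    lo, hi = max(0, n + K - N), min(K, n)
    if np.any(k_arr < 0) or np.any(k_arr > hi):
        raise DomainError(f"require 0 <= k <= min(K, n)={hi}")

    j = np.arange(lo, hi + 1)
    logpmf = _log_comb(K, j) + _log_comb(N - K, n - j) - _log_comb(N, n)
    # suffix log-sum-exp: log P(X >= j) for each support point j
    log_tail = np.logaddexp.accumulate(logpmf[::-1])[::-1]
    tails = np.minimum(np.exp(log_tail), 1.0)

    out = np.ones(k_arr.shape)
    above = k_arr > lo  # k <= lo means the whole support: exactly 1
    out[above] = tails[k_arr[above] - lo]
    return float(out[0]) if np.isscalar(k) or np.asarray(k).ndim == 0 else out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise DomainError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    query, collection: GeneSetCollection, universe
) -> list[EnrichmentResult]:
    """Over-representation of a query gene set against a collection.

    Query genes outside the universe are dropped with a warning; terms are
    intersected with the universe and skipped when empty there.  Results
    are sorted by ascending p, ties broken by term ID, with q-values
    adjusted across the collection's tested terms.
    """
    universe = {normalize_gene(g) for g in universe}
    if not universe:
        raise ValueError("universe must be non-empty")
    query = {normalize_gene(g) for g in query}
    dropped = query - universe
    if dropped:
        warnings.warn(
            f"{len(dropped)} query gene(s) outside the universe were dropped",
            stacklevel=2,
        )
    query &= universe
    if not query:
        return []

    N, n = len(universe), len(query)
    rows = []
    for term in sorted(collection.terms):
        desc, genes = collection.terms[term]
        term_in_universe = genes & universe
        K = len(term_in_universe)
        if K == 0:
            continue
        k = len(term_in_universe & query)
        p = hypergeom_upper_tail(k, K, n, N)
        rows.append((term, desc, k, K, p))
    if not rows:
        return []
    qvals = bh_adjust([r[4] for r in rows])
    results = [
        EnrichmentResult(term=t, description=d, k=k, K=K, n=n, N=N, p=p, q=float(q))
        for (t, d, k, K, p), q in zip(rows, qvals)
    ]
    results.sort(key=lambda r: (r.p, r.term))
    return results


def write_enrichment(results: list[EnrichmentResult], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#term\tdescription\tk\tK\tn\tN\tp\tq\n")
        for r in results:
            fh.write(
                f"{r.term}\t{r.description}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t"
                f"{r.p:.6g}\t{r.q:.6g}\n"
            )
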