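"""Hypergeometric term enrichment with BH-FDR, and genotype subtraction.

Enrichment of a query gene set (e.g. TR-bound genes) in user-supplied
gene–term annotations is scored with the one-sided hypergeometric test
(equivalently Fisher's exact upper tail) and adjusted by Benjamini–
Hochberg.  The genotype-differential ("subtraction") analysis keeps the
terms enriched among wild-type-bound genes that are not enriched among
knockout-bound genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genesets import GeneSet
from .io import TermAnnotation

__all__ = [
    "EnrichmentResult",
    "hypergeom_p",
    "bh_fdr",
    "enrich",
    "differential_enrichment",
]


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int  # query ∩ term
    K: int  # term size within background
    n: int  # query size within background
    N: int  # background size
    p_value: float
    fdr: float
    enriched: bool


def hypergeom_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail probability P(X ≥ k), X ~ Hypergeometric(N, K, n).

    ``N`` background genes of which ``K`` carry the term; ``n`` drawn
    (the query); ``k`` observed carrying the term.
    """
    if N < 0 or not (0 <= K <= N) or not (0 <= n <= N):
        raise ValueError(f"inconsistent counts K={K}, n={n}, N={N}")
    if not (0 <= k <= min(n, K)):
        raise ValueError(f"k={k} outside [0, min(n={n}, K={K})]")
    if k == 0:
        return 1.0
    # survival function computed in log space internally by scipy
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return [float(q) for q in adjusted]


def enrich(
    query: GeneSet,
    background: GeneSet,
    terms: Sequence[TermAnnotation],
    fdr_threshold: float = 0.05,
) -> list[EnrichmentResult]:
    """Score every term against the query, BH-adjust, sort by (fdr, p, id).

    Terms are intersected with the background before counting; terms empty
    after restriction are dropped.  ``enriched`` flags fdr < threshold.
    """
    stray = query.gene_ids - background.gene_ids
    if stray:
        shown = ", ".join(sorted(stray)[:5])
        raise ValueError(
            f"{len(stray)} query gene(s) absent from background: {shown}"
        )
    N = len(background.gene_ids)
    n = len(query.gene_ids)
    kept = []
    pvals = []
    for term in terms:
        term_genes = term.gene_ids & background.gene_ids
        K = len(term_genes)
        if K == 0:
            continue
        k = len(term_genes & query.gene_ids)
        kept.append((term, k, K))
        pvals.append(hypergeom_p(k, K, n, N))
    fdrs = bh_fdr(pvals)
    results = [
        EnrichmentResult(
            term_id=term.term_id,
            term_name=term.term_name,
            k=k,
            K=K,
            n=n,
            N=N,
            p_value=p,
            fdr=q,
            enriched=q < fdr_threshold,
        )
        for (term, k, K), p, q in zip(kept, pvals, fdrs)
    ]
    results.sort(key=lambda r: (r.fdr, r.p_value, r.term_id))
    return results


def differential_enrichment(
    enriched_a: Sequence[EnrichmentResult],
    enriched_b: Sequence[EnrichmentResult],
) -> list[EnrichmentResult]:
    """Terms enriched in A but not in B, keeping A's statistics and order."""
    b_enriched = {r.term_id for r in enriched_b if r.enriched}
    return [
        r for r in enriched_a if r.enriched and r.term_id not in b_enriched
    ]
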