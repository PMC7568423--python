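"""Hypergeometric over-representation of a query gene list against gene sets.

For each term of a GMT collection, the p-value is the exact upper tail
P(X >= k) for X ~ Hypergeometric(N, K, n): drawing the n query genes from a
background of N that contains K term members, the chance of k or more hits.
Family-wise error is controlled by the Holm (Bonferroni step-down)
correction; plain Bonferroni is also emitted for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class EnrichmentRecord:
    term_id: str
    description: str
    overlap: int        # k
    term_size: int      # K, within the background
    query_size: int     # n
    background_size: int  # N
    pvalue: float
    holm_p: float | None = None
    bonferroni_p: float | None = None
    members_hit: tuple[str, ...] = ()


def hypergeom_tail_p(k: int, K: int, n: int, N: int) -> float:
    """Exact upper-tail P(X >= k), X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(K, n)) or K > N or n > N or min(k, K, n, N) < 0:
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(min(1.0, stats.hypergeom.sf(k - 1, N, K, n)))


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="holm")[1]


def enrich_terms(query, collection: dict[str, tuple[str, list[str]]],
                 background) -> list[EnrichmentRecord]:
    """Over-representation of ``query`` in each term of ``collection``.

    Term members are intersected with the background before the term size K
    is computed; terms with K = 0 are not tested. Records are sorted by raw
    p ascending; Holm and Bonferroni are computed across all tested terms.
    """
    query = set(query)
    bg = set(background)
    if not query:
        raise ValueError("empty query gene set")
    stray = sorted(query - bg)
    if stray:
        raise ValueError(f"query genes not in background: {stray[:10]}")
    N, n = len(bg), len(query)
    records: list[EnrichmentRecord] = []
    for term, (desc, members) in collection.items():
        in_bg = [m for m in dict.fromkeys(members) if m in bg]
        K = len(in_bg)
        if K == 0:
            continue
        hits = tuple(m for m in in_bg if m in query)
        k = len(hits)
        records.append(EnrichmentRecord(
            term_id=term, description=desc, overlap=k, term_size=K,
            query_size=n, background_size=N,
            pvalue=hypergeom_tail_p(k, K, n, N), members_hit=hits,
        ))
    if records:
        raw = [r.pvalue for r in records]
        holm = holm_adjust(raw)
        bonf = np.minimum(1.0, np.asarray(raw) * len(raw))
        for r, h, b in zip(records, holm, bonf):
            r.holm_p = float(h)
            r.bonferroni_p = float(b)
    records.sort(key=lambda r: (r.pvalue, r.term_id))
    return records


def records_to_frame(records: list[EnrichmentRecord]):
    import pandas as pd
    return pd.DataFrame({
        "term_id": [r.term_id for r in records],
        "description": [r.description for r in records],
        "overlap": [r.overlap for r in records],
        "term_size": [r.term_size for r in records],
        "query_size": [r.query_size for r in records],
        "background_size": [r.background_size for r in records],
        "pvalue": [r.pvalue for r in records],
        "holm_p": [r.holm_p for r in records],
        "bonferroni_p": [r.bonferroni_p for r in records],
        "members_hit": ["|".join(r.members_hit) for r in records],
    })
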