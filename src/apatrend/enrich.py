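"""Gene-set over-representation of called gene lists.

Fold enrichment is (list hits / list size) / (population hits / population
size).  The p-value is the EASE score: the upper-tail hypergeometric
probability computed with one list hit removed (a conservative variant of
Fisher's one-tailed test used by the DAVID annotation service); a plain
Fisher variant is available.  Rows are BH-adjusted with the same step-up
code used by the switch and expression stages.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .apaswitch import bh_fdr
from .refio import GeneSetCollection


@dataclass
class EnrichmentRow:
    set_id: str
    set_name: str
    list_hits: int  # k
    list_size: int  # n
    pop_hits: int  # K
    pop_size: int  # N
    fold: float
    p: float
    fdr: float = float("nan")


def fold_enrichment(k: int, n: int, big_k: int, big_n: int) -> float:
    """(k/n) / (K/N); zero when the list has no hits."""
    if n <= 0 or big_k <= 0 or big_n <= 0:
        raise ValueError("list size, population hits and population size must be > 0")
    return (k * big_n) / (n * big_k)


def ease_test(k: int, n: int, big_k: int, big_n: int, penalize: bool = True) -> float:
    """One-tailed over-representation p-value.

    With ``penalize`` (EASE): P(X >= k - 1) under Hypergeom(N, K, n), so a
    single hit is never significant (k=1 gives p=1); k=0 gives p=1.
    Without: plain Fisher upper tail P(X >= k).
    """
    if not (0 <= k <= min(n, big_k) and k <= n <= big_n and big_k <= big_n):
        raise ValueError(f"inconsistent contingency values k={k} n={n} K={big_k} N={big_n}")
    k_eff = k - 1 if penalize else k
    if k_eff <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k_eff - 1, big_n, big_k, n))


def enrich_list(
    genes: list[str],
    sets: GeneSetCollection,
    background: list[str],
    penalize: bool = True,
) -> list[EnrichmentRow]:
    """One EnrichmentRow per gene set with >= 1 list hit, sorted by p.

    ``background`` is the universe of testable genes; the query list is
    restricted to it.  Set memberships are intersected with the background
    before computing K.
    """
    bg = set(background)
    if not bg:
        raise ValueError("empty background")
    query = set(genes) & bg
    rows = []
    for sid, (name, members) in sets.sets.items():
        pop_hits = members & bg
        hits = query & pop_hits
        if not hits or not pop_hits:
            continue
        k, n, big_k, big_n = len(hits), len(query), len(pop_hits), len(bg)
        rows.append(
            EnrichmentRow(
                sid,
                name,
                k,
                n,
                big_k,
                big_n,
                fold_enrichment(k, n, big_k, big_n),
                ease_test(k, n, big_k, big_n, penalize),
            )
        )
    rows.sort(key=lambda r: (r.p, r.set_id))
    fdrs = bh_fdr([r.p for r in rows]) if rows else []
    for r, q in zip(rows, fdrs):
        r.fdr = float(q)
    return rows


def enrichment_to_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "set_id": [r.set_id for r in rows],
            "set_name": [r.set_name for r in rows],
            "list_hits": [r.list_hits for r in rows],
            "list_size": [r.list_size for r in rows],
            "pop_hits": [r.pop_hits for r in rows],
            "pop_size": [r.pop_size for r in rows],
            "enrichment_fold": [round(r.fold, 2) for r in rows],
            "p": [r.p for r in rows],
            "fdr": [r.fdr for r in rows],
        }
    )
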