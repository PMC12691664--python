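"""Hypergeometric over-representation analysis of day/night gene sets.

For a query gene list against a pathway collection, the upper-tail
hypergeometric p-value asks how surprising the observed overlap is when
drawing the query from the expression-filtered universe.  Raw p-values map
to the reporting tiers <=0.001, <=0.01, <=0.05, <=0.1, ns; BH-adjusted
q-values are reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import pandas as pd

from .diel_stats import bh_adjust
from .errors import InputError

TIER_EDGES = ((0.001, "<=0.001"), (0.01, "<=0.01"), (0.05, "<=0.05"), (0.1, "<=0.1"))


@dataclass
class GeneSetCollection:
    """Named, non-empty gene sets (GMT-backed), order-preserving."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise InputError(f"gene set {name!r} is empty")

    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Exact upper-tail P(X >= k), X ~ Hypergeometric(N items, K successes,
    n draws); integer arithmetic, no approximation."""
    if not (0 <= k <= min(K, n) and 0 <= K <= N and 0 <= n <= N):
        raise InputError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    total = comb(N, n)
    tail = sum(comb(K, x) * comb(N - K, n - x) for x in range(k, min(K, n) + 1))
    return tail / total


def p_tier(p: float) -> str:
    for edge, label in TIER_EDGES:
        if p <= edge:
            return label
    return "ns"


def enrich_sets(
    query: set[str],
    universe: set[str],
    collection: GeneSetCollection,
) -> pd.DataFrame:
    """One row per pathway: overlap, p, BH q across tested sets, and tier.

    Sets are intersected with the universe first; sets with zero overlap are
    reported but excluded from testing (p, q, tier = NA).
    """
    query = set(query)
    universe = set(universe)
    stray = query - universe
    if stray:
        raise InputError(f"query genes outside the universe: {sorted(stray)[:10]}")
    N, n = len(universe), len(query)
    rows = []
    for name in collection.names():
        members = set(collection.sets[name]) & universe
        K = len(members)
        k = len(members & query)
        p = hypergeom_pvalue(k, K, n, N) if k >= 1 else float("nan")
        rows.append({"set": name, "overlap": k, "set_size": K,
                     "query_size": n, "universe_size": N, "p": p})
    table = pd.DataFrame(rows)
    tested = table["p"].notna()
    table["q"] = float("nan")
    if tested.any():
        table.loc[tested, "q"] = bh_adjust(table.loc[tested, "p"].to_numpy())
    table["tier"] = [p_tier(p) if pd.notna(p) else "not_tested" for p in table["p"]]
    return table
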