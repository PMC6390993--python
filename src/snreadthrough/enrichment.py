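"""Representation-factor enrichment with exact hypergeometric p-values.

For a query list of n genes out of a universe of N, a gene set of size K
overlapping the query in k genes has representation factor
RF = (k*N)/(K*n), the observed/expected overlap ratio, with the upper-tail
hypergeometric probability P(X >= k) as its p-value (the convention of the
standard over-representation calculators).  Multiple sets are corrected by
Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence, Set

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class EnrichmentResult:
    set_name: str
    k: int
    K: int
    n: int
    N: int
    RF: float
    p: float
    q: float


def _check_bounds(k: int, K: int, n: int, N: int) -> None:
    if K <= 0 or n <= 0:
        raise ValueError("K and n must be positive")
    if N < max(K, n):
        raise ValueError("universe N smaller than a set")
    if not 0 <= k <= min(K, n):
        raise ValueError("overlap k outside [0, min(K, n)]")


def representation_factor(k: int, K: int, n: int, N: int) -> float:
    """Observed/expected overlap ratio (k*N)/(K*n)."""
    _check_bounds(k, K, n, N)
    return (k * N) / (K * n)


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    Evaluated through the survival function of the hypergeometric
    distribution, which works in log space and stays accurate for the
    extreme tails enrichment analyses produce.
    """
    _check_bounds(k, K, n, N)
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    q_(i) = min_{j >= i} p_(j) * m / j over the sorted p-values, capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def enrich(query: Set[str], catalogs: Mapping[str, Set[str]],
           universe: Set[str]) -> pd.DataFrame:
    """RF/hypergeometric enrichment of each catalog against a query list.

    All sets are intersected with the universe first; the universe size N is
    always reported so results are self-describing.
    """
    query = set(query) & set(universe)
    n, N = len(query), len(universe)
    rows = []
    for name in sorted(catalogs):
        members = set(catalogs[name]) & set(universe)
        K = len(members)
        k = len(members & query)
        rows.append({
            "set_name": name, "k": k, "K": K, "n": n, "N": N,
            "RF": representation_factor(k, K, n, N),
            "p": hypergeom_pvalue(k, K, n, N),
        })
    table = pd.DataFrame(rows)
    table["q"] = bh_adjust(table["p"].to_numpy()) if len(table) else []
    return table


def overlap_table(named_sets: Mapping[str, Set[str]]) -> pd.DataFrame:
    """Inclusive and exclusive intersection counts for every set combination.

    ``inclusive`` counts elements present in all named sets of the combination
    regardless of membership elsewhere; ``exclusive`` counts elements in
    exactly those sets.  Exclusive counts partition the union.
    """
    if len(named_sets) < 2:
        raise ValueError("need at least 2 sets")
    names = sorted(named_sets)
    membership: dict[str, frozenset[str]] = {}
    for el in set().union(*named_sets.values()):
        membership[el] = frozenset(n for n in names if el in named_sets[n])
    rows = []
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            cset = frozenset(combo)
            inclusive = len(set.intersection(*(set(named_sets[n]) for n in combo)))
            exclusive = sum(1 for m in membership.values() if m == cset)
            rows.append({
                "combination": "&".join(combo), "degree": r,
                "inclusive": inclusive, "exclusive": exclusive,
            })
    return pd.DataFrame(rows)


def overlaps_to_upset_json(named_sets: Mapping[str, Set[str]]) -> dict:
    """UpSet-style JSON layout of the overlap table."""
    table = overlap_table(named_sets)
    return {
        "sets": [{"name": n, "size": len(named_sets[n])}
                 for n in sorted(named_sets)],
        "intersections": [
            {"sets": row["combination"].split("&"),
             "inclusive": int(row["inclusive"]),
             "exclusive": int(row["exclusive"])}
            for _, row in table.iterrows()
        ],
    }


def read_gene_sets(path) -> dict[str, set[str]]:
    """Two-column TSV (set_name, gene_id) -> named gene sets."""
    df = pd.read_csv(path, sep="\t", header=None, names=["set_name", "gene_id"])
    return {name: set(sub["gene_id"]) for name, sub in df.groupby("set_name")}


def write_gene_sets(sets: Mapping[str, Set[str]], path) -> None:
    rows = [(name, gid) for name in sorted(sets) for gid in sorted(sets[name])]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
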