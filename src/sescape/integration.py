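"""Joining enhancer/SE categories with expression results.

Three readouts: (i) do genes near one enhancer category shift expression
relative to another (rank-sum comparison of log2 fold changes), (ii) which
disease-SE-driven, disease-up-regulated genes are reversed by treatment
(the three-way "rescued gene" intersection), and (iii) which user-supplied
gene sets are over-represented among a hit list (hypergeometric ORA).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

EXACT_MAX_N = 8


@dataclass
class CategoryExpression:
    name: str
    genes: list[str]
    log2fc: np.ndarray


def mannwhitney_exact(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p by full enumeration of group assignments.

    Enumerates all C(n+m, n) splits of the pooled values, computes the
    Mann-Whitney U of each (with 0.5 credit for ties) and returns the
    fraction of splits whose U deviates from the null mean n*m/2 at least
    as much as the observed one. Exact under exchangeability, ties included.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])

    def u_stat(idx: tuple[int, ...]) -> float:
        mask = np.zeros(n + m, dtype=bool)
        mask[list(idx)] = True
        a, b = pooled[mask], pooled[~mask]
        gt = np.sum(a[:, None] > b[None, :])
        ties = np.sum(a[:, None] == b[None, :])
        return float(gt) + 0.5 * float(ties)

    u_obs = u_stat(tuple(range(n)))
    center = n * m / 2.0
    dev_obs = abs(u_obs - center)
    total = comb(n + m, n)
    extreme = 0
    for idx in combinations(range(n + m), n):
        if abs(u_stat(idx) - center) >= dev_obs - 1e-12:
            extreme += 1
    return extreme / total


def mannwhitney_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p: exact enumeration when both groups are small
    (<= 8), otherwise the normal approximation with tie correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    if len(x) <= EXACT_MAX_N and len(y) <= EXACT_MAX_N:
        return mannwhitney_exact(x, y)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def compare_category_expression(
    categories: dict[str, set[str]], de: pd.DataFrame
) -> tuple[list[CategoryExpression], dict[tuple[str, str], float]]:
    """Rank-sum comparison of log2 fold changes between gene categories.

    Each category is joined to the DE table by gene id; every unordered
    category pair gets a two-sided Mann-Whitney p-value. A category with
    no gene present in the DE table is an error (it would silently produce
    no comparison).
    """
    cats: list[CategoryExpression] = []
    for name, genes in categories.items():
        present = sorted(g for g in genes if g in de.index)
        if not present:
            raise ValueError(f"category {name!r} has no genes in the DE table")
        cats.append(
            CategoryExpression(name, present, de.loc[present, "log2fc"].to_numpy())
        )
    pvals: dict[tuple[str, str], float] = {}
    for c1, c2 in combinations(cats, 2):
        pvals[(c1.name, c2.name)] = mannwhitney_p(c1.log2fc, c2.log2fc)
    return cats, pvals


@dataclass
class RescueResult:
    """Venn decomposition of SE-driven / disease-up / treatment-down genes."""

    se_driven: set[str]
    up_in_disease: set[str]
    down_on_treatment: set[str]
    rescued: set[str]

    def venn_counts(self) -> dict[str, int]:
        a, b, c = self.se_driven, self.up_in_disease, self.down_on_treatment
        return {
            "se_only": len(a - b - c),
            "up_only": len(b - a - c),
            "down_only": len(c - a - b),
            "se_and_up": len((a & b) - c),
            "se_and_down": len((a & c) - b),
            "up_and_down": len((b & c) - a),
            "rescued": len(a & b & c),
        }


def rescued_genes(
    se_genes: set[str], up_set: set[str], down_set: set[str]
) -> RescueResult:
    """Genes driven by condition-specific SEs, up in disease, reversed by treatment."""
    return RescueResult(
        se_driven=set(se_genes),
        up_in_disease=set(up_set),
        down_on_treatment=set(down_set),
        rescued=set(se_genes) & set(up_set) & set(down_set),
    )


@dataclass
class OraResult:
    set_name: str
    k: int  # hits in the set
    K: int  # set size within the universe
    n: int  # total hits
    N: int  # universe size
    p: float
    q: float = np.nan

    @property
    def enrichment_ratio(self) -> float:
        if self.n == 0 or self.K == 0:
            return np.nan
        return (self.k / self.n) / (self.K / self.N)


def ora_hypergeom(
    hits: set[str], gene_sets: dict[str, set[str]], universe: set[str]
) -> list[OraResult]:
    """Hypergeometric over-representation of each gene set among the hits.

    p = P(X >= k) with X ~ Hypergeometric(N, K, n) where N is the universe
    size, K the set size after intersecting with the universe, n the hit
    count. Sets empty after intersection are skipped; BH correction is
    applied across the tested sets. Results are sorted by p ascending.
    """
    if not hits <= universe:
        raise ValueError("hits must be a subset of the universe")
    N, n = len(universe), len(hits)
    results: list[OraResult] = []
    for name, members in gene_sets.items():
        in_universe = members & universe
        K = len(in_universe)
        if K == 0:
            continue
        k = len(hits & in_universe)
        # upper tail including k itself; k = 0 gives exactly 1
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        results.append(OraResult(name, k, K, n, N, min(p, 1.0)))
    if results:
        qs = bh_adjust([r.p for r in results])
        for r, q in zip(results, qs):
            r.q = float(q)
    results.sort(key=lambda r: (r.p, r.set_name))
    return results


def se_driven_genes(assignments, category_region_ids: set[str]) -> set[str]:
    """Genes assigned (>=1 region) from a set of SE region ids; deduplicated."""
    return {
        a.gene_id
        for a in assignments
        if a.gene_id is not None and a.region_id in category_region_ids
    }
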