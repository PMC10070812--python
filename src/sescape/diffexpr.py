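"""Negative-binomial differential expression for two-condition count matrices.

A deliberately transparent stage in the spirit of the standard NB
framework: median-of-ratios size factors, a pooled method-of-moments
dispersion per gene, a Wald test on the log2 fold change with a
delta-method standard error, and Benjamini-Hochberg FDR control. It omits
dispersion shrinkage, outlier (Cook's) filtering and fold-change
moderation on purpose — every number it produces is reproducible from the
formulas below, which makes it calibratable against simulation.

Two threshold presets are provided and the caller must pick one:
``results`` (q < 0.01, |log2FC| >= 1) and ``methods`` (q < 0.05,
|log2FC| >= 1, i.e. fold change <= -2 or >= 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: named (q_max, lfc_min) threshold presets
PRESETS: dict[str, tuple[float, float]] = {
    "results": (0.01, 1.0),
    "methods": (0.05, 1.0),
}

DISPERSION_FLOOR = 1e-8
PSEUDOCOUNT = 0.5


@dataclass
class CountMatrix:
    """Genes x samples integer counts with a condition label per sample."""

    counts: pd.DataFrame
    conditions: dict[str, str]

    def __post_init__(self) -> None:
        vals = self.counts.to_numpy()
        if np.any(vals < 0):
            raise ValueError("counts must be >= 0")
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be integral")
        if self.counts.index.has_duplicates:
            raise ValueError("gene ids must be unique")
        missing = set(self.counts.columns) - set(self.conditions)
        if missing:
            raise ValueError(f"samples without condition label: {sorted(missing)}")

    def samples_for(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns if self.conditions[s] == condition]


def read_counts(counts_path: str, groups_path: str) -> CountMatrix:
    """Read a tab-separated count table (gene id index, sample header) and a
    two-column sample-to-condition map."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    groups = pd.read_csv(
        groups_path, sep="\t", header=None, names=["sample", "condition"]
    )
    conditions = dict(zip(groups["sample"].astype(str), groups["condition"]))
    return CountMatrix(counts, conditions)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For genes with nonzero counts in every sample, factor_j is the median
    of count_gj / geometric-mean_g(count). Requires at least one such gene.
    """
    vals = counts.to_numpy(dtype=float)
    all_nonzero = np.all(vals > 0, axis=1)
    if not np.any(all_nonzero):
        raise ValueError(
            "no gene has nonzero counts in all samples; size factors are "
            "undefined — supply a pseudo-reference or filter samples"
        )
    sub = vals[all_nonzero]
    log_geomean = np.mean(np.log(sub), axis=1)
    ratios = np.log(sub) - log_geomean[:, None]
    return pd.Series(np.exp(np.median(ratios, axis=0)), index=counts.columns)


def bh_adjust(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in the input order."""
    p = np.asarray(p, dtype=float)
    if p.size and (np.min(p) < 0 or np.max(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def nb_wald(
    matrix: CountMatrix,
    group_a: str,
    group_b: str,
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-gene NB Wald test of group_b versus group_a.

    Counts are normalized by size factors; the per-gene dispersion is a
    pooled method-of-moments estimate alpha = max(0, (s^2 - m)/m^2) from
    the within-group sample variances, moderated by flooring each gene's
    estimate at the across-gene median and then at 1e-8; the reported
    log2 fold change is log2((mean_b + c)/(mean_a + c)) and its standard
    error comes from the delta method under Var = m + alpha*m^2.

    Returns a DataFrame indexed by gene with columns baseMean, log2fc, p, q.
    """
    cols_a = matrix.samples_for(group_a)
    cols_b = matrix.samples_for(group_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("each compared group needs at least 2 samples")
    sf = size_factors(matrix.counts[cols_a + cols_b])
    norm = matrix.counts[cols_a + cols_b].to_numpy(dtype=float) / sf.to_numpy()
    na, nb = len(cols_a), len(cols_b)
    xa, xb = norm[:, :na], norm[:, na:]
    mean_a = xa.mean(axis=1)
    mean_b = xb.mean(axis=1)
    base_mean = norm.mean(axis=1)

    # pooled within-group variance (df-weighted) and grand within-group mean
    ss = np.sum((xa - mean_a[:, None]) ** 2, axis=1) + np.sum(
        (xb - mean_b[:, None]) ** 2, axis=1
    )
    s2 = ss / (na + nb - 2)
    m_bar = (na * mean_a + nb * mean_b) / (na + nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(m_bar > 0, (s2 - m_bar) / np.maximum(m_bar, 1e-300) ** 2, 0.0)
    alpha = np.maximum(alpha, 0.0)
    # moderate the noisy per-gene estimate by flooring it at the across-gene
    # median: with few replicates the raw moment estimate is often 0, which
    # would wildly overstate significance, while genes with genuinely high
    # dispersion keep their own estimate
    if alpha.size:
        alpha = np.maximum(alpha, float(np.median(alpha)))
    alpha = np.maximum(alpha, DISPERSION_FLOOR)

    log2fc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))
    var_ma = (mean_a + alpha * mean_a**2) / na
    var_mb = (mean_b + alpha * mean_b**2) / nb
    ln2 = np.log(2.0)
    se = np.sqrt(
        var_ma / (mean_a + pseudocount) ** 2 + var_mb / (mean_b + pseudocount) ** 2
    ) / ln2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, 0.0, 1.0)
    # both groups flat at the same level: a genuine null identity
    p[(se == 0) & (log2fc == 0)] = 1.0
    q = bh_adjust(p)
    return pd.DataFrame(
        {"baseMean": base_mean, "log2fc": log2fc, "p": p, "q": q},
        index=matrix.counts.index,
    )


def de_filter(
    table: pd.DataFrame, q_max: float = 0.01, lfc_min: float = 1.0
) -> tuple[set[str], set[str]]:
    """Split a DE table into (up, down) gene sets.

    q is compared strictly (< q_max); |log2fc| inclusively (>= lfc_min) —
    the boundary conventions are part of the contract.
    """
    sig = table["q"] < q_max
    up = set(table.index[sig & (table["log2fc"] >= lfc_min)])
    down = set(table.index[sig & (table["log2fc"] <= -lfc_min)])
    return up, down


def de_filter_preset(table: pd.DataFrame, preset: str = "results") -> tuple[set[str], set[str]]:
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    q_max, lfc_min = PRESETS[preset]
    return de_filter(table, q_max=q_max, lfc_min=lfc_min)
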