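"""MA-plot normalization of paired peak signals between two conditions.

Between-condition comparisons of ChIP-seq peak intensity are confounded by
global differences in immunoprecipitation efficiency and depth. Following
the MAnorm model, peaks common to both conditions are assumed unchanged on
average; a robust linear fit of M = log2(x/y) against A = mean log
intensity over common peaks captures the global bias, and subtracting the
fitted line rescales M for every peak. A two-sided binomial test on the
rescaled densities gives a per-peak differential P-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .genomic_io import GenomicInterval, Peak, PeakSet, SignalTrack
from .peak_landscape import PeakCategories

PSEUDOCOUNT = 0.5
#: per-bp weight turning a density into a pseudo-count for the binomial test
LIBRARY_WEIGHT = 1.0


@dataclass
class NormalizedPeakPair:
    """Per-peak densities in two conditions with MA statistics."""

    peak_id: str
    chrom: str
    start: int
    end: int
    x: float
    y: float
    M: float
    A: float
    M_norm: float = np.nan
    p: float = np.nan
    is_common: bool = False


@dataclass(frozen=True)
class ManormFit:
    """Robust linear trend M = a + b*A fitted on common peaks."""

    intercept: float
    slope: float
    n_common: int


def peak_read_density(peak: Peak, track: SignalTrack) -> float:
    """Length-weighted mean signal over the peak interval (0 on empty track)."""
    return track.mean(peak.chrom, peak.start, peak.end)


def ma_transform(
    x: float, y: float, pseudocount: float = PSEUDOCOUNT
) -> tuple[float, float]:
    """(M, A) = (log2((x+c)/(y+c)), 0.5*log2((x+c)(y+c))) for densities x, y."""
    if x < 0 or y < 0:
        raise ValueError(f"densities must be >= 0, got ({x}, {y})")
    xm, ym = x + pseudocount, y + pseudocount
    return float(np.log2(xm / ym)), float(0.5 * np.log2(xm * ym))


def fit_manorm(common: Iterable[tuple[float, float]]) -> ManormFit:
    """Fit the MA trend on common peaks by Huber robust regression (t = 1.345).

    Robustness matters because a minority of common peaks may be genuinely
    differential; Huber downweights them instead of letting them drag the
    global trend.
    """
    pts = np.asarray(list(common), dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 common peaks to fit the MA trend")
    m, a = pts[:, 0], pts[:, 1]
    if np.allclose(m, m[0]):
        return ManormFit(intercept=float(m[0]), slope=0.0, n_common=len(m))
    X = sm.add_constant(a)
    res = sm.RLM(m, X, M=sm.robust.norms.HuberT(t=1.345)).fit()
    return ManormFit(
        intercept=float(res.params[0]), slope=float(res.params[1]), n_common=len(m)
    )


def normalize_m(
    pairs: Sequence[NormalizedPeakPair], fit: ManormFit
) -> list[NormalizedPeakPair]:
    """Subtract the fitted trend: M_norm = M - (a + b*A). Returns new pairs."""
    out = []
    for p in pairs:
        m_norm = p.M - (fit.intercept + fit.slope * p.A)
        out.append(
            NormalizedPeakPair(
                p.peak_id, p.chrom, p.start, p.end, p.x, p.y, p.M, p.A,
                M_norm=m_norm, p=p.p, is_common=p.is_common,
            )
        )
    return out


def binom_pvalue(x: float, y: float) -> float:
    """Two-sided binomial P-value for a (x, y) count pair under H0: p = 1/2.

    Inputs are rounded to the nearest integer; with n = x + y and
    X ~ Binomial(n, 1/2), p = min(1, 2 * min(P(X <= x), P(X >= x))).
    A zero total yields p = 1.
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be >= 0")
    xi, yi = int(round(x)), int(round(y))
    n = xi + yi
    if n == 0:
        return 1.0
    lower = stats.binom.cdf(xi, n, 0.5)
    upper = stats.binom.sf(xi - 1, n, 0.5)
    return float(min(1.0, 2.0 * min(lower, upper)))


def _adjusted_y(pair: NormalizedPeakPair, fit: ManormFit) -> float:
    """Condition-B density rescaled so that its M against x equals M_norm."""
    shift = fit.intercept + fit.slope * pair.A
    return (pair.y + PSEUDOCOUNT) * 2.0**shift - PSEUDOCOUNT


def manorm_table(
    categories: PeakCategories,
    track_a: SignalTrack,
    track_b: SignalTrack,
    pseudocount: float = PSEUDOCOUNT,
) -> tuple[list[NormalizedPeakPair], ManormFit]:
    """Full MA normalization of a classified two-condition landscape.

    Common pairs are measured over the union interval of the pair on each
    condition's own track; specific peaks over their own interval. The
    trend is fitted on common pairs only, then M_norm and the binomial
    P-value (on length-weighted pseudo-counts with the fitted rescaling
    applied to condition B) are computed for every entry.
    """
    pairs: list[NormalizedPeakPair] = []
    for pa, pb in categories.common_pairs:
        start = min(pa.start, pb.start)
        end = max(pa.end, pb.end)
        union = GenomicInterval(pa.chrom, start, end)
        x = track_a.mean(union.chrom, union.start, union.end)
        y = track_b.mean(union.chrom, union.start, union.end)
        m, a = ma_transform(x, y, pseudocount)
        pairs.append(
            NormalizedPeakPair(
                f"{pa.name}|{pb.name}", union.chrom, start, end, x, y, m, a,
                is_common=True,
            )
        )
    for spec_set in (categories.a_specific, categories.b_specific):
        for p in spec_set:
            x = track_a.mean(p.chrom, p.start, p.end)
            y = track_b.mean(p.chrom, p.start, p.end)
            m, a = ma_transform(x, y, pseudocount)
            pairs.append(NormalizedPeakPair(p.name, p.chrom, p.start, p.end, x, y, m, a))
    fit = fit_manorm([(p.M, p.A) for p in pairs if p.is_common])
    pairs = normalize_m(pairs, fit)
    out = []
    for p in pairs:
        length = p.end - p.start
        x_cnt = p.x * length * LIBRARY_WEIGHT
        y_cnt = max(_adjusted_y(p, fit), 0.0) * length * LIBRARY_WEIGHT
        pval = binom_pvalue(x_cnt, y_cnt)
        out.append(
            NormalizedPeakPair(
                p.peak_id, p.chrom, p.start, p.end, p.x, p.y, p.M, p.A,
                M_norm=p.M_norm, p=pval, is_common=p.is_common,
            )
        )
    return out, fit


def write_manorm_table(pairs: Sequence[NormalizedPeakPair], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("peak_id\tchrom\tstart\tend\tx\ty\tM\tA\tM_norm\tp\tis_common\n")
        for p in pairs:
            fh.write(
                f"{p.peak_id}\t{p.chrom}\t{p.start}\t{p.end}\t{p.x:.6g}\t{p.y:.6g}\t"
                f"{p.M:.6g}\t{p.A:.6g}\t{p.M_norm:.6g}\t{p.p:.6g}\t{int(p.is_common)}\n"
            )
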