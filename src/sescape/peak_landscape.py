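"""Two-condition peak landscape: common/specific classification and signal profiles.

A peak present in both conditions (overlapping >=1 bp with a peak of the
other condition) is "common"; otherwise it is condition-specific. Composite
profiles average the normalized signal in fixed windows around peak centers,
the standard view of how a chromatin mark distributes around its peaks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genomic_io import Peak, PeakSet, SignalTrack


@dataclass
class PeakCategories:
    """Decomposition of two peak sets into overlap classes.

    ``common_pairs`` holds every overlapping (A-peak, B-peak) pair; a peak
    overlapping several partners contributes several pairs but is counted
    once in the per-category totals.
    """

    common_pairs: list[tuple[Peak, Peak]]
    a_specific: PeakSet
    b_specific: PeakSet

    @property
    def common_a(self) -> list[Peak]:
        seen: dict[str, Peak] = {}
        for pa, _ in self.common_pairs:
            seen.setdefault(pa.name, pa)
        return list(seen.values())

    @property
    def common_b(self) -> list[Peak]:
        seen: dict[str, Peak] = {}
        for _, pb in self.common_pairs:
            seen.setdefault(pb.name, pb)
        return list(seen.values())

    def counts(self) -> dict[str, int]:
        return {
            "common_a": len(self.common_a),
            "common_b": len(self.common_b),
            "a_specific": len(self.a_specific),
            "b_specific": len(self.b_specific),
        }


@dataclass
class CompositeProfile:
    """Mean signal in ``nbins`` equal bins across +-``window`` bp around peak centers."""

    window: int
    nbins: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.nbins,):
            raise ValueError("values length must equal nbins")


def classify_peaks(a: PeakSet, b: PeakSet) -> PeakCategories:
    """Split two peak sets into common pairs and condition-specific peaks.

    Overlap is >=1 bp in half-open coordinates (the bedtools default); no
    reciprocal-fraction requirement.
    """
    pairs: list[tuple[Peak, Peak]] = []
    a_common: set[str] = set()
    b_common: set[str] = set()
    b_by_chrom = b.by_chrom()
    for chrom, a_peaks in a.by_chrom().items():
        b_peaks = b_by_chrom.get(chrom, [])
        j0 = 0
        for pa in a_peaks:
            # advance past B peaks entirely left of pa
            while j0 < len(b_peaks) and b_peaks[j0].end <= pa.start:
                j0 += 1
            j = j0
            while j < len(b_peaks) and b_peaks[j].start < pa.end:
                pb = b_peaks[j]
                if pb.end > pa.start:
                    pairs.append((pa, pb))
                    a_common.add(pa.name)
                    b_common.add(pb.name)
                j += 1
    a_specific = PeakSet([p for p in a if p.name not in a_common], label=a.label)
    b_specific = PeakSet([p for p in b if p.name not in b_common], label=b.label)
    return PeakCategories(pairs, a_specific, b_specific)


def _peak_profile(
    peak: Peak, track: SignalTrack, window: int, nbins: int
) -> np.ndarray:
    center = peak.interval.center
    edges = center - window + (2.0 * window / nbins) * np.arange(nbins + 1)
    out = np.empty(nbins)
    for i in range(nbins):
        lo, hi = edges[i], edges[i + 1]
        # fractional bp at the bin edges are integrated exactly against the
        # piecewise-constant track
        out[i] = _mean_real(track, peak.chrom, lo, hi)
    return out


def _mean_real(track: SignalTrack, chrom: str, lo: float, hi: float) -> float:
    """Length-weighted mean over a real-valued window of a step function."""
    if hi <= lo:
        return 0.0
    ilo, ihi = int(np.floor(lo)), int(np.ceil(hi))
    if ihi <= 0:
        return 0.0
    total = track.integral(chrom, max(ilo, 0), ihi)
    # trim the partial first/last base
    if lo > ilo and lo >= 0:
        total -= (lo - ilo) * track.value_at(chrom, ilo)
    if hi < ihi:
        total -= (ihi - hi) * track.value_at(chrom, ihi - 1)
    return total / (hi - lo)


def profile_heatmap_matrix(
    peaks: PeakSet,
    track: SignalTrack,
    window: int = 2000,
    nbins: int = 100,
    sort_rows: bool = False,
) -> np.ndarray:
    """Per-peak signal profiles as a (n_peaks, nbins) matrix.

    Row i is the binned mean signal around the center of peak i; column
    means reproduce :func:`composite_profile`. With ``sort_rows`` rows are
    ordered by decreasing total signal, the usual heatmap presentation.
    """
    if len(peaks) == 0:
        raise ValueError("cannot profile an empty PeakSet")
    if nbins < 1 or window <= 0:
        raise ValueError("need nbins >= 1 and window > 0")
    mat = np.vstack([_peak_profile(p, track, window, nbins) for p in peaks])
    if sort_rows:
        mat = mat[np.argsort(-mat.sum(axis=1), kind="stable")]
    return mat


def composite_profile(
    peaks: PeakSet, track: SignalTrack, window: int = 2000, nbins: int = 100
) -> CompositeProfile:
    """Mean signal profile over all peaks: the composite-plot curve.

    For each peak the window [center - window, center + window) is split
    into ``nbins`` equal bins; each bin holds the length-weighted mean track
    signal, and the composite is the unweighted mean over peaks.
    """
    mat = profile_heatmap_matrix(peaks, track, window=window, nbins=nbins)
    return CompositeProfile(window=window, nbins=nbins, values=mat.mean(axis=0))
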