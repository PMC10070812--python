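"""ROSE-style super-enhancer calling.

Enhancer peaks closer than a gap threshold (12.5 kb by default) are
stitched into candidate regions; regions are ranked by total H3K27ac
signal; the ranked curve is split at its tangent (inflection) point and
regions above the cutoff are super-enhancers (SEs), the rest lone
enhancers (LEs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genomic_io import GenomicInterval, Peak, PeakSet, SignalTrack

DEFAULT_STITCH_GAP = 12_500


@dataclass
class StitchedRegion:
    """A maximal chain of peaks pairwise within the stitching gap."""

    interval: GenomicInterval
    members: list[str]
    signal: float = 0.0

    @property
    def region_id(self) -> str:
        return f"{self.interval.chrom}:{self.interval.start}-{self.interval.end}"


@dataclass
class SERankTable:
    """Stitched regions ranked by signal with the SE/LE split.

    ``regions`` are sorted by signal descending; ``ranks[i]`` is the 1-based
    rank of ``regions[i]``; a region is an SE iff its signal strictly
    exceeds ``cutoff_signal``, so SEs occupy a prefix of the ranking.
    """

    regions: list[StitchedRegion]
    ranks: list[int]
    cutoff_signal: float
    is_se: list[bool]

    @property
    def ses(self) -> list[StitchedRegion]:
        return [r for r, se in zip(self.regions, self.is_se) if se]

    @property
    def les(self) -> list[StitchedRegion]:
        return [r for r, se in zip(self.regions, self.is_se) if not se]

    def rank_plot_coords(self) -> list[tuple[int, float]]:
        """(rank, signal) pairs for the hockey-stick plot, rank 1 = highest."""
        return [(rk, r.signal) for rk, r in zip(self.ranks, self.regions)]


def stitch(peaks: PeakSet, gap: int = DEFAULT_STITCH_GAP) -> list[StitchedRegion]:
    """Merge peaks whose end-to-start distance is <= gap, per chromosome.

    A single left-to-right pass: a peak joins the open region iff
    peak.start - region.end <= gap. Adjacent half-open intervals have gap 0
    and merge at any gap >= 0; regions never span chromosomes.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    regions: list[StitchedRegion] = []
    for chrom, chrom_peaks in peaks.by_chrom().items():
        cur_start = cur_end = None
        cur_members: list[str] = []
        for p in chrom_peaks:
            if cur_end is not None and p.start - cur_end <= gap:
                cur_end = max(cur_end, p.end)
                cur_members.append(p.name)
            else:
                if cur_members:
                    regions.append(
                        StitchedRegion(
                            GenomicInterval(chrom, cur_start, cur_end), cur_members
                        )
                    )
                cur_start, cur_end = p.start, p.end
                cur_members = [p.name]
        if cur_members:
            regions.append(
                StitchedRegion(GenomicInterval(chrom, cur_start, cur_end), cur_members)
            )
    return regions


def region_signal(
    region: StitchedRegion, track: SignalTrack, peaks: PeakSet
) -> float:
    """Total signal of a stitched region: sum over members of density x length.

    Gaps between member peaks contribute nothing, so a sparse stitched
    region is not rewarded for its span.
    """
    by_name = {p.name: p for p in peaks}
    total = 0.0
    for name in region.members:
        p = by_name[name]
        total += track.integral(p.chrom, p.start, p.end)
    return total


def se_cutoff(signals: np.ndarray | list[float]) -> tuple[float, int]:
    """Tangent cutoff on the ascending rank-signal curve.

    With signals sorted ascending as y_1..y_n and s = (max - min)/n, slide
    a line of slope s through each point (i, y_i) and count the points on
    or below it; the point minimizing that count (smallest index on ties)
    is where the line is tangent to the curve's elbow. Returns
    (cutoff_signal, cutoff_index) with the index 1-based into the ascending
    order. Signals strictly above cutoff_signal are SEs, so an all-equal
    input yields zero SEs.
    """
    y = np.sort(np.asarray(signals, dtype=float))
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 regions to place a cutoff")
    if np.any(y < 0):
        raise ValueError("signals must be >= 0")
    s = (y[-1] - y[0]) / n
    if s == 0.0:
        return float(y[0]), 1
    idx = np.arange(1, n + 1)
    # counts[i] = #{j : y_j <= s*j + (y_i - s*i)}, written as
    # y_j - y_i <= s*(j - i) so the diagonal j = i is exactly 0 <= 0
    counts = np.sum(
        y[None, :] - y[:, None] <= s * (idx[None, :] - idx[:, None]), axis=1
    )
    best = int(np.argmin(counts))  # argmin takes the first (smallest) index on ties
    return float(y[best]), best + 1


def call_ses(
    regions: list[StitchedRegion], track: SignalTrack, peaks: PeakSet
) -> SERankTable:
    """Rank stitched regions by signal and split SEs from LEs at the tangent cutoff."""
    scored = [
        StitchedRegion(r.interval, list(r.members), region_signal(r, track, peaks))
        for r in regions
    ]
    cutoff, _ = se_cutoff([r.signal for r in scored])
    # sort by signal descending; region_id tie-break keeps the order deterministic
    scored.sort(key=lambda r: (-r.signal, r.region_id))
    ranks = list(range(1, len(scored) + 1))
    is_se = [r.signal > cutoff for r in scored]
    return SERankTable(scored, ranks, cutoff, is_se)


def classify_se_categories(
    se_a: SERankTable, se_b: SERankTable
) -> dict[str, list[StitchedRegion]]:
    """Split the SE regions of two conditions into common / A-specific / B-specific.

    An SE of one condition overlapping (>=1 bp) any SE of the other is
    common; the common list holds regions from both conditions.
    """

    def _overlaps_any(region: StitchedRegion, others: list[StitchedRegion]) -> bool:
        return any(region.interval.overlaps(o.interval) for o in others)

    ses_a, ses_b = se_a.ses, se_b.ses
    common = [r for r in ses_a if _overlaps_any(r, ses_b)]
    common += [r for r in ses_b if _overlaps_any(r, ses_a)]
    return {
        "common": common,
        "a_specific": [r for r in ses_a if not _overlaps_any(r, ses_b)],
        "b_specific": [r for r in ses_b if not _overlaps_any(r, ses_a)],
    }


def write_se_table(table: SERankTable, path: str) -> None:
    """BED6+ of stitched regions: chrom, start, end, id, signal, rank, is_se."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tregion_id\tsignal\trank\tis_se\n")
        for rank, region, se in zip(table.ranks, table.regions, table.is_se):
            iv = region.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{region.region_id}\t"
                f"{region.signal:.6g}\t{rank}\t{int(se)}\n"
            )
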