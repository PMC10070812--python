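"""Nearest-TSS assignment of enhancers and SEs to genes.

Each region is assigned to the gene whose transcription start site is
nearest (0 if the TSS falls inside the region, otherwise the gap to the
closest region edge, bedtools-closest semantics). Assignments beyond a
distance cap are dropped; the cap defaults to 500 kb and is a prominent
parameter because published enhancer-gene maps rarely state theirs.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Iterable, Sequence

from .genomic_io import GenomicInterval, TSSAnnotation

DEFAULT_MAX_DISTANCE = 500_000
#: distance-bin edges in bp for assignment summaries: 0, (0,5k], (5k,50k], beyond
DEFAULT_BIN_EDGES = (0, 5_000, 50_000)


@dataclass(frozen=True)
class GeneAssignment:
    """One region's nearest-gene call; gene_id is None beyond the cap."""

    region_id: str
    gene_id: str | None
    distance: int
    n_candidates: int = 0


def _distance_to(region: GenomicInterval, tss: int) -> int:
    """Gap from a TSS to the nearest region edge; 0 if inside (half-open)."""
    if region.start <= tss < region.end:
        return 0
    if tss < region.start:
        return region.start - tss
    return tss - region.end


def nearest_tss(
    region: GenomicInterval,
    region_id: str,
    tss: TSSAnnotation,
    max_distance: int = DEFAULT_MAX_DISTANCE,
) -> GeneAssignment:
    """Assign one region to the gene with the nearest TSS within max_distance.

    Ties on distance go to the lexicographically smallest gene_id. A
    chromosome absent from the annotation yields an unassigned record, not
    an error. ``n_candidates`` counts all genes within the cap.
    """
    index = tss.chrom_index(region.chrom)
    if index is None:
        return GeneAssignment(region_id, None, 0, 0)
    positions, gene_ids = index
    lo = bisect.bisect_left(positions, region.start - max_distance)
    hi = bisect.bisect_right(positions, region.end + max_distance)
    best: tuple[int, str] | None = None
    n_cand = 0
    for i in range(lo, hi):
        d = _distance_to(region, positions[i])
        if d > max_distance:
            continue
        n_cand += 1
        key = (d, gene_ids[i])
        if best is None or key < best:
            best = key
    if best is None:
        return GeneAssignment(region_id, None, 0, 0)
    return GeneAssignment(region_id, best[1], best[0], n_cand)


def assign_regions(
    regions: Iterable[tuple[str, GenomicInterval]],
    tss: TSSAnnotation,
    max_distance: int = DEFAULT_MAX_DISTANCE,
) -> list[GeneAssignment]:
    return [nearest_tss(iv, rid, tss, max_distance) for rid, iv in regions]


@dataclass
class AssignmentSummary:
    """Counts of regions by candidate-gene multiplicity and distance bin."""

    n_zero: int
    n_one: int
    n_multi: int
    bin_fractions: dict[str, float]

    @property
    def n_assigned(self) -> int:
        return self.n_one + self.n_multi


def assignment_summary(
    assignments: Sequence[GeneAssignment],
    max_distance: int = DEFAULT_MAX_DISTANCE,
    bin_edges: tuple[int, ...] = DEFAULT_BIN_EDGES,
) -> AssignmentSummary:
    """Summarize how many regions found 0 / 1 / >=2 genes, and at what distance.

    Distance bins are [0], (0, 5 kb], (5 kb, 50 kb], (50 kb, cap] by
    default; fractions are over assigned regions and sum to 1 (all zero
    when nothing is assigned).
    """
    n_zero = sum(1 for a in assignments if a.gene_id is None)
    n_one = sum(1 for a in assignments if a.n_candidates == 1)
    n_multi = sum(1 for a in assignments if a.n_candidates >= 2)
    edges = list(bin_edges) + [max_distance]
    labels = ["0"] + [
        f"({edges[i]}, {edges[i + 1]}]" for i in range(len(edges) - 1)
    ]
    counts = dict.fromkeys(labels, 0)
    assigned = [a for a in assignments if a.gene_id is not None]
    for a in assigned:
        if a.distance == 0:
            counts["0"] += 1
            continue
        for i in range(len(edges) - 1):
            if edges[i] < a.distance <= edges[i + 1]:
                counts[labels[i + 1]] += 1
                break
    total = len(assigned)
    fractions = {k: (v / total if total else 0.0) for k, v in counts.items()}
    return AssignmentSummary(n_zero, n_one, n_multi, fractions)


def write_assignments(assignments: Sequence[GeneAssignment], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("region_id\tgene_id\tdistance\tn_candidates\n")
        for a in assignments:
            gid = a.gene_id if a.gene_id is not None else "."
            fh.write(f"{a.region_id}\t{gid}\t{a.distance}\t{a.n_candidates}\n")
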