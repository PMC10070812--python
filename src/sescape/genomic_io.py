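"""Readers, writers and validated containers for the genomic formats the pipeline consumes.

All coordinates are 0-based half-open (BED convention). Formats with other
conventions are converted at the boundary. Chromosome names are compared by
exact string match — no ``chr`` aliasing — so that input mismatches surface
as empty overlaps rather than silent misjoins.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval on a chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start, got [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share at least 1 bp."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class Peak:
    """A called enrichment peak with a non-negative signal summary."""

    interval: GenomicInterval
    name: str
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError(f"peak score must be >= 0, got {self.score}")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


class PeakSet:
    """An ordered, uniquely named collection of peaks for one condition.

    Peaks are stored sorted by (chrom, start, end); duplicate names are
    rejected at construction so every downstream join on peak name is
    unambiguous.
    """

    def __init__(self, peaks: Iterable[Peak], label: str = "") -> None:
        self.label = label
        self.peaks: list[Peak] = sorted(
            peaks, key=lambda p: (p.chrom, p.start, p.end)
        )
        names = [p.name for p in self.peaks]
        if len(set(names)) != len(names):
            seen: set[str] = set()
            dup = next(n for n in names if n in seen or seen.add(n))  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate peak name {dup!r} in PeakSet {label!r}")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def __getitem__(self, i: int) -> Peak:
        return self.peaks[i]

    def by_chrom(self) -> dict[str, list[Peak]]:
        out: dict[str, list[Peak]] = {}
        for p in self.peaks:
            out.setdefault(p.chrom, []).append(p)
        return out


class SignalTrack:
    """Piecewise-constant signal: sorted non-overlapping intervals per chromosome.

    Positions outside the listed intervals have value 0. Supports
    length-weighted mean queries over arbitrary half-open windows, the
    primitive behind read densities and composite profiles.
    """

    def __init__(self, records: Iterable[tuple[str, int, int, float]]) -> None:
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in records:
            if end <= start:
                raise FormatError(f"empty interval {chrom}:{start}-{end}")
            if value < 0:
                raise FormatError(f"negative signal {value} at {chrom}:{start}-{end}")
            per_chrom.setdefault(chrom, []).append((start, end, value))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._values: dict[str, np.ndarray] = {}
        for chrom, recs in per_chrom.items():
            recs.sort()
            starts = np.array([r[0] for r in recs], dtype=np.int64)
            ends = np.array([r[1] for r in recs], dtype=np.int64)
            if np.any(starts[1:] < ends[:-1]):
                i = int(np.argmax(starts[1:] < ends[:-1]))
                raise FormatError(
                    f"overlapping records on {chrom}: "
                    f"[{starts[i]},{ends[i]}) and [{starts[i + 1]},{ends[i + 1]})"
                )
            self._starts[chrom] = starts
            self._ends[chrom] = ends
            self._values[chrom] = np.array([r[2] for r in recs], dtype=float)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._starts)

    def value_at(self, chrom: str, pos: int) -> float:
        """Signal at a single base (0 outside any record)."""
        starts = self._starts.get(chrom)
        if starts is None:
            return 0.0
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < self._ends[chrom][i]:
            return float(self._values[chrom][i])
        return 0.0

    def integral(self, chrom: str, start: int, end: int) -> float:
        """Integral of the signal over [start, end) in signal x bp units."""
        if end <= start:
            return 0.0
        starts = self._starts.get(chrom)
        if starts is None or len(starts) == 0:
            return 0.0
        ends = self._ends[chrom]
        values = self._values[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if hi <= lo:
            return 0.0
        ov = np.minimum(ends[lo:hi], end) - np.maximum(starts[lo:hi], start)
        return float(np.sum(ov * values[lo:hi]))

    def mean(self, chrom: str, start: int, end: int) -> float:
        """Length-weighted mean signal over [start, end), zero-filled."""
        if end <= start:
            return 0.0
        return self.integral(chrom, start, end) / (end - start)


@dataclass(frozen=True)
class TSSRecord:
    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"tss must be >= 0, got {self.tss}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


class TSSAnnotation:
    """Gene transcription start sites, indexed per chromosome for nearest queries."""

    def __init__(self, records: Iterable[TSSRecord]) -> None:
        self.records = list(records)
        ids = [r.gene_id for r in self.records]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dup = next(g for g in ids if g in seen or seen.add(g))  # type: ignore[func-returns-value]
            raise FormatError(f"duplicate gene_id {dup!r} in TSS annotation")
        self._by_chrom: dict[str, tuple[list[int], list[str]]] = {}
        per: dict[str, list[tuple[int, str]]] = {}
        for r in self.records:
            per.setdefault(r.chrom, []).append((r.tss, r.gene_id))
        for chrom, items in per.items():
            items.sort()
            self._by_chrom[chrom] = ([t for t, _ in items], [g for _, g in items])

    def __len__(self) -> int:
        return len(self.records)

    def chrom_index(self, chrom: str) -> tuple[list[int], list[str]] | None:
        """(sorted tss positions, gene ids) for a chromosome, or None."""
        return self._by_chrom.get(chrom)


# ---------------------------------------------------------------------------
# readers


def _parse_int(tok: str, path: str, lineno: int, what: str) -> int:
    try:
        return int(tok)
    except ValueError:
        raise FormatError(f"{path}:{lineno}: non-integer {what} {tok!r}") from None


def read_bed(path: str, label: str = "") -> PeakSet:
    """Read BED3/BED5/narrowPeak into a sorted PeakSet.

    Missing names become ``peak_<i>``; missing scores become 0. For
    narrowPeak (10 columns) the signalValue column is used as the score;
    the summit column is ignored.
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 columns")
            chrom = cols[0]
            start = _parse_int(cols[1], path, lineno, "start")
            end = _parse_int(cols[2], path, lineno, "end")
            if end <= start:
                raise FormatError(
                    f"{path}:{lineno}: end ({end}) must exceed start ({start})"
                )
            name = cols[3] if len(cols) > 3 and cols[3] not in ("", ".") else f"peak_{lineno}"
            if len(cols) >= 10:  # narrowPeak: col 7 is signalValue
                score = float(cols[6])
            elif len(cols) >= 5 and cols[4] not in ("", "."):
                score = float(cols[4])
            else:
                score = 0.0
            try:
                peaks.append(Peak(GenomicInterval(chrom, start, end), name, score))
            except ValueError as e:
                raise FormatError(f"{path}:{lineno}: {e}") from None
    return PeakSet(peaks, label=label or path)


def write_bed(peaks: PeakSet, path: str) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{p.score:g}\n")


def read_intervals(path: str) -> list[GenomicInterval]:
    """Read a plain BED3+ file (e.g. a blacklist) as bare intervals."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 columns")
            start = _parse_int(cols[1], path, lineno, "start")
            end = _parse_int(cols[2], path, lineno, "end")
            try:
                out.append(GenomicInterval(cols[0], start, end))
            except ValueError as e:
                raise FormatError(f"{path}:{lineno}: {e}") from None
    return sorted(out)


def read_bedgraph(path: str) -> SignalTrack:
    """Read a 4-column bedGraph; overlapping records or negative values are errors."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            start = _parse_int(cols[1], path, lineno, "start")
            end = _parse_int(cols[2], path, lineno, "end")
            try:
                value = float(cols[3])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric value {cols[3]!r}") from None
            if end <= start:
                raise FormatError(f"{path}:{lineno}: end must exceed start")
            if value < 0:
                raise FormatError(f"{path}:{lineno}: negative value {value}")
            records.append((cols[0], start, end, value))
    try:
        return SignalTrack(records)
    except FormatError as e:
        raise FormatError(f"{path}: {e}") from None


def write_bedgraph(track: SignalTrack, path: str) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms:
            starts = track._starts[chrom]
            ends = track._ends[chrom]
            values = track._values[chrom]
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def filter_blacklist(
    peaks: PeakSet, blacklist: Sequence[GenomicInterval]
) -> PeakSet:
    """Remove every peak overlapping (>=1 bp) any blacklist interval.

    Half-open adjacency does not count as overlap; an empty blacklist is
    the identity.
    """
    if not blacklist:
        return PeakSet(list(peaks), label=peaks.label)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in sorted(blacklist):
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    kept = []
    for p in peaks:
        ivs = by_chrom.get(p.chrom)
        if ivs is None:
            kept.append(p)
            continue
        starts = [s for s, _ in ivs]
        i = bisect.bisect_right(starts, p.end - 1)  # candidates starting before p.end
        hit = any(e > p.start for s, e in ivs[:i] if s < p.end)
        if not hit:
            kept.append(p)
    return PeakSet(kept, label=peaks.label)


def read_tss_table(path: str) -> TSSAnnotation:
    """Read a tab-separated TSS table: gene_id, chrom, tss, strand."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            tss = _parse_int(cols[2], path, lineno, "tss")
            try:
                records.append(TSSRecord(cols[0], cols[1], tss, cols[3]))
            except ValueError as e:
                raise FormatError(f"{path}:{lineno}: {e}") from None
    return TSSAnnotation(records)


def write_tss_table(ann: TSSAnnotation, path: str) -> None:
    with open(path, "w") as fh:
        for r in ann.records:
            fh.write(f"{r.gene_id}\t{r.chrom}\t{r.tss}\t{r.strand}\n")


def read_gmt(path: str) -> dict[str, set[str]]:
    """Read GMT gene sets: name, description, then member genes."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"{path}:{lineno}: expected name, description, >=1 gene")
            name = cols[0]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene set {name!r}")
            sets[name] = {g for g in cols[2:] if g}
    return sets


def write_gmt(sets: dict[str, Iterable[str]], path: str) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            members = "\t".join(sorted(genes))
            fh.write(f"{name}\tna\t{members}\n")


def read_jaspar_pwm(path: str):
    """Read a JASPAR PFM library; see :mod:`sescape.motif_enrichment`."""
    from .motif_enrichment import read_jaspar_pwms

    return read_jaspar_pwms(path)
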