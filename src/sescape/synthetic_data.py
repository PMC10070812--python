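"""Seeded generator of a complete toy study with planted ground truth.

Emulates a two-condition (normal vs degenerated) H3K27ac landscape plus a
third, treated condition in the expression data: common and
condition-specific peaks, a global between-condition scaling bias,
clustered high-signal peaks forming super-enhancers in the degenerated
condition, count matrices in which SE-linked genes carry planted
up-regulation that treatment reverses, and sequences with planted motif
occurrences. Every emitted record traces to a truth record, and all
outputs are pure functions of (config, seed): each output stream draws
from its own child generator spawned from the master seed, so
regenerating one file never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomic_io import (
    GenomicInterval,
    Peak,
    PeakSet,
    SignalTrack,
    TSSAnnotation,
    TSSRecord,
)

CONDITION_NORMAL = "N"
CONDITION_DISEASE = "D"
CONDITION_TREATED = "T"


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class LandscapeConfig:
    """Geometry and signal model of the two-condition peak landscape."""

    chrom_sizes: tuple[tuple[str, int], ...] = (
        ("chr1", 5_000_000),
        ("chr2", 5_000_000),
        ("chr3", 5_000_000),
    )
    n_common: int = 500
    n_a_specific: int = 150
    n_b_specific: int = 150
    n_se_b: int = 20  # planted B-specific SE clusters
    se_peaks_min: int = 5
    se_peaks_max: int = 15
    peak_width_min: int = 400
    peak_width_max: int = 800
    # spacing between placed elements; > stitch gap so lone peaks stay lone
    spacing_min: int = 12_600
    spacing_max: int = 14_500
    se_gap_min: int = 500
    se_gap_max: int = 3_000
    scaling_exponent: float = 1.0  # condition-B signal bias, 2**d
    density_log_mean: float = float(np.log(3.0))
    density_log_sd: float = 0.5
    se_density_mult: float = 10.0  # per-peak SE density vs median LE density
    cross_background: float = 0.05  # off-condition signal of specific peaks
    edge_jitter: int = 50


@dataclass(frozen=True)
class CountsConfig:
    """Expression model for the normal / disease / treated count matrices."""

    n_genes: int = 2000
    n_reps: int = 3
    dispersion: float = 0.02
    base_mean_log_mean: float = float(np.log(100.0))
    base_mean_log_sd: float = 0.8
    se_gene_lfc: float = 1.5  # planted up-regulation of SE-linked genes in D
    rescued_fraction: float = 0.8  # fraction of SE genes reversed in T
    n_extra_up: int = 50  # non-SE up-regulated genes in D vs N
    n_extra_down: int = 50
    extra_lfc: float = 1.5
    depth_log_sd: float = 0.1  # per-sample library-depth wobble


@dataclass(frozen=True)
class SequenceConfig:
    """Motif-planting model for target enhancer sequences."""

    n_targets: int = 100
    seq_length: int = 500
    gc: float = 0.4
    planted_consensus: str = "TGACTCAG"
    plant_fraction: float = 0.8
    mutation_rate: float = 0.05
    n_decoy_motifs: int = 7
    decoy_length: int = 8


@dataclass(frozen=True)
class StudyConfig:
    landscape: LandscapeConfig = LandscapeConfig()
    counts: CountsConfig = CountsConfig()
    sequences: SequenceConfig = SequenceConfig()
    name: str = "moderate"


def study_config(name: str = "moderate") -> StudyConfig:
    """Named study presets.

    ``moderate``: planted SE-gene log2FC 1.5 — recovery is expected but not
    guaranteed gene-by-gene. ``strong``: log2FC 3 — the rescued set should
    be recovered exactly. ``big-landscape``: a wider genome carrying ~1000
    lone-enhancer regions around the 20 planted SEs, for cutoff stress
    tests.
    """
    if name == "moderate":
        return StudyConfig(name=name)
    if name == "strong":
        return StudyConfig(counts=CountsConfig(se_gene_lfc=3.0), name=name)
    if name == "big-landscape":
        landscape = LandscapeConfig(
            chrom_sizes=(("chr1", 6_000_000), ("chr2", 6_000_000), ("chr3", 6_000_000)),
            n_common=700,
            n_a_specific=100,
            n_b_specific=300,
        )
        return StudyConfig(landscape=landscape, name=name)
    raise ValueError(f"unknown study config {name!r}")


# ---------------------------------------------------------------------------
# landscape


@dataclass
class LandscapeTruth:
    peak_class: dict[str, str]  # peak name -> common / a_specific / b_specific / se_b
    scaling_exponent: float
    se_regions: list[GenomicInterval]  # planted B-specific SE cluster spans
    se_gene_ids: list[str]  # gene planted inside each SE cluster, same order


@dataclass
class SyntheticLandscape:
    peaks_a: PeakSet
    peaks_b: PeakSet
    track_a: SignalTrack
    track_b: SignalTrack
    tss: TSSAnnotation
    truth: LandscapeTruth


def _labeled_rng(seed: int, stream: int) -> np.random.Generator:
    """One independent substream per output, so streams never interleave."""
    return np.random.default_rng(np.random.SeedSequence([seed, stream]))


def generate_landscape(
    config: LandscapeConfig, seed: int
) -> SyntheticLandscape:
    """Generate peaks, tracks, TSS table and truth for the two conditions.

    Elements (lone-peak slots and SE clusters) are placed left to right
    with inter-element spacing above the stitch gap, in a seeded shuffled
    order, so lone peaks never stitch into each other and each planted SE
    cluster stitches into exactly one region.
    """
    rng_place = _labeled_rng(seed, 1)
    rng_signal = _labeled_rng(seed, 2)
    rng_genes = _labeled_rng(seed, 3)

    elements: list[str] = (
        ["common"] * config.n_common
        + ["a_specific"] * config.n_a_specific
        + ["b_specific"] * config.n_b_specific
        + ["se_b"] * config.n_se_b
    )
    rng_place.shuffle(elements)

    scale_b = 2.0**config.scaling_exponent
    median_density = float(np.exp(config.density_log_mean))

    peaks_a: list[Peak] = []
    peaks_b: list[Peak] = []
    rec_a: list[tuple[str, int, int, float]] = []
    rec_b: list[tuple[str, int, int, float]] = []
    peak_class: dict[str, str] = {}
    se_regions: list[GenomicInterval] = []

    def draw_density() -> float:
        return float(
            rng_signal.lognormal(config.density_log_mean, config.density_log_sd)
        )

    def poisson_density(lam_density: float, width: int) -> float:
        return float(rng_signal.poisson(lam_density * width)) / width

    def jittered(start: int, end: int, limit: int) -> tuple[int, int]:
        j1 = int(rng_signal.integers(-config.edge_jitter, config.edge_jitter + 1))
        j2 = int(rng_signal.integers(-config.edge_jitter, config.edge_jitter + 1))
        s = max(0, start + j1)
        e = min(limit, end + j2)
        if e - s < 50:  # degenerate jitter; keep original
            return start, end
        return s, e

    chrom_iter = iter(config.chrom_sizes)
    chrom, chrom_size = next(chrom_iter)
    cursor = int(rng_place.integers(1000, 5000))
    counter = 0

    def advance(needed: int) -> None:
        nonlocal chrom, chrom_size, cursor
        while cursor + needed > chrom_size:
            try:
                chrom, chrom_size = next(chrom_iter)
            except StopIteration:
                raise ValueError(
                    "landscape does not fit the configured chromosomes; "
                    "enlarge chrom_sizes or reduce peak counts"
                ) from None
            cursor = int(rng_place.integers(1000, 5000))

    for kind in elements:
        counter += 1
        if kind == "se_b":
            n_peaks = int(
                rng_place.integers(config.se_peaks_min, config.se_peaks_max + 1)
            )
            widths = rng_place.integers(
                config.peak_width_min, config.peak_width_max + 1, size=n_peaks
            )
            gaps = rng_place.integers(
                config.se_gap_min, config.se_gap_max + 1, size=n_peaks - 1
            )
            span = int(np.sum(widths) + np.sum(gaps))
            advance(span)
            start = cursor
            pos = start
            for i, w in enumerate(widths):
                name = f"seB_{counter}_{i}"
                dens = config.se_density_mult * median_density * float(
                    rng_signal.lognormal(0.0, 0.25)
                )
                dens_b = poisson_density(dens * scale_b, int(w))
                dens_a = poisson_density(
                    dens * config.cross_background, int(w)
                )
                peaks_b.append(
                    Peak(GenomicInterval(chrom, pos, pos + int(w)), name, dens_b)
                )
                rec_b.append((chrom, pos, pos + int(w), dens_b))
                if dens_a > 0:
                    rec_a.append((chrom, pos, pos + int(w), dens_a))
                peak_class[name] = "se_b"
                pos += int(w)
                if i < n_peaks - 1:
                    pos += int(gaps[i])
            se_regions.append(GenomicInterval(chrom, start, pos))
            cursor = pos + int(
                rng_place.integers(config.spacing_min, config.spacing_max + 1)
            )
            continue

        width = int(
            rng_place.integers(config.peak_width_min, config.peak_width_max + 1)
        )
        advance(width)
        start, end = cursor, cursor + width
        base = draw_density()
        name = f"{kind}_{counter}"
        peak_class[name] = kind
        if kind == "common":
            dens_a = poisson_density(base, width)
            dens_b = poisson_density(base * scale_b, width)
            sa, ea = jittered(start, end, chrom_size)
            sb, eb = jittered(start, end, chrom_size)
            peaks_a.append(Peak(GenomicInterval(chrom, sa, ea), name + "_A", dens_a))
            peaks_b.append(Peak(GenomicInterval(chrom, sb, eb), name + "_B", dens_b))
            peak_class[name + "_A"] = "common"
            peak_class[name + "_B"] = "common"
            del peak_class[name]
            if dens_a > 0:
                rec_a.append((chrom, sa, ea, dens_a))
            if dens_b > 0:
                rec_b.append((chrom, sb, eb, dens_b))
        elif kind == "a_specific":
            dens_a = poisson_density(base, width)
            dens_b = poisson_density(base * config.cross_background * scale_b, width)
            peaks_a.append(Peak(GenomicInterval(chrom, start, end), name, dens_a))
            if dens_a > 0:
                rec_a.append((chrom, start, end, dens_a))
            if dens_b > 0:
                rec_b.append((chrom, start, end, dens_b))
        else:  # b_specific
            dens_b = poisson_density(base * scale_b, width)
            dens_a = poisson_density(base * config.cross_background, width)
            peaks_b.append(Peak(GenomicInterval(chrom, start, end), name, dens_b))
            if dens_b > 0:
                rec_b.append((chrom, start, end, dens_b))
            if dens_a > 0:
                rec_a.append((chrom, start, end, dens_a))
        cursor = end + int(
            rng_place.integers(config.spacing_min, config.spacing_max + 1)
        )

    # genes: one planted inside each SE cluster, decoys well away from them
    se_gene_ids = [f"SEG{i + 1:03d}" for i in range(len(se_regions))]
    tss_records = []
    for gid, region in zip(se_gene_ids, se_regions):
        pos = int(rng_genes.integers(region.start, region.end))
        strand = "+" if rng_genes.random() < 0.5 else "-"
        tss_records.append(TSSRecord(gid, region.chrom, pos, strand))

    forbidden: dict[str, list[tuple[int, int]]] = {}
    margin = 5000
    for region in se_regions:
        forbidden.setdefault(region.chrom, []).append(
            (region.start - margin, region.end + margin)
        )
    chrom_names = [c for c, _ in config.chrom_sizes]
    sizes = dict(config.chrom_sizes)
    n_decoys = 0
    i_decoy = 0
    while i_decoy < 10**7 and n_decoys < _n_decoy_genes(config):
        i_decoy += 1
        chrom_g = chrom_names[int(rng_genes.integers(len(chrom_names)))]
        pos = int(rng_genes.integers(0, sizes[chrom_g]))
        if any(s <= pos < e for s, e in forbidden.get(chrom_g, [])):
            continue
        n_decoys += 1
        strand = "+" if rng_genes.random() < 0.5 else "-"
        tss_records.append(TSSRecord(f"G{n_decoys:04d}", chrom_g, pos, strand))

    truth = LandscapeTruth(
        peak_class=peak_class,
        scaling_exponent=config.scaling_exponent,
        se_regions=se_regions,
        se_gene_ids=se_gene_ids,
    )
    return SyntheticLandscape(
        peaks_a=PeakSet(peaks_a, label="A"),
        peaks_b=PeakSet(peaks_b, label="B"),
        track_a=SignalTrack(rec_a),
        track_b=SignalTrack(rec_b),
        tss=TSSAnnotation(tss_records),
        truth=truth,
    )


def _n_decoy_genes(config: LandscapeConfig) -> int:
    # decoy genes fill the gene universe around the planted SE genes
    return 980


# ---------------------------------------------------------------------------
# counts


@dataclass
class CountsTruth:
    lfc_disease: dict[str, float]  # planted log2FC in D vs N (0 if null)
    reversed_in_treated: set[str]  # genes returning to baseline in T
    rescued: set[str]  # SE-linked, up in D, reversed in T
    se_genes: set[str]


@dataclass
class SyntheticCounts:
    counts: pd.DataFrame
    conditions: dict[str, str]
    truth: CountsTruth


def generate_counts(
    config: CountsConfig,
    se_gene_ids: list[str],
    seed: int,
    extra_gene_ids: list[str] | None = None,
) -> SyntheticCounts:
    """NB count matrices for conditions N, D, T with planted effects.

    SE-linked genes are up-regulated in D versus N by ``se_gene_lfc``; a
    ``rescued_fraction`` of them returns to baseline in T (the planted
    rescued set). Extra non-SE genes carry up/down effects in D, half of
    the ups also reversed in T, so the treated contrast is not trivially
    equal to the SE truth.
    """
    rng = _labeled_rng(seed, 10)
    gene_ids = list(se_gene_ids)
    if extra_gene_ids:
        gene_ids += [g for g in extra_gene_ids if g not in set(se_gene_ids)]
    n_fill = config.n_genes - len(gene_ids)
    gene_ids += [f"NULL{i + 1:04d}" for i in range(max(0, n_fill))]
    n_genes = len(gene_ids)

    base_mean = rng.lognormal(
        config.base_mean_log_mean, config.base_mean_log_sd, size=n_genes
    )
    lfc_d = np.zeros(n_genes)
    reversed_flags = np.zeros(n_genes, dtype=bool)

    se_set = set(se_gene_ids)
    idx_by_gene = {g: i for i, g in enumerate(gene_ids)}
    for g in se_gene_ids:
        lfc_d[idx_by_gene[g]] = config.se_gene_lfc
    n_rescued = int(round(config.rescued_fraction * len(se_gene_ids)))
    rescued_ids = list(
        rng.choice(np.array(se_gene_ids), size=n_rescued, replace=False)
    ) if se_gene_ids else []
    for g in rescued_ids:
        reversed_flags[idx_by_gene[g]] = True

    # extra (non-SE) differential genes among the fill genes
    fill = [g for g in gene_ids if g not in se_set and lfc_d[idx_by_gene[g]] == 0]
    n_extra = config.n_extra_up + config.n_extra_down
    extra = list(rng.choice(np.array(fill), size=min(n_extra, len(fill)), replace=False))
    for j, g in enumerate(extra):
        i = idx_by_gene[g]
        if j < config.n_extra_up:
            lfc_d[i] = config.extra_lfc
            if j % 2 == 0:  # half of the extra ups also reversed by treatment
                reversed_flags[i] = True
        else:
            lfc_d[i] = -config.extra_lfc

    mu_n = base_mean
    mu_d = base_mean * 2.0**lfc_d
    mu_t = np.where(reversed_flags, mu_n, mu_d)

    samples: dict[str, np.ndarray] = {}
    conditions: dict[str, str] = {}
    alpha = config.dispersion
    for cond, mu in (
        (CONDITION_NORMAL, mu_n),
        (CONDITION_DISEASE, mu_d),
        (CONDITION_TREATED, mu_t),
    ):
        for rep in range(1, config.n_reps + 1):
            depth = float(rng.lognormal(0.0, config.depth_log_sd))
            m = mu * depth
            r = 1.0 / alpha
            p = r / (r + m)
            name = f"{cond}_rep{rep}"
            samples[name] = rng.negative_binomial(r, p)
            conditions[name] = cond

    counts = pd.DataFrame(samples, index=gene_ids)
    rescued = {
        g
        for g in gene_ids
        if g in se_set
        and lfc_d[idx_by_gene[g]] >= 1.0
        and reversed_flags[idx_by_gene[g]]
    }
    truth = CountsTruth(
        lfc_disease={g: float(lfc_d[idx_by_gene[g]]) for g in gene_ids},
        reversed_in_treated={g for g in gene_ids if reversed_flags[idx_by_gene[g]]},
        rescued=rescued,
        se_genes=se_set,
    )
    return SyntheticCounts(counts=counts, conditions=conditions, truth=truth)


# ---------------------------------------------------------------------------
# sequences


@dataclass
class SequenceTruth:
    planted_motif_id: str
    planted_in: set[str]  # target sequence ids carrying the motif


@dataclass
class SyntheticSequences:
    targets: dict[str, str]  # id -> sequence
    pwm_counts: list[tuple[str, np.ndarray]]  # JASPAR-writable count matrices
    truth: SequenceTruth


def _consensus_counts(consensus: str, sharpness: float = 100.0) -> np.ndarray:
    from .motif_enrichment import BASES

    L = len(consensus)
    counts = np.ones((4, L))
    for j, base in enumerate(consensus):
        counts[BASES.index(base), j] = sharpness
    return counts


def generate_sequences(config: SequenceConfig, seed: int) -> SyntheticSequences:
    """Target sequences with a planted consensus plus a decoy PWM library.

    Backgrounds are i.i.d. with the configured GC; the planted consensus is
    inserted at a random position of a ``plant_fraction`` of targets with
    per-position mutations at ``mutation_rate``.
    """
    from .motif_enrichment import BASES

    rng = _labeled_rng(seed, 20)
    p_gc = config.gc / 2.0
    p_at = (1.0 - config.gc) / 2.0
    base_p = np.array([p_at, p_gc, p_gc, p_at])  # A C G T

    def random_seq(n: int) -> str:
        return "".join(
            BASES[i] for i in rng.choice(4, size=n, p=base_p)
        )

    consensus = config.planted_consensus.upper()
    L = len(consensus)
    targets: dict[str, str] = {}
    planted: set[str] = set()
    for i in range(config.n_targets):
        sid = f"target_{i + 1}"
        seq = list(random_seq(config.seq_length))
        if rng.random() < config.plant_fraction:
            pos = int(rng.integers(0, config.seq_length - L + 1))
            inserted = [
                c if rng.random() >= config.mutation_rate else BASES[int(rng.integers(4))]
                for c in consensus
            ]
            seq[pos : pos + L] = inserted
            planted.add(sid)
        targets[sid] = "".join(seq)

    pwm_counts = [("PLANTED", _consensus_counts(consensus))]
    for j in range(config.n_decoy_motifs):
        decoy = "".join(BASES[int(rng.integers(4))] for _ in range(config.decoy_length))
        pwm_counts.append((f"DECOY{j + 1}", _consensus_counts(decoy)))

    return SyntheticSequences(
        targets=targets,
        pwm_counts=pwm_counts,
        truth=SequenceTruth("PLANTED", planted),
    )


def write_fasta(sequences: dict[str, str], path: str) -> None:
    with open(path, "w") as fh:
        for sid, seq in sequences.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_fasta(path: str) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}
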