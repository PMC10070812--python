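"""Known-motif scanning and enrichment over enhancer sequences.

Each position-weight matrix is scanned over target and background
sequences as log-odds scores against the background base composition; a
sequence "has" the motif if any window on either strand reaches a fixed
fraction (default 0.8) of the maximum attainable score. Enrichment of
targets over background is a one-sided Fisher exact test on the
has/has-not contingency table, BH-corrected across motifs. Background
sequences default to per-sequence dinucleotide shuffles of the targets,
which preserve length, base and dinucleotide composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .diffexpr import bh_adjust
from .genomic_io import FormatError

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
DEFAULT_SCORE_FRACTION = 0.8
UNIFORM_BG = (0.25, 0.25, 0.25, 0.25)


@dataclass
class PWM:
    """A 4 x L base-probability matrix (rows A, C, G, T) with background."""

    motif_id: str
    probs: np.ndarray
    background: tuple[float, float, float, float] = UNIFORM_BG

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[0] != 4:
            raise ValueError("PWM needs a 4 x L matrix")
        if self.probs.shape[1] < 4:
            raise ValueError("PWM length must be >= 4")
        if not np.allclose(self.probs.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")
        if np.any(self.probs <= 0):
            raise ValueError("PWM probabilities must be > 0 (apply a pseudocount)")

    @property
    def length(self) -> int:
        return int(self.probs.shape[1])

    def log_odds(self) -> np.ndarray:
        bg = np.asarray(self.background, dtype=float)[:, None]
        return np.log2(self.probs / bg)

    def max_score(self) -> float:
        return float(self.log_odds().max(axis=0).sum())

    def reverse_complement(self) -> "PWM":
        return PWM(self.motif_id, self.probs[::-1, ::-1], self.background)

    @classmethod
    def from_counts(
        cls,
        motif_id: str,
        counts: np.ndarray,
        pseudocount: float = 0.5,
        background: tuple[float, float, float, float] = UNIFORM_BG,
    ) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        col_sums = counts.sum(axis=0)
        if np.any(col_sums <= 0):
            raise FormatError(f"motif {motif_id!r} has a zero-sum column")
        probs = (counts + pseudocount) / (col_sums + 4 * pseudocount)
        return cls(motif_id, probs, background)


def read_jaspar_pwms(path: str) -> list[PWM]:
    """Read a JASPAR-style PFM text file (>header then 4 A/C/G/T count rows)."""
    pwms: list[PWM] = []
    seen: set[str] = set()
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    i = 0
    while i < len(lines):
        header = lines[i]
        if not header.startswith(">"):
            raise FormatError(f"{path}: expected '>' header, got {header!r}")
        motif_id = header[1:].split()[0]
        if motif_id in seen:
            raise FormatError(f"{path}: duplicate motif id {motif_id!r}")
        seen.add(motif_id)
        rows = []
        for j, base in enumerate(BASES):
            tokens = lines[i + 1 + j].replace("[", " ").replace("]", " ").split()
            if tokens and tokens[0].upper() in ("A", "C", "G", "T"):
                if tokens[0].upper() != base:
                    raise FormatError(
                        f"{path}: motif {motif_id!r} row {j + 1} labelled "
                        f"{tokens[0]!r}, expected {base!r}"
                    )
                tokens = tokens[1:]
            rows.append([float(t) for t in tokens])
        counts = np.asarray(rows, dtype=float)
        if counts.ndim != 2:
            raise FormatError(f"{path}: ragged matrix for motif {motif_id!r}")
        pwms.append(PWM.from_counts(motif_id, counts))
        i += 5
    return pwms


def write_jaspar_pwms(pwms: list[tuple[str, np.ndarray]], path: str) -> None:
    """Write (motif_id, 4 x L count matrix) pairs in JASPAR PFM format."""
    with open(path, "w") as fh:
        for motif_id, counts in pwms:
            fh.write(f">{motif_id}\n")
            for base, row in zip(BASES, np.asarray(counts)):
                cells = " ".join(f"{v:g}" for v in row)
                fh.write(f"{base} [ {cells} ]\n")


def _encode(seq: str) -> np.ndarray:
    """A=0 C=1 G=2 T=3, anything else (N) = 4."""
    arr = np.full(len(seq), 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        arr[np.frombuffer(seq.upper().encode(), dtype=np.uint8) == ord(base)] = idx
    return arr


def _best_window_score(encoded: np.ndarray, lom: np.ndarray) -> float:
    """Maximum log-odds window score of one strand; N scores 0."""
    L = lom.shape[1]
    n = len(encoded) - L + 1
    if n <= 0:
        return -np.inf
    # pad the score table with a zero row for N
    table = np.vstack([lom, np.zeros((1, L))])
    idx = np.lib.stride_tricks.sliding_window_view(encoded, L)
    scores = table[idx, np.arange(L)].sum(axis=1)
    return float(scores.max())


def scan_sequence(
    seq: str, pwm: PWM, score_fraction: float = DEFAULT_SCORE_FRACTION
) -> bool:
    """True iff any window on either strand scores >= score_fraction * max score.

    Sequences shorter than the motif have no hit; N positions contribute a
    log-odds of 0 (background-neutral).
    """
    threshold = score_fraction * pwm.max_score()
    enc = _encode(seq)
    fwd = _best_window_score(enc, pwm.log_odds())
    if fwd >= threshold - 1e-12:
        return True
    rev = _best_window_score(enc, pwm.reverse_complement().log_odds())
    return rev >= threshold - 1e-12


def fisher_enrichment_p(
    k_target: int, n_target: int, k_background: int, n_background: int
) -> float:
    """One-sided Fisher exact p for target hit-rate exceeding background."""
    table = [
        [k_target, n_target - k_target],
        [k_background, n_background - k_background],
    ]
    return float(stats.fisher_exact(table, alternative="greater")[1])


@dataclass
class MotifHitSummary:
    motif_id: str
    pct_target: float
    pct_background: float
    p: float
    q: float = np.nan
    rank: int = 0


def enrich_motifs(
    targets: list[str],
    background: list[str],
    pwms: list[PWM],
    score_fraction: float = DEFAULT_SCORE_FRACTION,
    top: int | None = 10,
) -> list[MotifHitSummary]:
    """Per-motif enrichment of targets over background sequences.

    Reports the two figures a motif analysis prints: the percentage of
    sequences carrying each motif on each side, and a one-sided Fisher p
    (BH-corrected across motifs). Motifs are ranked by ascending p; when
    ``top`` is given only the first ``top`` are returned.
    """
    if not targets or not background:
        raise ValueError("need non-empty target and background sequence sets")
    if min(len(targets), len(background)) < 10:
        import warnings

        warnings.warn(
            "fewer than 10 sequences on one side; enrichment p-values will "
            "be unstable",
            stacklevel=2,
        )
    summaries = []
    for pwm in pwms:
        kt = sum(scan_sequence(s, pwm, score_fraction) for s in targets)
        kb = sum(scan_sequence(s, pwm, score_fraction) for s in background)
        p = fisher_enrichment_p(kt, len(targets), kb, len(background))
        summaries.append(
            MotifHitSummary(
                pwm.motif_id,
                100.0 * kt / len(targets),
                100.0 * kb / len(background),
                p,
            )
        )
    qs = bh_adjust([s.p for s in summaries])
    for s, q in zip(summaries, qs):
        s.q = float(q)
    summaries.sort(key=lambda s: (s.p, s.motif_id))
    for i, s in enumerate(summaries, 1):
        s.rank = i
    return summaries[:top] if top is not None else summaries


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """A random shuffle of ``seq`` preserving its exact dinucleotide counts.

    Altschul-Erickson style: view the sequence as an Eulerian walk on the
    graph whose edges are its dinucleotides, pick a random last-exit edge
    toward the terminal base for every other vertex (rejecting choices
    that strand part of the walk), shuffle the remaining edges, and walk.
    """
    if len(seq) <= 2:
        return seq
    s = seq.upper()
    edges: dict[str, list[str]] = {}
    for a, b in zip(s, s[1:]):
        edges.setdefault(a, []).append(b)
    last = s[-1]
    vertices = list(edges)

    for _ in range(1000):
        # choose a candidate last-exit edge per non-terminal vertex
        last_exit = {
            v: edges[v][rng.integers(len(edges[v]))] for v in vertices if v != last
        }
        # the last-exit edges must form a tree rooted at `last`
        ok = True
        for v in last_exit:
            seen = {v}
            cur = v
            while cur != last:
                cur = last_exit.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - would need a pathological graph
        raise RuntimeError("dinucleotide shuffle failed to find an Eulerian order")

    pools: dict[str, list[str]] = {}
    for v, targets_v in edges.items():
        rest = list(targets_v)
        if v != last:
            rest.remove(last_exit[v])
        rng.shuffle(rest)
        if v != last:
            rest.append(last_exit[v])
        pools[v] = rest

    out = [s[0]]
    cur = s[0]
    counters = {v: 0 for v in pools}
    for _ in range(len(s) - 1):
        nxt = pools[cur][counters[cur]]
        counters[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def make_background(targets: list[str], seed: int) -> list[str]:
    """Per-target dinucleotide-shuffled background, reproducible from seed."""
    rng = np.random.default_rng(seed)
    return [dinucleotide_shuffle(s, rng) for s in targets]
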