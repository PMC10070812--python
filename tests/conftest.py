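import numpy as np
import pytest

from sescape.genomic_io import GenomicInterval, Peak, PeakSet, SignalTrack


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_peakset(rng, n, label="X", chroms=("chr1", "chr2"), span=100_000):
    """Random non-degenerate peaks, possibly overlapping, unique names."""
    peaks = []
    for i in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, span))
        width = int(rng.integers(1, 500))
        peaks.append(Peak(GenomicInterval(chrom, start, start + width), f"{label}{i}"))
    return PeakSet(peaks, label=label)


def random_track(rng, chrom="chr1", n=50, span=100_000, vmax=10.0):
    """Random piecewise-constant track with gaps."""
    cuts = np.sort(rng.choice(span, size=2 * n, replace=False))
    records = []
    for i in range(0, 2 * n, 2):
        if rng.random() < 0.8:  # leave some gaps at value 0
            records.append(
                (chrom, int(cuts[i]), int(cuts[i + 1]), float(rng.uniform(0, vmax)))
            )
    return SignalTrack(records)


def track_to_array(track, chrom, length):
    """Base-resolution expansion of a track, the oracle for mean queries."""
    arr = np.zeros(length)
    for pos in range(length):
        arr[pos] = track.value_at(chrom, pos)
    return arr


@pytest.fixture(scope="session")
def strong_report():
    """One full pipeline run on the strong study, shared across tests."""
    from sescape.pipeline import PipelineConfig, run_all

    return run_all(PipelineConfig(study="strong", seed=7))
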