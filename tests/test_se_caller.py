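import numpy as np
import pytest

from sescape.genomic_io import GenomicInterval, Peak, PeakSet, SignalTrack
from sescape.se_caller import (
    call_ses,
    classify_se_categories,
    region_signal,
    se_cutoff,
    stitch,
)
from sescape.synthetic_data import generate_landscape, study_config


def oracle_stitch(peaks, gap):
    """Transitive-closure merge via an explicit O(n^2) adjacency scan."""
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    items = list(peaks)
    n = len(items)
    rows, cols = [], []
    for i in range(n):
        for j in range(n):
            pi, pj = items[i], items[j]
            if pi.chrom != pj.chrom:
                continue
            # within-gap in either direction, or overlapping
            if pi.start - pj.end <= gap and pj.start - pi.end <= gap:
                rows.append(i)
                cols.append(j)
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    ncomp, labels = connected_components(adj, directed=False)
    groups = {}
    for i, lbl in enumerate(labels):
        groups.setdefault(lbl, []).append(items[i])
    regions = set()
    for members in groups.values():
        chrom = members[0].chrom
        regions.add(
            (chrom, min(p.start for p in members), max(p.end for p in members),
             frozenset(p.name for p in members))
        )
    return regions


def oracle_cutoff(signals):
    """Evaluate the below-count at every index with explicit line values."""
    y = sorted(signals)
    n = len(y)
    s = (y[-1] - y[0]) / n
    if s == 0:
        return y[0], 1
    best_i, best_count = None, None
    for i in range(1, n + 1):
        # difference form keeps j == i exactly on the line
        count = sum(
            1 for j in range(1, n + 1) if y[j - 1] - y[i - 1] <= s * (j - i)
        )
        if best_count is None or count < best_count:
            best_i, best_count = i, count
    return y[best_i - 1], best_i


class TestStitch:
    def test_forced_toy_result(self):
        peaks = PeakSet(
            [
                Peak(GenomicInterval("chr1", 0, 100), "p0"),
                Peak(GenomicInterval("chr1", 5000, 5100), "p1"),
                Peak(GenomicInterval("chr1", 20000, 20100), "p2"),
            ]
        )
        regions = stitch(peaks, gap=12_500)
        assert len(regions) == 2
        assert (regions[0].interval.start, regions[0].interval.end) == (0, 5100)
        assert regions[0].members == ["p0", "p1"]
        assert regions[1].members == ["p2"]

    def test_zero_gap_merges_only_bookended(self):
        peaks = PeakSet(
            [
                Peak(GenomicInterval("chr1", 0, 100), "p0"),
                Peak(GenomicInterval("chr1", 100, 200), "p1"),
                Peak(GenomicInterval("chr1", 201, 300), "p2"),
            ]
        )
        regions = stitch(peaks, gap=0)
        assert [r.members for r in regions] == [["p0", "p1"], ["p2"]]

    def test_regions_never_span_chromosomes(self):
        peaks = PeakSet(
            [
                Peak(GenomicInterval("chr1", 0, 100), "p0"),
                Peak(GenomicInterval("chr2", 150, 250), "p1"),
            ]
        )
        assert len(stitch(peaks, gap=10**9)) == 2

    def test_matches_transitive_closure_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 300))
            gap = int(rng.integers(0, 3000))
            peaks = []
            for i in range(n):
                start = int(rng.integers(0, 200_000))
                peaks.append(
                    Peak(
                        GenomicInterval(
                            ["chr1", "chr2"][int(rng.integers(2))],
                            start,
                            start + int(rng.integers(1, 1500)),
                        ),
                        f"p{i}",
                    )
                )
            ps = PeakSet(peaks)
            got = {
                (r.interval.chrom, r.interval.start, r.interval.end,
                 frozenset(r.members))
                for r in stitch(ps, gap=gap)
            }
            assert got == oracle_stitch(ps, gap)

    def test_peak_conservation_and_disjoint_sorted(self, rng):
        peaks = []
        for i in range(500):
            start = int(rng.integers(0, 500_000))
            peaks.append(
                Peak(GenomicInterval("chr1", start, start + int(rng.integers(1, 800))), f"p{i}")
            )
        regions = stitch(PeakSet(peaks), gap=1000)
        assert sum(len(r.members) for r in regions) == 500
        for r1, r2 in zip(regions, regions[1:]):
            assert r1.interval.end < r2.interval.start  # disjoint with gap


class TestSeCutoff:
    def test_documented_toy_vector(self):
        cutoff, idx = se_cutoff([1, 2, 3, 4, 100])
        assert cutoff == 4.0 and idx == 4
        assert sum(v > cutoff for v in [1, 2, 3, 4, 100]) == 1

    def test_all_equal_yields_no_ses(self):
        cutoff, _ = se_cutoff([5.0] * 10)
        assert cutoff == 5.0
        assert sum(v > cutoff for v in [5.0] * 10) == 0

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 300))
            y = rng.lognormal(3, 1, n)
            got = se_cutoff(y)
            assert got == oracle_cutoff(list(y))

    def test_scale_invariance_of_labels(self, rng):
        y = rng.lognormal(3, 1, 200)
        cutoff, _ = se_cutoff(y)
        labels = y > cutoff
        for k in (0.01, 3.0, 1000.0):
            ck, _ = se_cutoff(k * y)
            np.testing.assert_array_equal(k * y > ck, labels)

    def test_extreme_outlier_always_called(self, rng):
        for n in (10, 100, 1000):
            y = np.geomspace(1, 50, n)
            y[-1] *= 100
            cutoff, _ = se_cutoff(y)
            assert y.max() > cutoff

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            se_cutoff([1.0, 2.0])


class TestCallSes:
    def _toy(self):
        peaks, records = [], []
        signals = [1, 2, 3, 4, 100]
        for i, sig in enumerate(signals):
            start = 50_000 * i
            peaks.append(Peak(GenomicInterval("chr1", start, start + 100), f"p{i}"))
            records.append(("chr1", start, start + 100, sig / 100))
        return PeakSet(peaks), SignalTrack(records)

    def test_toy_table_has_one_se(self):
        ps, track = self._toy()
        table = call_ses(stitch(ps), track, ps)
        assert len(table.ses) == 1
        assert table.ses[0].members == ["p4"]
        assert [r for r, se in zip(table.ranks, table.is_se) if se] == [1]

    def test_rank_plot_coords_descend(self):
        ps, track = self._toy()
        table = call_ses(stitch(ps), track, ps)
        coords = table.rank_plot_coords()
        assert [c[0] for c in coords] == [1, 2, 3, 4, 5]
        assert all(a[1] >= b[1] for a, b in zip(coords, coords[1:]))

    def test_input_order_invariance(self, rng):
        peaks, records = [], []
        for i in range(30):
            start = 40_000 * i
            peaks.append(Peak(GenomicInterval("chr1", start, start + 200), f"p{i}"))
            records.append(("chr1", start, start + 200, float(rng.lognormal(1, 1))))
        ps = PeakSet(peaks)
        track = SignalTrack(records)
        regions = stitch(ps)
        perm = list(regions)
        rng.shuffle(perm)
        t1 = call_ses(regions, track, ps)
        t2 = call_ses(perm, track, ps)
        assert [r.region_id for r in t1.regions] == [r.region_id for r in t2.regions]
        assert t1.is_se == t2.is_se

    def test_region_signal_additivity(self):
        ps, track = self._toy()
        regions = stitch(ps, gap=10**9)  # all five in one region
        assert len(regions) == 1
        total = region_signal(regions[0], track, ps)
        assert total == pytest.approx(sum([1, 2, 3, 4, 100]))


class TestClassifySeCategories:
    def _table(self, intervals, ses):
        from sescape.se_caller import SERankTable, StitchedRegion

        regions = [StitchedRegion(iv, [f"m{i}"], sig) for i, (iv, sig) in enumerate(intervals)]
        regions.sort(key=lambda r: -r.signal)
        return SERankTable(
            regions, list(range(1, len(regions) + 1)), cutoff_signal=0.0, is_se=ses
        )

    def test_identical_sets_all_common(self):
        iv = GenomicInterval("chr1", 0, 1000)
        ta = self._table([(iv, 5.0)], [True])
        tb = self._table([(iv, 7.0)], [True])
        cats = classify_se_categories(ta, tb)
        assert len(cats["common"]) == 2  # one region from each side
        assert not cats["a_specific"] and not cats["b_specific"]

    def test_disjoint_sets_all_specific(self):
        ta = self._table([(GenomicInterval("chr1", 0, 1000), 5.0)], [True])
        tb = self._table([(GenomicInterval("chr1", 5000, 6000), 7.0)], [True])
        cats = classify_se_categories(ta, tb)
        assert not cats["common"]
        assert len(cats["a_specific"]) == 1 and len(cats["b_specific"]) == 1

    def test_matches_all_pairs_oracle(self, rng):
        def random_table(n):
            items = []
            for _ in range(n):
                start = int(rng.integers(0, 80_000))
                items.append(
                    (GenomicInterval("chr1", start, start + int(rng.integers(500, 4000))),
                     float(rng.lognormal(1, 1)))
                )
            return self._table(items, [bool(rng.random() < 0.5) for _ in range(n)])

        ta, tb = random_table(40), random_table(40)
        cats = classify_se_categories(ta, tb)
        ses_a, ses_b = ta.ses, tb.ses
        a_spec = [r for r in ses_a if not any(r.interval.overlaps(o.interval) for o in ses_b)]
        b_spec = [r for r in ses_b if not any(r.interval.overlaps(o.interval) for o in ses_a)]
        assert {r.region_id for r in cats["a_specific"]} == {r.region_id for r in a_spec}
        assert {r.region_id for r in cats["b_specific"]} == {r.region_id for r in b_spec}
        assert len(cats["common"]) == (len(ses_a) - len(a_spec)) + (len(ses_b) - len(b_spec))


class TestPlantedSeRecovery:
    def test_planted_ses_recovered_in_big_landscape(self):
        """20 planted SE clusters among ~1000 lone-enhancer regions in the
        disease condition: at least 90% must be called SE."""
        cfg = study_config("big-landscape")
        land = generate_landscape(cfg.landscape, seed=7)
        from sescape.se_caller import call_ses, stitch

        regions = stitch(land.peaks_b)
        table = call_ses(regions, land.track_b, land.peaks_b)
        se_ivs = [r.interval for r in table.ses]
        recovered = sum(
            any(iv.overlaps(se) for se in se_ivs) for iv in land.truth.se_regions
        )
        assert len(regions) >= 900  # the intended LE background scale
        assert recovered >= 0.9 * len(land.truth.se_regions)
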