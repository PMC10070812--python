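from collections import Counter
from math import comb

import numpy as np
import pytest

from sescape.motif_enrichment import (
    PWM,
    dinucleotide_shuffle,
    enrich_motifs,
    fisher_enrichment_p,
    make_background,
    read_jaspar_pwms,
    scan_sequence,
    write_jaspar_pwms,
)
from sescape.synthetic_data import SequenceConfig, generate_sequences

COMP = str.maketrans("ACGT", "TGCA")


def revcomp(s):
    return s.translate(COMP)[::-1]


def sharp_pwm(consensus, p_major=0.91):
    probs = np.full((4, len(consensus)), (1 - p_major) / 3)
    for j, base in enumerate(consensus):
        probs["ACGT".index(base), j] = p_major
    return PWM("test", probs)


def naive_scan(seq, pwm, fraction):
    """Position-by-position scorer over both strands, the scanning oracle."""
    lom = pwm.log_odds()
    threshold = fraction * pwm.max_score()
    L = pwm.length
    for strand_seq in (seq, revcomp(seq)):
        for i in range(len(strand_seq) - L + 1):
            score = 0.0
            for j, base in enumerate(strand_seq[i : i + L]):
                if base in "ACGT":
                    score += lom["ACGT".index(base), j]
            if score >= threshold - 1e-12:
                return True
    return False


def dinuc_counts(s):
    return Counter(zip(s, s[1:]))


class TestScanSequence:
    def test_consensus_window_hits(self):
        pwm = sharp_pwm("TGACTCAG")
        assert scan_sequence("AAAA" + "TGACTCAG" + "CCCC", pwm)

    def test_reverse_complement_hits(self):
        pwm = sharp_pwm("TGACTCAG")
        assert scan_sequence("AAAA" + revcomp("TGACTCAG") + "CCCC", pwm)

    def test_sequence_shorter_than_motif_is_no_hit(self):
        assert not scan_sequence("ACG", sharp_pwm("TGACTCAG"))

    def test_poly_n_neutral(self):
        pwm = sharp_pwm("TGACTCAG")
        assert not scan_sequence("N" * 50, pwm)

    def test_matches_naive_scanner_on_random_sequences(self, rng):
        pwm = sharp_pwm("TGACTCAG")
        bases = np.array(list("ACGT"))
        for fraction in (0.8, 0.95):
            for _ in range(30):
                seq = "".join(bases[rng.integers(0, 4, size=200)])
                assert scan_sequence(seq, pwm, fraction) == naive_scan(
                    seq, pwm, fraction
                )

    def test_strand_symmetry(self, rng):
        pwm = sharp_pwm("TGACTCAG")
        bases = np.array(list("ACGT"))
        for _ in range(20):
            seq = "".join(bases[rng.integers(0, 4, size=150)])
            assert scan_sequence(seq, pwm) == scan_sequence(revcomp(seq), pwm)


def oracle_fisher_greater(a, b, c, d):
    """One-sided Fisher tail by explicit enumeration over the table family."""
    row1, row2 = a + b, c + d
    col1 = a + c
    total = row1 + row2
    denom = comb(total, col1)
    p = 0.0
    for k in range(max(0, col1 - row2), min(row1, col1) + 1):
        if k >= a:
            p += comb(row1, k) * comb(row2, col1 - k) / denom
    return p


class TestFisher:
    def test_strong_table_closed_form(self):
        p = fisher_enrichment_p(9, 10, 1, 10)
        expected = (comb(10, 9) * comb(10, 1) + comb(10, 10) * comb(10, 0)) / comb(20, 10)
        assert p == pytest.approx(expected)

    def test_equal_rates_not_enriched(self):
        assert fisher_enrichment_p(5, 10, 5, 10) >= 0.5

    def test_matches_enumeration_for_small_margins(self, rng):
        for _ in range(200):
            n1 = int(rng.integers(1, 16))
            n2 = int(rng.integers(1, 16))
            a = int(rng.integers(0, n1 + 1))
            c = int(rng.integers(0, n2 + 1))
            got = fisher_enrichment_p(a, n1, c, n2)
            assert got == pytest.approx(
                oracle_fisher_greater(a, n1 - a, c, n2 - c), rel=1e-9
            )


class TestEnrichMotifs:
    def test_absent_motif_zero_percent_p_one(self):
        pwm = sharp_pwm("TGACTCAG")
        res = enrich_motifs(["AAAAAAAAAAAA"] * 12, ["AAAAAAAAAAAA"] * 12, [pwm])
        assert res[0].pct_target == 0.0
        assert res[0].p == 1.0

    def test_planted_motif_ranks_first(self, rng):
        cfg = SequenceConfig(n_targets=60, seq_length=300)
        seqs = generate_sequences(cfg, seed=5)
        pwms = [PWM.from_counts(mid, cnt) for mid, cnt in seqs.pwm_counts]
        targets = list(seqs.targets.values())
        background = make_background(targets, seed=99)
        res = enrich_motifs(targets, background, pwms)
        assert res[0].motif_id == "PLANTED"
        assert res[0].pct_target > res[0].pct_background

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            enrich_motifs([], ["ACGT"], [sharp_pwm("TGACTCAG")])


class TestBackground:
    def test_dinucleotide_composition_preserved_per_sequence(self, rng):
        bases = np.array(list("ACGT"))
        targets = ["".join(bases[rng.integers(0, 4, size=300)]) for _ in range(10)]
        shuffled = make_background(targets, seed=3)
        for orig, shuf in zip(targets, shuffled):
            assert len(shuf) == len(orig)
            assert dinuc_counts(shuf) == dinuc_counts(orig)
            assert Counter(shuf) == Counter(orig)

    def test_same_seed_reproducible(self, rng):
        bases = np.array(list("ACGT"))
        targets = ["".join(bases[rng.integers(0, 4, size=200)]) for _ in range(5)]
        assert make_background(targets, seed=11) == make_background(targets, seed=11)

    def test_short_unique_path_fixed_point(self):
        rng = np.random.default_rng(0)
        # ACGT's dinucleotide multiset admits only itself
        assert dinucleotide_shuffle("ACGT", rng) == "ACGT"

    def test_shuffles_vary_for_long_sequences(self, rng):
        bases = np.array(list("ACGT"))
        target = "".join(bases[rng.integers(0, 4, size=400)])
        outs = {make_background([target], seed=s)[0] for s in range(5)}
        assert len(outs) > 1


class TestJaspar:
    def test_roundtrip(self, tmp_path, rng):
        counts = rng.integers(0, 50, size=(4, 8)).astype(float)
        counts[0, :] += 1  # no zero-sum columns
        path = tmp_path / "m.jaspar"
        write_jaspar_pwms([("M1", counts)], str(path))
        pwms = read_jaspar_pwms(str(path))
        assert pwms[0].motif_id == "M1"
        expected = (counts + 0.5) / (counts.sum(axis=0) + 2.0)
        np.testing.assert_allclose(pwms[0].probs, expected)
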