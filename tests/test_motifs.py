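"""PWM construction, scanning, ZOOPS counting and enrichment."""

import itertools

import numpy as np
import pytest

from cistrokit.motifs import (
    PWM,
    MotifHit,
    load_motif_library,
    motif_enrichment_test,
    parse_motif_counts,
    percent_of_targets,
    pwm_from_counts,
    read_fasta,
    scan_sequence,
    score_threshold_for_fpr,
    write_fasta,
)

COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq):
    return seq.translate(COMP)[::-1]


class TestPwmConstruction:
    def test_single_column_arithmetic(self):
        counts = np.array([[10, 0, 0, 0]] * 4)
        pwm = pwm_from_counts(counts, pseudocount=0.25)
        assert pwm.probs[0, 0] == pytest.approx(10.25 / 11)
        expected = np.log2((10.25 / 11) / 0.25)
        assert pwm.log_odds[0, 0] == pytest.approx(expected)

    def test_uniform_counts_zero_log_odds(self):
        pwm = pwm_from_counts(np.full((5, 4), 25.0))
        assert np.allclose(pwm.log_odds, 0.0)

    def test_probs_sum_to_one(self, rng):
        counts = rng.integers(0, 50, size=(6, 4)).astype(float) + 1
        pwm = pwm_from_counts(counts)
        assert np.allclose(pwm.probs.sum(axis=1), 1.0)

    def test_zero_column_rejected(self):
        counts = np.array([[10, 5, 1, 2], [0, 0, 0, 0], [1, 1, 1, 1], [2, 2, 2, 2]])
        with pytest.raises(ValueError, match="observation"):
            pwm_from_counts(counts)

    def test_width_minimum(self):
        with pytest.raises(ValueError, match="width"):
            pwm_from_counts(np.full((3, 4), 10.0))


class TestThreshold:
    def test_exact_enumeration_oracle(self, gata3):
        """The DP threshold must match exhaustive enumeration of all 4^w
        words: tail probability <= 1e-4 at the threshold, > 1e-4 just below
        the next achievable score."""
        lo = gata3.log_odds
        w = lo.shape[0]
        scores = sorted(
            sum(lo[i, word[i]] for i in range(w))
            for word in itertools.product(range(4), repeat=w)
        )
        scores = np.array(scores)
        n = len(scores)
        tail_at = lambda t: np.sum(scores >= t - 1e-9) / n
        assert tail_at(gata3.threshold) <= 1e-4
        below = scores[scores < gata3.threshold - 1e-6]
        assert below.size and tail_at(below.max()) > 1e-4

    def test_short_motif_threshold_capped(self, motif_library):
        """A 6-bp motif cannot reach a 1e-4 per-window FPR; its threshold is
        capped at the maximum score so the consensus still registers."""
        half = motif_library["NR-half"]
        assert half.threshold == pytest.approx(half.max_score, abs=1e-6)
        assert scan_sequence(half, "TT" + half.consensus + "GG")


class TestScanning:
    def test_consensus_hit_max_score(self, gata3):
        seq = "TTT" + gata3.consensus + "CCGTA"
        hits = scan_sequence(gata3, seq)
        plus = [h for h in hits if h.strand == "+"]
        assert [h.offset for h in plus] == [3]
        assert plus[0].score == pytest.approx(gata3.max_score)

    def test_hand_computed_log_odds(self):
        """Score of a window equals the hand-summed per-position log-odds."""
        counts = np.array(
            [[10, 0, 0, 0], [0, 10, 0, 0], [0, 0, 10, 0], [0, 0, 0, 10]],
            dtype=float,
        )  # consensus ACGT
        pwm = pwm_from_counts(counts, pseudocount=0.25)
        hi = np.log2((10.25 / 11) / 0.25)
        lo_ = np.log2((0.25 / 11) / 0.25)
        hits = scan_sequence(pwm, "TTACGT")
        plus = [h for h in hits if h.strand == "+" and h.offset == 2]
        assert plus and plus[0].score == pytest.approx(4 * hi)
        # window "TTAC" at offset 0 mismatches every consensus base; verify
        # the hand-summed log-odds on a permissive copy of the PWM
        open_pwm = PWM("open", pwm.probs, pwm.background, threshold=-100.0)
        all_hits = {(h.offset, h.strand): h.score for h in scan_sequence(open_pwm, "TTACGT")}
        assert all_hits[(0, "+")] == pytest.approx(4 * lo_)
        # window "TACG" at offset 1: T/A mismatch, A/C mismatch, C/G mismatch,
        # G/T mismatch on the forward strand as well
        assert all_hits[(1, "+")] == pytest.approx(4 * lo_)

    def test_reverse_strand_hit(self, gata3):
        seq = "GG" + revcomp(gata3.consensus) + "ACGTA"
        hits = scan_sequence(gata3, seq)
        assert [(h.offset, h.strand) for h in hits] == [(2, "-")]
        assert hits[0].score == pytest.approx(gata3.max_score)

    def test_strand_consistency_under_revcomp(self, gata3, rng):
        """Scanning the reverse complement swaps strands and mirrors offsets."""
        bases = "ACGT"
        seq = "".join(rng.choice(list(bases), 60)) + gata3.consensus + "ACGTACGT"
        fwd = scan_sequence(gata3, seq)
        rev = scan_sequence(gata3, revcomp(seq))
        L, w = len(seq), gata3.width
        mirrored = sorted(
            (L - w - h.offset, {"+": "-", "-": "+"}[h.strand], round(h.score, 9))
            for h in rev
        )
        assert mirrored == sorted((h.offset, h.strand, round(h.score, 9)) for h in fwd)

    def test_n_windows_skipped(self, gata3):
        seq = gata3.consensus[:4] + "N" + gata3.consensus[5:]
        assert scan_sequence(gata3, seq) == []

    def test_short_sequence_empty(self, gata3):
        assert scan_sequence(gata3, "ACG") == []


class TestPercentOfTargets:
    def test_zoops_duplicate_hits_count_once(self, gata3):
        double = gata3.consensus + "TT" + gata3.consensus
        single = "TT" * 4 + gata3.consensus
        k, n, pct = percent_of_targets(gata3, [double + "A" * 2, single + "A" * 8])
        assert (k, n) == (2, 2) and pct == 100.0

    def test_hit_free_zero_percent(self, gata3):
        k, n, pct = percent_of_targets(gata3, ["A" * 50] * 10)
        assert (k, n, pct) == (0, 10, 0.0)

    def test_fixture_percents_exact(self, gata3, motif_classes):
        seqs = motif_classes["seqs"]
        assert percent_of_targets(gata3, seqs["shared"])[2] == pytest.approx(30.91)
        assert percent_of_targets(gata3, seqs["only_era"])[2] == pytest.approx(17.64)

    def test_fixture_backgrounds_hit_free(self, gata3, motif_classes):
        """Every embedded sequence is detected and no background sequence
        scores a hit, so the percents are exact by construction."""
        truth = motif_classes["truth"].set_index("seq")
        for cls, seqs in motif_classes["seqs"].items():
            from cistrokit.motifs import has_hit_batch

            hits = has_hit_batch(gata3, list(seqs.values()))
            embedded = truth.loc[list(seqs.keys()), "embedded"].to_numpy()
            assert np.array_equal(hits, embedded)


class TestEnrichment:
    def _seqs(self, gata3, n_hit, n_clean):
        hit = [gata3.consensus + "A" * 12] * n_hit
        clean = ["A" * 20] * n_clean
        return hit + clean

    def test_exhaustive_combinatorial_example(self, gata3):
        res = motif_enrichment_test(
            gata3, self._seqs(gata3, 3, 1), self._seqs(gata3, 2, 4)
        )
        assert res.p == pytest.approx(55 / 210)
        assert res.percent_of_target == pytest.approx(75.0)

    def test_identical_sets_not_enriched(self, gata3):
        seqs = self._seqs(gata3, 3, 5)
        assert motif_enrichment_test(gata3, seqs, seqs).p >= 0.5

    def test_all_target_hit_closed_form(self, gata3):
        from math import comb

        res = motif_enrichment_test(
            gata3, self._seqs(gata3, 4, 0), self._seqs(gata3, 0, 6)
        )
        assert res.p == pytest.approx(1 / comb(10, 4))

    def test_p_monotone_in_k_target(self, gata3):
        pvals = [
            motif_enrichment_test(
                gata3, self._seqs(gata3, k, 6 - k), self._seqs(gata3, 2, 6)
            ).p
            for k in range(0, 7)
        ]
        assert all(a >= b for a, b in zip(pvals, pvals[1:]))


class TestLibraryAndIO:
    def test_packaged_library_complete(self, motif_library):
        expected = {"ERE", "DR1", "FOXA1", "GATA3", "AP-1", "AP2-gamma",
                    "CTCF", "NR-half"}
        assert expected <= set(motif_library)
        for pwm in motif_library.values():
            assert pwm.width >= 4
            assert np.allclose(pwm.probs.sum(axis=1), 1.0)

    def test_parse_rejects_incomplete_matrix(self):
        with pytest.raises(ValueError, match="rows"):
            parse_motif_counts(">X\nA: 1 2\nC: 1 2\nG: 1 2\n")

    def test_fasta_roundtrip(self, tmp_path):
        seqs = {"s1": "ACGTACGTAC" * 12, "s2": "TTTT"}
        write_fasta(seqs, tmp_path / "x.fa")
        assert read_fasta(tmp_path / "x.fa") == seqs
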